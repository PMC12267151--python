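import numpy as np
import pytest

from pigtracer.enrichment import EnrichmentCurve
from pigtracer.peaks import bateman
from pigtracer.simulate import SCHEDULE_MIN, bateman_from_targets


@pytest.fixture(scope="session")
def schedule() -> np.ndarray:
    return np.asarray(SCHEDULE_MIN, dtype=float)


@pytest.fixture(scope="session")
def gln_truth_params() -> dict:
    """Bateman parameters hitting the glutamine-tracer reference summaries
    (Emax 1.18 MPE, Tmax 31.3 min, AUC 148.1 MPE·min over 0–300 min)."""
    A, ka, ke = bateman_from_targets(1.18, 31.3, 148.1, 0.0)
    return {"A": A, "ka": ka, "ke": ke, "t0": 0.0}


@pytest.fixture()
def noiseless_gln_curve(schedule, gln_truth_params) -> EnrichmentCurve:
    y = bateman(schedule, **gln_truth_params)
    y[schedule < 0] = 0.0
    return EnrichmentCurve(
        animal_id="pig-1",
        analyte="Gln_m5",
        unit="MPE",
        times_min=schedule,
        values=y,
        basal=0.0,
        baseline_corrected=True,
    )
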