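"""End-to-end run on a small synthetic cohort.

Simulates a reduced 2x2 cohort (3 animals per cell, glutamine-study
analytes only), runs simulate -> enrich -> fit -> metrics, and prints the
group summary together with how well the estimated rates of appearance
recover the generator's ground truth.
"""

import tempfile
from pathlib import Path

import pandas as pd

from pigtracer import run_pipeline

config = {
    "seed": 42,
    "group_sizes": {"LBW-Gln": 3, "NBW-Gln": 3, "LBW-W": 3, "NBW-W": 3},
    "analytes": ["Gln_m5", "Glc_m3", "CO2_gln"],
}

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "run"
    manifest = run_pipeline(out, config=config)
    print("stage row counts:", manifest["row_counts"])

    summary = pd.read_csv(out / "kinetics_group_summary.csv")
    ra = summary[summary["metric"] == "ra_mmol_kg_h"]
    print("\nestimated group-mean glutamine Ra, mmol/(kg*h):")
    print(ra[["group", "mean", "sem", "n"]].to_string(index=False))

    est = pd.read_csv(out / "kinetics.csv")
    truth = pd.read_csv(out / "truth.csv")
    m = est.merge(truth, on=["animal_id", "analyte"])
    m = m[m["ra_true_mmol_kg_h"].notna()]
    rel = ((m["ra_mmol_kg_h"] - m["ra_true_mmol_kg_h"]).abs()
           / m["ra_true_mmol_kg_h"])
    print(f"\nper-animal Ra recovery: median |rel error| {rel.median():.1%}")
# the manifest records seed, config hash and output checksums, so an
# identical configuration reproduces byte-identical tables
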