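"""Convert raw isotope readouts into baseline-corrected enrichment curves.

Two instrument channels feed the tracer pipeline:

* GC-MS isotopologue peak-area ratios (e.g. the m+4/m+0 ratio of a glutamine
  fragment, or m+6/m+0 and m+3/m+0 of glucose derivatives), converted to molar
  percent excess (MPE) through a linear calibration built from gravimetric
  standards of known enrichment.
* IRMS delta values (δ¹³C, ‰ vs VPDB) for CO₂, converted to atom percent
  excess (APE) over the animal's own basal sample with standard isotope-ratio
  arithmetic.

Both MPE and APE are percent-scale quantities; downstream kinetic equations
divide by 100 to reach mole/atom fraction excess.

Every animal contributes a basal sample drawn 15 min before the bolus
(time −15); enrichment curves are baseline-corrected by subtracting the basal
value so that the pre-bolus enrichment is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BASAL_TIME_MIN",
    "VPDB_R13",
    "CalibrationModel",
    "EnrichmentCurve",
    "DegenerateCalibrationError",
    "CalibrationFailureError",
    "build_calibration",
    "ratio_to_mpe",
    "delta_to_ape",
    "baseline_correct",
]

#: Nominal sampling time of the pre-bolus basal sample (minutes).
BASAL_TIME_MIN = -15.0

#: ¹³C/¹²C isotope ratio of the VPDB reference standard.
VPDB_R13 = 0.0111802


class DegenerateCalibrationError(ValueError):
    """Raised when fewer than two distinct standards are supplied."""


class CalibrationFailureError(ValueError):
    """Raised when a fitted calibration has a non-positive slope."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from an isotopologue peak-area ratio to MPE.

    Ordinary least squares with intercept; the intercept absorbs the
    natural-abundance offset of the measured ratio. ``valid_range`` is the
    MPE span covered by the standards — predictions outside it are flagged
    as extrapolated, not rejected.
    """

    slope: float
    intercept: float
    valid_range: tuple[float, float]
    residual_sd: float
    n_standards: int

    def predict(self, ratio: float) -> float:
        return self.slope * float(ratio) + self.intercept

    def inverse(self, mpe: float) -> float:
        """Ratio that the calibration maps to ``mpe`` (for simulation)."""
        return (float(mpe) - self.intercept) / self.slope


@dataclass
class EnrichmentCurve:
    """Per-animal, per-analyte enrichment time series.

    ``unit`` is ``"MPE"``, ``"APE"`` or a concentration unit such as
    ``"mmol/L"`` (the peak-fitting stage is unit-agnostic). ``basal`` holds
    the enrichment of the −15 min sample; after :func:`baseline_correct` it
    is zero and ``baseline_corrected`` is set.
    """

    animal_id: str
    analyte: str
    unit: str
    times_min: np.ndarray
    values: np.ndarray
    basal: float | None = None
    baseline_corrected: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError(
                f"times must be strictly increasing for {self.animal_id}/{self.analyte}"
            )

    @property
    def post_bolus(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) at t ≥ 0, excluding the basal point."""
        m = self.times_min >= 0
        return self.times_min[m], self.values[m]


def build_calibration(
    standards: list[tuple[float, float]],
) -> CalibrationModel:
    """Fit an OLS line mapping measured ratio → known MPE.

    Parameters
    ----------
    standards
        ``(known_mpe, measured_ratio)`` pairs, e.g. six standards spanning
        0–2.5 MPE.

    Raises
    ------
    DegenerateCalibrationError
        Fewer than two distinct known enrichments.
    CalibrationFailureError
        The fitted slope is not positive (ratio must increase with
        enrichment for a physically meaningful calibration).
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (known_mpe, measured_ratio) pairs")
    mpe, ratio = arr[:, 0], arr[:, 1]
    if np.unique(mpe).size < 2:
        raise DegenerateCalibrationError(
            "calibration needs at least 2 distinct standard enrichments"
        )
    # regress MPE on ratio: the instrument reading is the predictor at use time
    X = np.column_stack([ratio, np.ones_like(ratio)])
    coef, *_ = np.linalg.lstsq(X, mpe, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise CalibrationFailureError(f"non-positive calibration slope {slope:g}")
    resid = mpe - X @ coef
    dof = max(len(mpe) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        valid_range=(float(mpe.min()), float(mpe.max())),
        residual_sd=residual_sd,
        n_standards=int(len(mpe)),
    )


def ratio_to_mpe(
    ratio: float, cal: CalibrationModel
) -> tuple[float, list[str]]:
    """Convert one peak-area ratio to MPE through a calibration.

    Returns ``(mpe, flags)``. Predictions outside the calibrated MPE range
    carry the ``"extrapolated"`` flag; predictions more negative than one
    residual SD below zero are clamped to 0 with the ``"clamped_negative"``
    flag (small negatives within noise are kept as-is).
    """
    mpe = cal.predict(ratio)
    flags: list[str] = []
    lo, hi = cal.valid_range
    if not (lo <= mpe <= hi):
        flags.append("extrapolated")
    if mpe < -cal.residual_sd:
        flags.append("clamped_negative")
        mpe = 0.0
    return mpe, flags


def _atom_fraction(delta_permil: float, r_std: float) -> float:
    r = r_std * (delta_permil / 1000.0 + 1.0)
    return r / (1.0 + r)


def delta_to_ape(
    delta_sample: float, delta_basal: float, r_std: float = VPDB_R13
) -> float:
    """Atom percent excess of a sample δ¹³C over a basal δ¹³C.

    ``APE = 100 · (AF(δ_sample) − AF(δ_basal))`` with
    ``AF(δ) = R/(1+R)``, ``R = R_std·(δ/1000 + 1)``.

    Raises ``ValueError`` for δ ≤ −1000 ‰ (a nonphysical negative isotope
    ratio).
    """
    for d in (delta_sample, delta_basal):
        if not np.isfinite(d):
            raise ValueError("delta values must be finite")
        if d <= -1000.0:
            raise ValueError(f"delta {d} ‰ implies a non-positive isotope ratio")
    return 100.0 * (_atom_fraction(delta_sample, r_std) - _atom_fraction(delta_basal, r_std))


def baseline_correct(curve: EnrichmentCurve) -> EnrichmentCurve:
    """Subtract the −15 min basal enrichment from every point.

    Idempotent: a corrected curve has ``basal == 0`` and passes through
    unchanged. Negative post-correction values are retained (they are
    unbiased noise around zero) but flagged ``"negative_enrichment"``.

    Raises ``ValueError`` if no basal value is available.
    """
    if curve.baseline_corrected:
        return curve
    basal = curve.basal
    if basal is None:
        # accept a basal embedded in the time grid
        at_basal = curve.times_min <= BASAL_TIME_MIN
        if not at_basal.any():
            raise ValueError(
                f"no basal (−15 min) point for {curve.animal_id}/{curve.analyte}"
            )
        basal = float(curve.values[at_basal][0])
    values = curve.values - basal
    flags = list(curve.flags)
    if np.any(values < 0):
        flags.append("negative_enrichment")
    return replace(
        curve,
        values=values,
        basal=0.0,
        baseline_corrected=True,
        flags=flags,
    )
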