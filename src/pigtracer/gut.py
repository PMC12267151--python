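"""Sugar-probe absorption tests: LOQ censoring and Emax/Tmax/AUC summaries.

Three non-metabolized (or poorly metabolized) probe sugars characterize the
small intestine after an oral bolus:

* lactulose (0.75 g/kg) — paracellular permeability marker; in healthy
  animals plasma levels typically stay below the quantification limit,
* mannitol (0.3 g/kg) — transcellular marker of absorptive surface area,
* xylose (0.4 g/kg) — carrier-mediated absorption / malabsorption probe.

Plasma concentrations below the assay's limit of quantification (LOQ) are
flagged and stored at LOQ/2 (simple substitution; the flag is preserved so a
user can drop them instead). Curve summaries delegate to the same peak-fit
machinery used for tracer enrichments, so sugars and tracers share one
Emax/Tmax/AUC implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .enrichment import EnrichmentCurve
from .peaks import DEFAULT_FAMILIES, INTEGRATION_WINDOW_MIN, PeakFit, fit_peak_model

__all__ = [
    "SugarTestConfig",
    "SUGAR_DEFAULTS",
    "CensoredSeries",
    "censor_loq",
    "absorption_summary",
    "lactulose_mannitol_ratio",
]


@dataclass(frozen=True)
class SugarTestConfig:
    """Dose and quantification limit of one probe sugar."""

    analyte: str
    dose_g_per_kg: float
    loq_mmol_l: float

    def __post_init__(self) -> None:
        if self.dose_g_per_kg <= 0 or self.loq_mmol_l <= 0:
            raise ValueError("dose and LOQ must be positive")


SUGAR_DEFAULTS: dict[str, SugarTestConfig] = {
    "lactulose": SugarTestConfig("lactulose", 0.75, 0.03),
    "mannitol": SugarTestConfig("mannitol", 0.3, 0.06),
    "xylose": SugarTestConfig("xylose", 0.4, 0.01),
}


@dataclass
class CensoredSeries:
    """A concentration curve with below-LOQ values substituted at LOQ/2."""

    curve: EnrichmentCurve
    censored: np.ndarray  # bool mask aligned with curve.values
    n_censored: int
    all_below_loq: bool


def censor_loq(curve: EnrichmentCurve, cfg: SugarTestConfig) -> CensoredSeries:
    """Flag values below the LOQ and substitute LOQ/2.

    Values exactly at the LOQ are retained uncensored (≥ convention). A
    series with every point below the LOQ gets the ``all_below_loq`` flag —
    its summaries are not quantifiable.
    """
    values = np.asarray(curve.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("concentrations must be non-negative")
    mask = values < cfg.loq_mmol_l
    stored = np.where(mask, cfg.loq_mmol_l / 2.0, values)
    all_below = bool(mask.all())
    flags = list(curve.flags)
    if mask.any():
        flags.append("loq_censored")
    if all_below:
        flags.append("all_below_loq")
    new_curve = replace(curve, values=stored, flags=flags)
    return CensoredSeries(
        curve=new_curve,
        censored=mask,
        n_censored=int(mask.sum()),
        all_below_loq=all_below,
    )


def absorption_summary(
    series: CensoredSeries,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    window: tuple[float, float] = INTEGRATION_WINDOW_MIN,
) -> PeakFit | None:
    """Emax/Tmax/AUC of a sugar concentration curve via the shared peak fit.

    Returns ``None`` when the whole series is below the LOQ (the summary is
    not quantifiable). With fewer than 5 quantifiable post-bolus points the
    empirical fallback is used and flagged low-confidence.
    """
    if series.all_below_loq:
        return None
    curve = series.curve
    t_post = curve.times_min >= 0
    n_quant = int((~series.censored & t_post).sum())
    if n_quant < 5:
        fit = fit_peak_model(curve, families=(), window=window)
        return replace(fit, flags=tuple(set(fit.flags) | {"low_confidence"}))
    return fit_peak_model(curve, families=families, window=window)


def lactulose_mannitol_ratio(
    lac: PeakFit | None, man: PeakFit | None
) -> float | None:
    """AUC ratio lactulose:mannitol, or None when either is not quantifiable."""
    if lac is None or man is None or man.auc <= 0:
        return None
    return lac.auc / man.auc
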