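"""Synthetic factorial cohort generator with known kinetic ground truth.

Emulates a 2×2 birthweight × supplementation piglet study: four cells
(LBW-Gln 12, NBW-Gln 12, LBW-W 11, NBW-W 11 by default) of littermate-paired
animals from 18 litters, each with Bateman-shaped plasma enrichment curves
sampled at −15, 30, 60, …, 300 min, a delayed CO₂-enrichment response, probe
sugar concentration curves (lactulose drawn below its LOQ, as observed), and
multiplicative log-normal measurement noise.

Group-level curve targets default to the study's printed group means: plasma
tracer curves match the group Tmax and the AUC implied by the group rate of
appearance exactly, with Emax matched where the Bateman family permits (the
shape ratio ka/ke is solved from the AUC/Emax quotient; when the requested
peak is narrower than any Bateman curve, the near-symmetric limit is used and
the realized Emax is recorded). Per-animal parameters are log-normal around
the cell means with a litter random intercept; biological draws are
mean-preserving on the rate-of-appearance (1/AUC) scale and measurement
noise is mean-preserving on the enrichment scale, so cohort averages
converge to the configured kinetic targets.

Every simulated quantity is recorded in a per-animal ground-truth table
(curve parameters, analytic Emax/Tmax/AUC, true Ra, ¹³C recovery and
gluconeogenic conversion) so recovery of each pipeline stage can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .enrichment import BASAL_TIME_MIN, EnrichmentCurve
from .kinetics import (
    GLC_TRACER,
    GLN_TRACER,
    RecoveryInput,
    TracerDose,
    c13_recovery,
    dose_to_mmol,
    rate_of_appearance,
    tracer_excess_13c,
)
from .peaks import INTEGRATION_WINDOW_MIN, bateman, bateman_auc, bateman_tmax

__all__ = [
    "CELLS",
    "SCHEDULE_MIN",
    "SimulationConfig",
    "CohortTables",
    "bateman_from_targets",
    "simulate_enrichment_curve",
    "simulate_cohort",
    "ground_truth_table",
]

#: Factorial cells in fixed order: birthweight class × supplementation.
CELLS: tuple[str, ...] = ("LBW-Gln", "NBW-Gln", "LBW-W", "NBW-W")

#: Blood-sampling schedule (min relative to bolus; −15 is the basal sample).
SCHEDULE_MIN: tuple[float, ...] = (-15, 30, 60, 90, 120, 150, 180, 210, 240, 300)


def _cellmap(values: tuple[float, ...]) -> dict[str, float]:
    return dict(zip(CELLS, values))


@dataclass(frozen=True)
class AnalyteSpec:
    """Simulation targets for one analyte: per-cell (Emax, Tmax, AUC)."""

    name: str
    unit: str
    kind: str  # tracer | conversion | co2 | sugar
    emax: dict[str, float]
    tmax: dict[str, float]
    auc: dict[str, float] | None  # None → AUC follows from Emax and shape
    t0: float = 0.0
    dose: TracerDose | None = None
    normalization: float | None = None  # RBC→breath factor for CO₂ analytes


def _default_analytes() -> dict[str, AnalyteSpec]:
    """Group-mean targets taken from the study's printed kinetic tables.

    Plasma tracer AUCs are derived from the printed group rates of
    appearance (AUC = D/Ra on the MPE scale), keeping the truth table's Ra
    exactly at the configured group means; m+3 glucose AUCs follow from the
    printed conversion percentages applied to those glutamine AUCs.
    """
    ra_gln = _cellmap((2.68, 3.11, 3.07, 2.62))
    ra_glc = _cellmap((5.63, 5.48, 5.07, 6.61))
    conv = _cellmap((8.24, 9.78, 10.4, 7.37))
    d_gln = dose_to_mmol(GLN_TRACER)
    d_glc = dose_to_mmol(GLC_TRACER)
    auc_gln = {c: d_gln / ra_gln[c] * 100.0 * 60.0 for c in CELLS}
    auc_glc = {c: d_glc / ra_glc[c] * 100.0 * 60.0 for c in CELLS}
    auc_m3 = {c: conv[c] / 100.0 * auc_gln[c] for c in CELLS}
    return {
        "Gln_m5": AnalyteSpec(
            "Gln_m5", "MPE", "tracer",
            emax=_cellmap((1.18, 0.89, 0.96, 1.13)),
            tmax=_cellmap((31.3, 37.8, 36.6, 29.1)),
            auc=auc_gln, dose=GLN_TRACER,
        ),
        "Glc_m3": AnalyteSpec(
            "Glc_m3", "MPE", "conversion",
            emax=_cellmap((0.12, 0.09, 0.10, 0.11)),
            tmax=_cellmap((56.8, 75.1, 61.6, 56.5)),
            auc=auc_m3,
        ),
        "CO2_gln": AnalyteSpec(
            "CO2_gln", "APE", "co2",
            emax=_cellmap((0.10, 0.08, 0.09, 0.09)),
            tmax=_cellmap((59.1, 80.0, 74.9, 61.1)),
            auc=_cellmap((15.4, 14.2, 16.1, 14.5)),
            t0=15.0, dose=GLN_TRACER, normalization=0.90,
        ),
        "Glc_m6": AnalyteSpec(
            "Glc_m6", "MPE", "tracer",
            emax=_cellmap((0.68, 0.52, 0.61, 0.51)),
            tmax=_cellmap((49.6, 58.2, 50.3, 50.2)),
            auc=auc_glc, dose=GLC_TRACER,
        ),
        "CO2_glc": AnalyteSpec(
            "CO2_glc", "APE", "co2",
            emax=_cellmap((0.07, 0.07, 0.06, 0.05)),
            tmax=_cellmap((116.0, 144.0, 125.0, 120.0)),
            auc=_cellmap((13.7, 13.8, 12.7, 10.1)),
            t0=30.0, dose=GLC_TRACER, normalization=0.98,
        ),
        "xylose": AnalyteSpec(
            "xylose", "mmol/L", "sugar",
            emax=_cellmap((1.35, 1.27, 1.21, 0.92)),
            tmax=_cellmap((60.6, 101.0, 60.3, 72.8)),
            auc=_cellmap((214.0, 200.0, 164.0, 160.0)),
        ),
        "mannitol": AnalyteSpec(
            # no printed kinetic table for mannitol; plausible transcellular
            # probe levels, well above the 0.06 mmol/L LOQ
            "mannitol", "mmol/L", "sugar",
            emax=_cellmap((0.32, 0.28, 0.30, 0.28)),
            tmax=_cellmap((90.0, 100.0, 90.0, 95.0)),
            auc=None,
        ),
        "lactulose": AnalyteSpec(
            # intact barrier: plasma lactulose stays below the 0.03 mmol/L LOQ
            "lactulose", "mmol/L", "sugar",
            emax=_cellmap((0.012, 0.012, 0.012, 0.012)),
            tmax=_cellmap((120.0, 120.0, 120.0, 120.0)),
            auc=None,
        ),
    }


@dataclass
class SimulationConfig:
    """Study conditions of the simulated cohort.

    ``noise_cv`` is the multiplicative measurement CV on post-bolus points;
    ``animal_cv`` and ``litter_sd`` are the biological log-scale SDs of the
    per-animal amplitude/time multipliers and the shared litter intercept
    (defaults reflect the between-animal spread implied by the printed group
    SEMs). ``basal_sd`` is the absolute noise floor on the basal sample.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"LBW-Gln": 12, "NBW-Gln": 12, "LBW-W": 11, "NBW-W": 11}
    )
    n_litters: int = 18
    seed: int = 0
    schedule_min: tuple[float, ...] = SCHEDULE_MIN
    analytes: tuple[str, ...] = (
        "Gln_m5", "Glc_m3", "CO2_gln", "Glc_m6", "CO2_glc",
        "xylose", "mannitol", "lactulose",
    )
    noise_cv: float = 0.05
    basal_sd: float = 0.002
    animal_cv: float = 0.20
    litter_sd: float = 0.10
    tmax_cv: float = 0.10
    r_co2_mmol_kg_h: float = 48.0
    analyte_specs: dict[str, AnalyteSpec] = field(default_factory=_default_analytes)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be ≥ 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be ≥ 0")


@dataclass
class CohortTables:
    """Simulated study: animal metadata, long-format curves, ground truth."""

    animals: pd.DataFrame
    curves: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# curve construction


def _shape_quotient(g: float, tmax: float, t0: float, window_hi: float) -> float:
    """AUC/Emax of a unit-amplitude Bateman with shape ratio g = ka/ke."""
    tm = tmax - t0
    ke = math.log(g) / ((g - 1.0) * tm)
    ka = g * ke
    emax = math.exp(-ke * tm) - math.exp(-ka * tm)
    x = window_hi - t0
    auc = (1 - math.exp(-ke * x)) / ke - (1 - math.exp(-ka * x)) / ka
    return auc / emax


def bateman_from_targets(
    emax: float,
    tmax: float,
    auc: float | None,
    t0: float = 0.0,
    window: tuple[float, float] = INTEGRATION_WINDOW_MIN,
    shape_ratio: float = 5.0,
) -> tuple[float, float, float]:
    """Bateman parameters (A, ka, ke) hitting kinetic summary targets.

    With an AUC target, Tmax and AUC are matched exactly and the shape ratio
    ka/ke is solved so the peak height equals ``emax`` — the AUC/Emax
    quotient is monotone in the ratio, so a bracketed root always exists
    within the family's reachable band. Targets outside that band (peaks
    narrower than the near-symmetric limit or flatter than the window allows)
    clamp to the nearest representable shape: AUC stays exact, Emax drifts.

    Without an AUC target the fixed ``shape_ratio`` is used and the amplitude
    is set from ``emax``.
    """
    if not (window[0] <= t0 < tmax < window[1]):
        raise ValueError("need window lo ≤ t0 < tmax < window hi")
    tm = tmax - t0
    if auc is None:
        g = shape_ratio
    else:
        target = auc / emax
        lo, hi = 1.0 + 1e-9, 1e8
        f = lambda g: _shape_quotient(g, tmax, t0, window[1]) - target
        if f(lo) >= 0.0:
            g = lo
        elif f(hi) <= 0.0:
            g = hi
        else:
            g = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    ke = math.log(g) / ((g - 1.0) * tm)
    ka = g * ke
    emax_unit = math.exp(-ke * tm) - math.exp(-ka * tm)
    if auc is None:
        A = emax / emax_unit
    else:
        A = auc / bateman_auc(1.0, ka, ke, t0, window)
    return A, ka, ke


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def simulate_enrichment_curve(
    params: dict[str, float],
    schedule_min: tuple[float, ...],
    noise_cv: float,
    rng: np.random.Generator,
    animal_id: str = "sim",
    analyte: str = "analyte",
    unit: str = "MPE",
    basal_sd: float = 0.0,
) -> EnrichmentCurve:
    """Evaluate a Bateman curve on the schedule and add measurement noise.

    Post-bolus points get mean-preserving multiplicative log-normal noise
    (``×exp(σZ − σ²/2)`` with ``σ² = ln(1 + cv²)``); the basal point is an
    absolute-noise draw around zero. ``noise_cv = 0`` returns the exact
    deterministic evaluation.
    """
    t = np.asarray(schedule_min, dtype=float)
    y = bateman(t, params["A"], params["ka"], params["ke"], params.get("t0", 0.0))
    basal_mask = t <= BASAL_TIME_MIN
    y[basal_mask] = 0.0
    if noise_cv > 0:
        sigma = _lognormal_sigma(noise_cv)
        z = rng.standard_normal(t.size)
        mult = np.exp(sigma * z - 0.5 * sigma**2)
        y = np.where(basal_mask, y, y * mult)
    if basal_sd > 0:
        y[basal_mask] += basal_sd * rng.standard_normal(int(basal_mask.sum()))
    basal = float(y[basal_mask][0]) if basal_mask.any() else None
    return EnrichmentCurve(
        animal_id=animal_id,
        analyte=analyte,
        unit=unit,
        times_min=t,
        values=y,
        basal=basal,
    )


# ---------------------------------------------------------------------------
# cohort


def _make_animals(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Animal metadata: littermate-paired LBW/NBW, linear BW trajectories."""
    rows = []
    counters = {"LBW": 0, "NBW": 0}
    for cell in CELLS:
        n = cfg.group_sizes.get(cell, 0)
        biw_class, suppl = cell.split("-")
        for _ in range(n):
            idx = counters[biw_class]
            counters[biw_class] += 1
            # littermate pairing: the k-th LBW and k-th NBW share a litter
            litter = idx % cfg.n_litters + 1
            if biw_class == "LBW":
                biw = float(np.clip(1.04 + 0.08 * rng.standard_normal(), 0.8, 1.2))
                adg = 0.15 + 0.02 * rng.standard_normal()
                crl = 0.27 + 0.01 * rng.standard_normal()
            else:
                biw = float(np.clip(1.55 + 0.08 * rng.standard_normal(), 1.4, 1.8))
                adg = 0.22 + 0.02 * rng.standard_normal()
                crl = 0.31 + 0.01 * rng.standard_normal()
            adg = max(adg, 0.02)
            rows.append(
                {
                    "animal_id": f"{cell}-{idx + 1:04d}",
                    "litter_id": f"L{litter:03d}",
                    "biw_class": biw_class,
                    "supplementation": suppl,
                    "group": cell,
                    "birthweight_kg": round(biw, 4),
                    "adg_kg_d": round(adg, 4),
                    "bw_14d_kg": round(biw + adg * 13, 4),
                    "bw_16d_kg": round(biw + adg * 15, 4),
                    "crl_m": round(max(crl, 0.2), 4),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(cfg: SimulationConfig) -> CohortTables:
    """Simulate the full study: animals, curves and the ground-truth table.

    Draw order is fixed (cells, then animals, then analytes in configured
    order) so an identical seed reproduces byte-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    animals = _make_animals(cfg, rng)

    # litter random intercepts on the log scale; the +σ²/2 drifts below make
    # the joint amplitude × time draw mean-preserving on the 1/AUC (rate of
    # appearance) scale, so truth-table cell-mean Ra is unbiased for the
    # configured group Ra
    sig_l = cfg.litter_sd
    litter_ids = sorted(animals["litter_id"].unique())
    litter_eff = {
        lid: sig_l * float(rng.standard_normal()) + 0.5 * sig_l**2
        for lid in litter_ids
    }

    sig_a = _lognormal_sigma(cfg.animal_cv)
    sig_t = _lognormal_sigma(cfg.tmax_cv)
    window = INTEGRATION_WINDOW_MIN

    # group-level curve parameters, solved once per analyte × cell
    base_params: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for name in cfg.analytes:
        spec = cfg.analyte_specs[name]
        for cell in CELLS:
            auc = spec.auc[cell] if spec.auc is not None else None
            A, ka, ke = bateman_from_targets(
                spec.emax[cell], spec.tmax[cell], auc, spec.t0, window
            )
            base_params[(name, cell)] = (A, ka, ke, spec.t0)

    curve_rows: list[dict] = []
    truth_rows: list[dict] = []
    for _, animal in animals.iterrows():
        aid, cell, lid = animal["animal_id"], animal["group"], animal["litter_id"]
        leff = litter_eff[lid]
        per_analyte_auc: dict[str, float] = {}
        for name in cfg.analytes:
            spec = cfg.analyte_specs[name]
            A0, ka0, ke0, t00 = base_params[(name, cell)]
            # amplitude multiplier: litter intercept + animal effect
            amp = math.exp(leff + sig_a * float(rng.standard_normal()) + 0.5 * sig_a**2)
            # time-scale multiplier: dilates Tmax and AUC, preserves shape
            tsc = math.exp(sig_t * float(rng.standard_normal()) + 0.5 * sig_t**2)
            params = {"A": A0 * amp, "ka": ka0 / tsc, "ke": ke0 / tsc, "t0": t00 * tsc}
            curve = simulate_enrichment_curve(
                params, cfg.schedule_min, cfg.noise_cv, rng,
                animal_id=aid, analyte=name, unit=spec.unit,
                basal_sd=cfg.basal_sd,
            )
            mtype = "concentration" if spec.kind == "sugar" else "enrichment"
            for t, v in zip(curve.times_min, curve.values):
                curve_rows.append(
                    {
                        "animal_id": aid,
                        "analyte": name,
                        "unit": spec.unit,
                        "measurement_type": mtype,
                        "time_min": t,
                        "value": v,
                    }
                )
            tmax_true = bateman_tmax(params["ka"], params["ke"], params["t0"])
            emax_true = float(bateman(np.array([tmax_true]), **params)[0])
            auc_true = bateman_auc(
                params["A"], params["ka"], params["ke"], params["t0"], window
            )
            per_analyte_auc[name] = auc_true
            truth = {
                "animal_id": aid,
                "group": cell,
                "analyte": name,
                "A": params["A"],
                "ka": params["ka"],
                "ke": params["ke"],
                "t0": params["t0"],
                "emax_true": emax_true,
                "tmax_true_min": tmax_true,
                "auc_true_unit_min": auc_true,
                "ra_true_mmol_kg_h": np.nan,
                "rec_true_pct": np.nan,
                "conversion_true_pct": np.nan,
            }
            if spec.kind == "tracer":
                truth["ra_true_mmol_kg_h"] = rate_of_appearance(
                    dose_to_mmol(spec.dose), auc_true / 60.0
                )
            elif spec.kind == "co2":
                truth["rec_true_pct"] = c13_recovery(
                    RecoveryInput(
                        auc_co2_ape_min=auc_true,
                        r_co2_mmol_kg_h=cfg.r_co2_mmol_kg_h,
                        normalization=spec.normalization,
                    ),
                    tracer_excess_13c(spec.dose),
                )
            elif spec.kind == "conversion" and "Gln_m5" in per_analyte_auc:
                truth["conversion_true_pct"] = (
                    100.0 * auc_true / per_analyte_auc["Gln_m5"]
                )
            truth_rows.append(truth)

    curves = pd.DataFrame(curve_rows)
    truth = pd.DataFrame(truth_rows)
    return CohortTables(animals=animals, curves=curves, truth=truth, config=cfg)


def ground_truth_table(tables: CohortTables) -> pd.DataFrame:
    """Per-animal true parameters, joinable on (animal_id, analyte)."""
    return tables.truth.copy()
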