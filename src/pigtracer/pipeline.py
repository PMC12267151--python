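"""End-to-end orchestration: simulate or ingest → enrich → fit → metrics.

Stable file contracts, all plain CSV:

* ``curves.csv`` (input/intermediate, long format) — columns ``animal_id,
  analyte, unit, measurement_type, time_min, value``; ``measurement_type``
  one of ``ratio`` (GC-MS peak-area ratio, needs a calibration), ``delta``
  (IRMS ‰ vs VPDB), ``enrichment`` (already MPE/APE) or ``concentration``
  (mmol/L). Time is minutes relative to the bolus; −15 is the basal sample.
* ``fits.csv`` — one row per animal × analyte with family, parameters,
  Emax, Tmax (min), AUC (unit × min and unit × h), AICc, convergence, RMSE.
* ``kinetics.csv`` / ``kinetics_group_summary.csv`` — per-animal and
  group-mean ± SEM kinetic endpoints (Ra, ¹³C recovery %, conversion %).
* ``gut.csv`` — sugar-probe summaries after LOQ censoring.
* ``manifest.json`` — seed, config hash, per-stage row counts and a sha256
  checksum of every output file; deterministic stages re-run to identical
  checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    BASAL_TIME_MIN,
    CalibrationModel,
    EnrichmentCurve,
    baseline_correct,
    delta_to_ape,
    ratio_to_mpe,
)
from .gut import SUGAR_DEFAULTS, absorption_summary, censor_loq
from .kinetics import (
    GLC_TRACER,
    GLN_TRACER,
    RecoveryInput,
    c13_recovery,
    dose_to_mmol,
    gluconeogenic_conversion,
    rate_of_appearance,
    tracer_excess_13c,
)
from .peaks import DEFAULT_FAMILIES, fit_peak_model, summarize_fit
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "CURVE_COLUMNS",
    "SchemaError",
    "validate_curves",
    "enrich_curves",
    "fit_curves",
    "compute_metrics",
    "gut_summaries",
    "run_pipeline",
]

CURVE_COLUMNS = (
    "animal_id",
    "analyte",
    "unit",
    "measurement_type",
    "time_min",
    "value",
)

#: Which analyte plays which role in the kinetic endpoints.
ANALYTE_ROLES = {
    "Gln_m5": {"role": "tracer", "dose": GLN_TRACER},
    "Glc_m6": {"role": "tracer", "dose": GLC_TRACER},
    "CO2_gln": {"role": "co2", "dose": GLN_TRACER, "normalization": 0.90},
    "CO2_glc": {"role": "co2", "dose": GLC_TRACER, "normalization": 0.98},
    "Glc_m3": {"role": "conversion", "denominator": "Gln_m5"},
}


class SchemaError(ValueError):
    """Raised when an input table violates the documented file contract."""


def validate_curves(df: pd.DataFrame) -> None:
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"curves table missing column(s): {', '.join(missing)}")
    bad_type = set(df["measurement_type"]) - {
        "ratio", "delta", "enrichment", "concentration"
    }
    if bad_type:
        raise SchemaError(f"unknown measurement_type value(s): {sorted(bad_type)}")
    if df["value"].isna().any():
        n = int(df["value"].isna().sum())
        raise SchemaError(f"{n} missing value(s) in curves table")


# ---------------------------------------------------------------------------
# stages


def enrich_curves(
    df: pd.DataFrame,
    calibrations: dict[str, CalibrationModel] | None = None,
) -> pd.DataFrame:
    """Convert raw readouts to baseline-corrected enrichment/concentration.

    ``ratio`` rows need a calibration for their analyte; ``delta`` rows are
    converted to APE against the animal's basal delta; ``enrichment`` rows
    are baseline-corrected as-is; ``concentration`` rows pass through
    untouched (sugar tests are absolute concentrations, not excesses).
    """
    validate_curves(df)
    calibrations = calibrations or {}
    out_rows: list[dict] = []
    for (aid, analyte), grp in df.groupby(["animal_id", "analyte"], sort=True):
        grp = grp.sort_values("time_min")
        mtype = grp["measurement_type"].iloc[0]
        unit = str(grp["unit"].iloc[0])
        times = grp["time_min"].to_numpy(dtype=float)
        values = grp["value"].to_numpy(dtype=float)
        flags = [""] * len(values)
        if mtype == "ratio":
            if analyte not in calibrations:
                raise SchemaError(f"no calibration provided for analyte {analyte!r}")
            cal = calibrations[analyte]
            conv = [ratio_to_mpe(v, cal) for v in values]
            values = np.array([c[0] for c in conv])
            flags = [";".join(c[1]) for c in conv]
            unit = "MPE"
            mtype = "enrichment"
        elif mtype == "delta":
            basal_mask = times <= BASAL_TIME_MIN
            if not basal_mask.any():
                raise SchemaError(f"no basal delta for {aid}/{analyte}")
            basal_delta = float(values[basal_mask][0])
            values = np.array([delta_to_ape(v, basal_delta) for v in values])
            unit = "APE"
            mtype = "enrichment"

        if mtype == "enrichment":
            curve = EnrichmentCurve(
                animal_id=str(aid), analyte=str(analyte), unit=unit,
                times_min=times, values=values,
            )
            curve = baseline_correct(curve)
            values = curve.values
            curve_flags = ";".join(curve.flags)
        else:
            curve_flags = ""
        for t, v, fl in zip(times, values, flags):
            row_flags = ";".join(x for x in (fl, curve_flags) if x)
            out_rows.append(
                {
                    "animal_id": aid,
                    "analyte": analyte,
                    "unit": unit,
                    "measurement_type": mtype,
                    "time_min": t,
                    "value": v,
                    "flags": row_flags,
                }
            )
    return pd.DataFrame(out_rows)


def _curve_from_rows(grp: pd.DataFrame) -> EnrichmentCurve:
    grp = grp.sort_values("time_min")
    return EnrichmentCurve(
        animal_id=str(grp["animal_id"].iloc[0]),
        analyte=str(grp["analyte"].iloc[0]),
        unit=str(grp["unit"].iloc[0]),
        times_min=grp["time_min"].to_numpy(dtype=float),
        values=grp["value"].to_numpy(dtype=float),
        basal=0.0,
        baseline_corrected=True,
    )


def fit_curves(
    enriched: pd.DataFrame,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> pd.DataFrame:
    """Peak-fit every enrichment curve; one summary row per animal × analyte."""
    rows = []
    mask = enriched["measurement_type"] == "enrichment"
    for (_aid, _analyte), grp in enriched[mask].groupby(
        ["animal_id", "analyte"], sort=True
    ):
        fit = fit_peak_model(_curve_from_rows(grp), families=families)
        rows.append(summarize_fit(fit))
    if not rows:
        return pd.DataFrame(
            columns=["animal_id", "analyte", "family", "Emax", "Emax_unit",
                     "Tmax_min", "AUC_unit_min", "AUC_unit_h", "aicc",
                     "converged", "rmse", "flags"]
        )
    return pd.DataFrame(rows)


def compute_metrics(
    fits: pd.DataFrame,
    rec_mode: str = "dimensional",
    r_co2_mmol_kg_h: float = 48.0,
    t_hours: float = 5.0,
    roles: dict | None = None,
) -> pd.DataFrame:
    """Kinetic endpoints per animal from the fitted AUCs.

    Emits one row per animal × analyte-role: Ra for plasma tracers, recovery
    % for CO₂ curves, conversion % for the m+3 glucose / m+5 glutamine pair.
    """
    roles = roles if roles is not None else ANALYTE_ROLES
    metric_cols = ["animal_id", "analyte", "auc_unit_min", "ra_mmol_kg_h",
                   "rec_pct", "rec_mode", "conversion_pct", "flags"]
    if fits.empty:
        return pd.DataFrame(columns=metric_cols)
    idx = fits.set_index(["animal_id", "analyte"])["AUC_unit_min"]
    rows = []
    for (aid, analyte), auc in idx.items():
        if analyte not in roles:
            continue
        spec = roles[analyte]
        rec: dict = {
            "animal_id": aid,
            "analyte": analyte,
            "auc_unit_min": auc,
            "ra_mmol_kg_h": np.nan,
            "rec_pct": np.nan,
            "rec_mode": "",
            "conversion_pct": np.nan,
            "flags": "",
        }
        try:
            if spec["role"] == "tracer":
                rec["ra_mmol_kg_h"] = rate_of_appearance(
                    dose_to_mmol(spec["dose"]), auc / 60.0
                )
            elif spec["role"] == "co2":
                rec["rec_pct"] = c13_recovery_from_auc(
                    auc, spec["dose"], spec["normalization"],
                    rec_mode, r_co2_mmol_kg_h, t_hours,
                )
                rec["rec_mode"] = rec_mode
            elif spec["role"] == "conversion":
                denom = idx.get((aid, spec["denominator"]), np.nan)
                if np.isfinite(denom) and denom > 0:
                    rec["conversion_pct"] = gluconeogenic_conversion(auc, denom)
                else:
                    rec["flags"] = "missing_denominator"
        except ValueError as exc:
            rec["flags"] = f"metric_error:{exc}"
        rows.append(rec)
    return pd.DataFrame(rows)


def c13_recovery_from_auc(
    auc_ape_min: float,
    dose,
    normalization: float,
    mode: str = "dimensional",
    r_co2_mmol_kg_h: float = 48.0,
    t_hours: float = 5.0,
) -> float:
    """Recovery % straight from a CO₂ AUC and the dose specification."""
    inp = RecoveryInput(
        auc_co2_ape_min=max(auc_ape_min, 0.0),
        r_co2_mmol_kg_h=r_co2_mmol_kg_h,
        t_hours=t_hours,
        normalization=normalization,
        mode=mode,
    )
    return c13_recovery(inp, tracer_excess_13c(dose))


def group_summary(metrics: pd.DataFrame, animals: pd.DataFrame) -> pd.DataFrame:
    """Cell means ± SEM of each kinetic endpoint by factorial group."""
    merged = metrics.merge(animals[["animal_id", "group"]], on="animal_id")
    out = []
    for (group, analyte), grp in merged.groupby(["group", "analyte"], sort=True):
        for col in ("ra_mmol_kg_h", "rec_pct", "conversion_pct"):
            vals = grp[col].dropna()
            if vals.empty:
                continue
            out.append(
                {
                    "group": group,
                    "analyte": analyte,
                    "metric": col,
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else np.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(out)


def gut_summaries(
    curves: pd.DataFrame,
    configs: dict | None = None,
) -> pd.DataFrame:
    """LOQ-censor and summarize each sugar concentration curve."""
    configs = configs or SUGAR_DEFAULTS
    rows = []
    mask = curves["measurement_type"] == "concentration"
    for (aid, analyte), grp in curves[mask].groupby(
        ["animal_id", "analyte"], sort=True
    ):
        if analyte not in configs:
            continue
        grp = grp.sort_values("time_min")
        curve = EnrichmentCurve(
            animal_id=str(aid), analyte=str(analyte),
            unit=str(grp["unit"].iloc[0]),
            times_min=grp["time_min"].to_numpy(dtype=float),
            values=np.maximum(grp["value"].to_numpy(dtype=float), 0.0),
            basal=0.0, baseline_corrected=True,
        )
        series = censor_loq(curve, configs[analyte])
        fit = absorption_summary(series)
        row = {
            "animal_id": aid,
            "analyte": analyte,
            "n_censored": series.n_censored,
            "quantifiable": fit is not None,
        }
        if fit is None:
            row.update(
                Emax=np.nan, Tmax_min=np.nan, AUC_unit_min=np.nan,
                converged=False, flags="all_below_loq",
            )
        else:
            row.update(
                Emax=fit.emax, Tmax_min=fit.tmax_min, AUC_unit_min=fit.auc,
                converged=fit.converged, flags=";".join(fit.flags),
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    """Flat key-value YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a flat key: value mapping")
    return cfg


def run_pipeline(
    out_dir: str | Path,
    config: dict | None = None,
    input_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run simulate (or ingest) → enrich → fit → metrics → gut → manifest.

    With ``input_dir`` the stage chain starts from ``<input_dir>/curves.csv``
    (+ ``animals.csv``); otherwise a synthetic cohort is simulated. Returns
    the manifest dict (also written to ``manifest.json``).
    """
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config["seed"] = int(seed)

    sim_keys = (
        "seed", "noise_cv", "animal_cv", "litter_sd", "tmax_cv",
        "basal_sd", "n_litters", "r_co2_mmol_kg_h",
    )
    written: dict[str, Path] = {}
    if input_dir is None:
        sim_kwargs = {k: config[k] for k in sim_keys if k in config}
        if "group_sizes" in config:
            sim_kwargs["group_sizes"] = dict(config["group_sizes"])
        if "analytes" in config:
            sim_kwargs["analytes"] = tuple(config["analytes"])
        sim_cfg = SimulationConfig(**sim_kwargs)
        tables = simulate_cohort(sim_cfg)
        animals, curves = tables.animals, tables.curves
        _write_csv(animals, out / "animals.csv")
        _write_csv(curves, out / "curves.csv")
        _write_csv(tables.truth, out / "truth.csv")
        written.update(
            {
                "animals.csv": out / "animals.csv",
                "curves.csv": out / "curves.csv",
                "truth.csv": out / "truth.csv",
            }
        )
    else:
        input_dir = Path(input_dir)
        curves = pd.read_csv(input_dir / "curves.csv")
        animals_path = input_dir / "animals.csv"
        animals = pd.read_csv(animals_path) if animals_path.exists() else None

    validate_curves(curves)
    enriched = enrich_curves(curves)
    _write_csv(enriched, out / "enriched.csv")
    written["enriched.csv"] = out / "enriched.csv"

    families = tuple(config.get("families", DEFAULT_FAMILIES))
    fits = fit_curves(enriched, families=families)
    _write_csv(fits, out / "fits.csv")
    written["fits.csv"] = out / "fits.csv"

    rec_mode = config.get("rec_mode", "dimensional")
    metrics = compute_metrics(
        fits,
        rec_mode=rec_mode,
        r_co2_mmol_kg_h=config.get("r_co2_mmol_kg_h", 48.0),
        t_hours=config.get("t_hours", 5.0),
    )
    _write_csv(metrics, out / "kinetics.csv")
    written["kinetics.csv"] = out / "kinetics.csv"

    if animals is not None and not metrics.empty:
        summary = group_summary(metrics, animals)
        _write_csv(summary, out / "kinetics_group_summary.csv")
        written["kinetics_group_summary.csv"] = out / "kinetics_group_summary.csv"

    gut = gut_summaries(curves)
    if not gut.empty:
        _write_csv(gut, out / "gut.csv")
        written["gut.csv"] = out / "gut.csv"

    manifest = {
        "package_version": __version__,
        "seed": config.get("seed"),
        "rec_mode": rec_mode,
        "auc_method": "model" if families else "trapezoid",
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "row_counts": {
            "curves": int(len(curves)),
            "enriched": int(len(enriched)),
            "fits": int(len(fits)),
            "kinetics": int(len(metrics)),
        },
        "checksums": {name: _sha256(path) for name, path in sorted(written.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
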