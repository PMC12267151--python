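"""Peak-shaped curve fitting for bolus enrichment and concentration data.

After an oral bolus, plasma tracer enrichment (and probe-sugar concentration)
rises to a single maximum and decays. Three standard peak families are fitted
by nonlinear least squares and the winner is chosen by AICc:

* ``bateman`` — the one-compartment absorption–elimination (Bateman) curve
  ``A·(e^{−ke·τ} − e^{−ka·τ})``, ``τ = t − t0``, the mechanistic shape for
  first-order oral absorption; degenerate equal-rate limit ``A·τ·e^{−k·τ}``.
* ``lognormal_peak`` — ``A·exp(−ln²(t/tc)/(2σ²))``, an asymmetric empirical
  peak with maximum ``A`` at ``t = tc``.
* ``gamma_variate`` — ``A·(t/tp)^α·e^{α(1−t/tp)}``, maximum ``A`` at
  ``t = tp``.

The summary statistics are the curve maximum (Emax), its time (Tmax, min) and
the area under the curve over the sampling window (AUC, unit × min). AUC is
analytic for the Bateman family and adaptive quadrature otherwise; a
model-free trapezoid AUC is always available as oracle and fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .enrichment import EnrichmentCurve

__all__ = [
    "DEFAULT_FAMILIES",
    "INTEGRATION_WINDOW_MIN",
    "PeakModel",
    "PeakFit",
    "bateman",
    "bateman_tmax",
    "bateman_auc",
    "lognormal_peak",
    "gamma_variate",
    "fit_peak_model",
    "auc_trapezoid",
    "summarize_fit",
]

DEFAULT_FAMILIES: tuple[str, ...] = ("bateman", "lognormal_peak", "gamma_variate")

#: Sampling window of the bolus studies: −15 min basal, last sample 300 min.
INTEGRATION_WINDOW_MIN: tuple[float, float] = (0.0, 300.0)

_RATE_EQUAL_TOL = 1e-9


# ---------------------------------------------------------------------------
# model functions


def bateman(
    t: np.ndarray, A: float, ka: float, ke: float, t0: float = 0.0
) -> np.ndarray:
    """Bateman curve; zero before the lag ``t0``; handles the ka = ke limit."""
    t = np.asarray(t, dtype=float)
    tau = np.where(t > t0, t - t0, 0.0)
    if abs(ka - ke) < _RATE_EQUAL_TOL * max(ka, ke):
        return A * tau * np.exp(-ka * tau)
    return A * (np.exp(-ke * tau) - np.exp(-ka * tau))


def bateman_tmax(ka: float, ke: float, t0: float = 0.0) -> float:
    """Closed-form time of the Bateman maximum: ``t0 + ln(ka/ke)/(ka−ke)``."""
    if abs(ka - ke) < _RATE_EQUAL_TOL * max(ka, ke):
        return t0 + 1.0 / ka
    return t0 + math.log(ka / ke) / (ka - ke)


def bateman_auc(
    A: float,
    ka: float,
    ke: float,
    t0: float = 0.0,
    window: tuple[float, float] = INTEGRATION_WINDOW_MIN,
) -> float:
    """Analytic Bateman AUC over the integration window."""
    lo, hi = window
    x0 = max(lo, t0) - t0
    x1 = max(hi, t0) - t0
    if abs(ka - ke) < _RATE_EQUAL_TOL * max(ka, ke):
        k = ka

        def antider(x: float) -> float:
            # ∫ τ e^{−kτ} dτ = −e^{−kτ}(τ/k + 1/k²)
            return -math.exp(-k * x) * (x / k + 1.0 / k**2)

    else:

        def antider(x: float) -> float:
            return -math.exp(-ke * x) / ke + math.exp(-ka * x) / ka

    return A * (antider(x1) - antider(x0))


def lognormal_peak(t: np.ndarray, A: float, tc: float, sigma: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = A * np.exp(-np.log(t[pos] / tc) ** 2 / (2.0 * sigma**2))
    return out


def gamma_variate(t: np.ndarray, A: float, tp: float, alpha: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tp
    # log x + 1 − x ≤ 0 for all x > 0; clamp rounding noise near x = 1
    out[pos] = A * np.exp(np.minimum(alpha * (np.log(x) + 1.0 - x), 0.0))
    return out


def _bateman_jac(t: np.ndarray, A: float, ka: float, ke: float, t0: float) -> np.ndarray:
    tau = np.where(t > t0, t - t0, 0.0)
    active = (t > t0).astype(float)
    if abs(ka - ke) < _RATE_EQUAL_TOL * max(ka, ke):
        ek = np.exp(-ka * tau)
        base = tau * ek
        return np.column_stack(
            [base, -A * tau * base, -A * tau * base * 0.0, -A * ek * (1 - ka * tau) * active]
        )
    eke, eka = np.exp(-ke * tau), np.exp(-ka * tau)
    return np.column_stack(
        [
            eke - eka,
            A * tau * eka,
            -A * tau * eke,
            A * (ke * eke - ka * eka) * active,
        ]
    )


def _lognormal_jac(t: np.ndarray, A: float, tc: float, sigma: float) -> np.ndarray:
    y = lognormal_peak(t, A, tc, sigma)
    u = np.where(t > 0, np.log(np.maximum(t, 1e-300) / tc), 0.0)
    return np.column_stack(
        [y / A, y * u / (sigma**2 * tc), y * u**2 / sigma**3]
    )


def _gamma_jac(t: np.ndarray, A: float, tp: float, alpha: float) -> np.ndarray:
    y = gamma_variate(t, A, tp, alpha)
    x = np.where(t > 0, t / tp, 1.0)
    lnx = np.where(t > 0, np.log(np.maximum(t, 1e-300) / tp), 0.0)
    return np.column_stack(
        [y / A, y * alpha * (x - 1.0) / tp, y * (lnx + 1.0 - x)]
    )


@dataclass(frozen=True)
class PeakModel:
    """A fitted peak family with its named parameters."""

    family: str
    params: dict[str, float]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return _FAMILY_FUNCS[self.family](t, **self.params)


@dataclass(frozen=True)
class PeakFit:
    """Fit result carrying the three kinetic summaries.

    ``converged`` is False for the empirical (model-free) fallback, in which
    case Emax/Tmax are the maximal observed point and AUC is the trapezoid.
    """

    model: PeakModel | None
    emax: float
    tmax_min: float
    auc: float
    unit: str
    aicc: float
    converged: bool
    rmse: float
    animal_id: str = ""
    analyte: str = ""
    flags: tuple[str, ...] = field(default=())


_FAMILY_FUNCS = {
    "bateman": bateman,
    "lognormal_peak": lognormal_peak,
    "gamma_variate": gamma_variate,
}
_FAMILY_PARAMS = {
    "bateman": ("A", "ka", "ke", "t0"),
    "lognormal_peak": ("A", "tc", "sigma"),
    "gamma_variate": ("A", "tp", "alpha"),
}
_FAMILY_JACS = {
    "bateman": _bateman_jac,
    "lognormal_peak": _lognormal_jac,
    "gamma_variate": _gamma_jac,
}
_FAMILY_ORDER = {f: i for i, f in enumerate(DEFAULT_FAMILIES)}


# ---------------------------------------------------------------------------
# trapezoid AUC (fallback and oracle)


def auc_trapezoid(
    times_min: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float] = INTEGRATION_WINDOW_MIN,
) -> float:
    """Composite-trapezoid AUC over the observed grid within the window.

    A zero at t = 0 is prepended when the first observation is later (the
    baseline-corrected pre-bolus enrichment is zero by construction).
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 1:
        raise ValueError("need at least one point")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    lo, hi = window
    m = (t >= lo) & (t <= hi)
    t, y = t[m], y[m]
    if t.size == 0:
        return 0.0
    if t[0] > lo:
        t = np.insert(t, 0, lo)
        y = np.insert(y, 0, 0.0)
    return float(np.trapezoid(y, t))


# ---------------------------------------------------------------------------
# fitting


def _initial_guesses(family: str, t: np.ndarray, y: np.ndarray) -> list[dict]:
    """Five deterministic moment-based starts per family."""
    i = int(np.argmax(y))
    emax_obs = max(float(y[i]), 1e-12)
    tmax_obs = float(t[i]) if t[i] > 0 else float(t[t > 0][0] if (t > 0).any() else 60.0)
    starts: list[dict] = []
    if family == "bateman":
        for g in (2.0, 5.0, 10.0, 25.0, 60.0):
            ke = math.log(g) / ((g - 1.0) * tmax_obs)
            ka = g * ke
            peak_unit = math.exp(-ke * tmax_obs) - math.exp(-ka * tmax_obs)
            starts.append(
                {"A": emax_obs / peak_unit, "ka": ka, "ke": ke, "t0": 0.0}
            )
    elif family == "lognormal_peak":
        for sigma in (0.3, 0.5, 0.8, 1.2, 1.6):
            starts.append({"A": emax_obs, "tc": tmax_obs, "sigma": sigma})
    elif family == "gamma_variate":
        for alpha in (1.0, 2.0, 4.0, 8.0, 16.0):
            starts.append({"A": emax_obs, "tp": tmax_obs, "alpha": alpha})
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown family {family!r}")
    return starts


def _expit(u: float | np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -40.0, 40.0)))


def _fit_family(
    family: str,
    t: np.ndarray,
    y: np.ndarray,
    max_iter: int,
    fit_tol: float,
) -> tuple[PeakModel, float] | None:
    """Levenberg–Marquardt on log-parameters (positivity by construction).

    The Bateman lag t0 is mapped through a scaled sigmoid onto
    [0, first post-bolus time) so the optimizer stays unconstrained.
    """
    names = _FAMILY_PARAMS[family]
    func = _FAMILY_FUNCS[family]
    jac = _FAMILY_JACS[family]
    has_t0 = family == "bateman"
    t0_hi = 0.999 * float(t[t > 0][0]) if (t > 0).any() else 1.0

    def to_params(u: np.ndarray) -> np.ndarray:
        p = np.exp(np.clip(u[:3], -60.0, 60.0))
        if has_t0:
            p = np.append(p, t0_hi * _expit(u[3]))
        return p

    def resid(u: np.ndarray) -> np.ndarray:
        return func(t, *to_params(u)) - y

    def jac_u(u: np.ndarray) -> np.ndarray:
        p = to_params(u)
        J = jac(t, *p)
        scale = p[:3].copy()
        if has_t0:
            s = _expit(u[3])
            scale = np.append(scale, t0_hi * s * (1.0 - s))
        return J * scale

    best: tuple[float, PeakModel] | None = None
    for start in _initial_guesses(family, t, y):
        x = np.array([start[n] for n in names], dtype=float)
        u0 = np.log(np.maximum(x[: 4 if not has_t0 else 3], 1e-12))
        if has_t0:
            u0 = np.append(u0, 0.0)  # start the lag mid-interval
        try:
            res = optimize.least_squares(
                resid,
                u0,
                jac=jac_u,
                method="lm",
                ftol=fit_tol,
                xtol=fit_tol,
                max_nfev=max_iter,
            )
        except Exception:
            continue
        p = to_params(res.x)
        if not np.all(np.isfinite(p)):
            continue
        ssr = float(2.0 * res.cost)
        if best is None or ssr < best[0] - 1e-15:
            best = (ssr, PeakModel(family, dict(zip(names, map(float, p)))))
    if best is None:
        return None
    return best[1], best[0]


def _aicc(ssr: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    ssr = max(ssr, 1e-300)
    aic = n * math.log(ssr / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / denom


def _model_summaries(
    model: PeakModel, window: tuple[float, float]
) -> tuple[float, float, float]:
    p = model.params
    if model.family == "bateman":
        tmax = bateman_tmax(p["ka"], p["ke"], p["t0"])
        emax = float(bateman(np.array([tmax]), **p)[0])
        auc = bateman_auc(p["A"], p["ka"], p["ke"], p["t0"], window)
    elif model.family == "lognormal_peak":
        tmax, emax = p["tc"], p["A"]
        auc = integrate.quad(
            lambda x: float(model(np.array([x]))[0]), window[0], window[1], limit=200
        )[0]
    else:
        tmax, emax = p["tp"], p["A"]
        auc = integrate.quad(
            lambda x: float(model(np.array([x]))[0]), window[0], window[1], limit=200
        )[0]
    return emax, tmax, float(auc)


def _empirical_fallback(
    curve: EnrichmentCurve,
    window: tuple[float, float],
    flags: tuple[str, ...],
) -> PeakFit:
    t, y = curve.post_bolus
    i = int(np.argmax(y))  # argmax returns the earliest index on plateaus
    return PeakFit(
        model=None,
        emax=float(y[i]),
        tmax_min=float(t[i]),
        auc=auc_trapezoid(t, y, window),
        unit=curve.unit,
        aicc=math.inf,
        converged=False,
        rmse=math.nan,
        animal_id=curve.animal_id,
        analyte=curve.analyte,
        flags=flags,
    )


def fit_peak_model(
    curve: EnrichmentCurve,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    window: tuple[float, float] = INTEGRATION_WINDOW_MIN,
    max_iter: int = 500,
    fit_tol: float = 1e-10,
) -> PeakFit:
    """Fit peak families to a curve and return the AICc-best summary.

    Each family is fitted by nonlinear least squares (Levenberg–Marquardt on
    log-parameters) from five deterministic moment-based starts; the winner
    has the lowest AICc, ties
    broken by fewer parameters then by family order. Emax and Tmax come from
    the winning model's closed forms; AUC is analytic (Bateman) or adaptive
    quadrature over the integration window.

    Falls back to the empirical summary (max point, earliest time of max,
    trapezoid AUC) with ``converged=False`` when no family converges, when
    ``families`` is empty, or when the curve has fewer than 5 post-bolus
    points or no positive value.
    """
    t, y = curve.post_bolus
    flags: list[str] = []
    if t.size < 5:
        flags.append("low_confidence")
    if t.size < 2 or not np.any(y > 0) or not families:
        if not np.any(y > 0):
            flags.append("no_positive_signal")
        return _empirical_fallback(curve, window, tuple(flags))
    if flags:
        return _empirical_fallback(curve, window, tuple(flags))

    # a fitted peak located far before the first observation (or past the
    # window) is pure extrapolation — such candidates are inadmissible
    tmax_lo = 0.5 * float(t[t > 0][0]) if (t > 0).any() else 0.0
    candidates: list[tuple[float, int, int, PeakModel, float]] = []
    for family in families:
        if family not in _FAMILY_FUNCS:
            raise ValueError(f"unknown peak family {family!r}")
        fitted = _fit_family(family, t, y, max_iter, fit_tol)
        if fitted is None:
            continue
        model, ssr = fitted
        p = model.params
        if family == "bateman":
            tmax_fit = bateman_tmax(p["ka"], p["ke"], p["t0"])
        else:
            tmax_fit = p["tc"] if family == "lognormal_peak" else p["tp"]
        if not (tmax_lo <= tmax_fit <= window[1]):
            continue
        aicc = _aicc(ssr, t.size, len(model.params))
        candidates.append(
            (aicc, len(model.params), _FAMILY_ORDER[family], model, ssr)
        )
    if not candidates:
        return _empirical_fallback(curve, window, ("fit_failed",))

    candidates.sort(key=lambda c: (round(c[0], 9), c[1], c[2]))
    aicc, _, _, model, ssr = candidates[0]
    emax, tmax, auc = _model_summaries(model, window)
    return PeakFit(
        model=model,
        emax=emax,
        tmax_min=tmax,
        auc=auc,
        unit=curve.unit,
        aicc=aicc,
        converged=True,
        rmse=math.sqrt(ssr / t.size),
        animal_id=curve.animal_id,
        analyte=curve.analyte,
        flags=tuple(flags),
    )


def summarize_fit(fit: PeakFit) -> dict:
    """Flat unit-carrying record of a fit (AUC in unit×min and unit×h)."""
    rec = {
        "animal_id": fit.animal_id,
        "analyte": fit.analyte,
        "family": fit.model.family if fit.model else "empirical",
        "Emax": fit.emax,
        "Emax_unit": fit.unit,
        "Tmax_min": fit.tmax_min,
        "AUC_unit_min": fit.auc,
        "AUC_unit_h": fit.auc / 60.0,
        "aicc": fit.aicc,
        "converged": fit.converged,
        "rmse": fit.rmse,
        "flags": ";".join(fit.flags),
    }
    if fit.model:
        for k, v in fit.model.params.items():
            rec[f"param_{k}"] = v
    return rec
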