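"""Design-level statistics of a 2×2 factorial animal study.

Covers the power/sample-size computation for the two main effects (Cohen's f
effect sizes on a noncentral-F power curve), the 1.5×IQR outlier screen
applied within factorial cells, and simple zootechnical indices (BMI,
ponderal index, average daily gain).

Group comparisons themselves (mixed models with litter random effects,
post-hoc tests) are out of scope: the pipeline emits tidy per-animal tables
that standard statistics tools consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DesignSpec",
    "OutlierRule",
    "power_2x2_main_effect",
    "required_sample_size_2x2",
    "flag_iqr_outliers",
    "body_indices",
    "average_daily_gain",
]


@dataclass(frozen=True)
class DesignSpec:
    """A balanced two-factor between-subjects design with target power."""

    f_a: float
    f_b: float
    alpha: float = 0.05
    power: float = 0.80
    levels_a: int = 2
    levels_b: int = 2

    def __post_init__(self) -> None:
        if self.f_a <= 0 or self.f_b <= 0:
            raise ValueError("effect sizes must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must be in (0, 1)")
        if self.levels_a < 2 or self.levels_b < 2:
            raise ValueError("each factor needs at least 2 levels")


@dataclass(frozen=True)
class OutlierRule:
    """Tukey fence rule: flag x outside [Q1 − m·IQR, Q3 + m·IQR]."""

    multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def power_2x2_main_effect(
    n_per_group: int, f: float, alpha: float = 0.05, levels: int = 2, n_cells: int = 4
) -> float:
    """Noncentral-F power of one main effect in a balanced factorial design.

    Numerator df = levels − 1; denominator df = N − n_cells (the cells model
    with interaction); noncentrality λ = f²·N with N the total sample size.
    """
    n_total = n_per_group * n_cells
    df1 = levels - 1
    df2 = n_total - n_cells
    if df2 <= 0:
        return 0.0
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(1.0 - stats.ncf.cdf(crit, df1, df2, f * f * n_total))


def required_sample_size_2x2(spec: DesignSpec, n_max: int = 10**6) -> int:
    """Smallest per-group n at which both main effects reach the target power.

    Iterates n upward independently for each effect and returns the larger
    requirement. Deterministic, closed-form power at each step.
    """
    n_cells = spec.levels_a * spec.levels_b
    required = []
    for f, levels in ((spec.f_a, spec.levels_a), (spec.f_b, spec.levels_b)):
        n = 2
        while power_2x2_main_effect(n, f, spec.alpha, levels, n_cells) < spec.power:
            n += 1
            if n > n_max:
                raise ValueError(f"target power unreachable within n ≤ {n_max}")
        required.append(n)
    return max(required)


def flag_iqr_outliers(
    values: np.ndarray,
    groups: np.ndarray | None = None,
    rule: OutlierRule = OutlierRule(),
    min_cell_size: int = 4,
) -> np.ndarray:
    """Flag values beyond the Tukey fences within each factorial cell.

    Quartiles use linear interpolation (type-7, the numpy default). Cells
    with fewer than ``min_cell_size`` values are skipped (no flags). Flags
    only — removal is a downstream user decision.
    """
    values = np.asarray(values, dtype=float)
    flags = np.zeros(values.shape, dtype=bool)
    if groups is None:
        groups = np.zeros(values.shape, dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        m = groups == g
        cell = values[m]
        if cell.size < min_cell_size:
            continue
        q1, q3 = np.percentile(cell, [25, 75])
        iqr = q3 - q1
        lo = q1 - rule.multiplier * iqr
        hi = q3 + rule.multiplier * iqr
        flags[m] = (cell < lo) | (cell > hi)
    return flags


def body_indices(bw_kg: float, crl_m: float) -> tuple[float, float]:
    """Body mass index (kg/m²) and ponderal index (kg/m³) from crown-rump length."""
    if crl_m <= 0:
        raise ValueError("crown-rump length must be positive")
    if bw_kg <= 0:
        raise ValueError("bodyweight must be positive")
    return bw_kg / crl_m**2, bw_kg / crl_m**3


def average_daily_gain(
    bw_start_kg: float, bw_end_kg: float, d_start: float, d_end: float
) -> float:
    """ADG in kg/d over an age window, e.g. days 1–16, 1–12 or 13–16."""
    if d_end <= d_start:
        raise ValueError("window must have positive length")
    return (bw_end_kg - bw_start_kg) / (d_end - d_start)
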