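"""Kinetic endpoints of the oral tracer bolus: Ra, ¹³C recovery, conversion.

Doses are given per kg bodyweight, so every quantity here is bodyweight
normalized. The three endpoints:

* Rate of appearance ``Ra = D / AUC`` — tracer dose D (mmol/kg) divided by the
  plasma tracer enrichment AUC expressed in mole-fraction-excess × h. Plasma
  AUCs arrive on the percent (MPE) scale, hence the explicit ÷100.
* ¹³C recovery in CO₂ (whole-body oxidation proxy): the amount of excess ¹³C
  exhaled, ``n(¹³C) = AUC(¹³CO₂)/100 × r(CO₂)``, as a percentage of the
  excess ¹³C in the tracer dose, normalized by the RBC→breath factor for
  the substrate. ``r(CO₂) = 48 mmol/(kg·h)`` for suckling piglets. A
  ``paper_literal`` mode multiplies additionally by the sampling period
  ``t`` (5 h), reproducing the source equation verbatim for audit; that form
  over-counts by the factor t and is not the default (see docs/methods.md).
* Gluconeogenic conversion: the percentage quotient of the plasma m+3 glucose
  AUC over the plasma m+5 glutamine AUC — glutamine carbon re-appearing in
  glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "NATURAL_ABUNDANCE_13C",
    "TracerDose",
    "GLN_TRACER",
    "GLC_TRACER",
    "RecoveryInput",
    "KineticResult",
    "dose_to_mmol",
    "tracer_excess_13c",
    "rate_of_appearance",
    "c13_recovery",
    "gluconeogenic_conversion",
]

#: Natural ¹³C abundance (atom fraction); basal plasma ¹³C reference.
NATURAL_ABUNDANCE_13C = 0.0111

_MASS_13C_MINUS_12C = 1.00336  # Da per substituted carbon


@dataclass(frozen=True)
class TracerDose:
    """An oral tracer dose with its unlabeled carrier.

    ``molar_mass_g_per_mol`` is the mass of the *labeled* species (each
    substituted ¹³C adds ≈1.00336 Da). The carrier is at natural abundance
    and therefore contributes no ¹³C excess over the basal plasma baseline.
    """

    compound: str
    tracer_mg_per_kg: float
    purity_atom_pct: float
    n_labeled: int
    molar_mass_g_per_mol: float
    carrier_g_per_kg: float
    natural_abundance: float = NATURAL_ABUNDANCE_13C

    def __post_init__(self) -> None:
        if self.tracer_mg_per_kg <= 0:
            raise ValueError("tracer dose must be positive")
        if not (90.0 < self.purity_atom_pct <= 100.0):
            raise ValueError("tracer purity must be in (90, 100] atom%")
        if self.n_labeled not in (5, 6):
            raise ValueError("n_labeled must be 5 (Gln) or 6 (Glc)")
        if self.molar_mass_g_per_mol <= 0:
            raise ValueError("molar mass must be positive")


#: [U-¹³C₅]glutamine, 10 mg/kg at 99.5 atom%, with 0.33 g/kg carrier Gln.
GLN_TRACER = TracerDose(
    compound="C13_5_Gln",
    tracer_mg_per_kg=10.0,
    purity_atom_pct=99.5,
    n_labeled=5,
    molar_mass_g_per_mol=146.14 + 5 * _MASS_13C_MINUS_12C,  # 151.16
    carrier_g_per_kg=0.33,
)

#: [U-¹³C₆]glucose, 10 mg/kg at 99 atom%, with 0.4 g/kg carrier Glc.
GLC_TRACER = TracerDose(
    compound="C13_6_Glc",
    tracer_mg_per_kg=10.0,
    purity_atom_pct=99.0,
    n_labeled=6,
    molar_mass_g_per_mol=180.16 + 6 * _MASS_13C_MINUS_12C,  # 186.18
    carrier_g_per_kg=0.4,
)


@dataclass(frozen=True)
class RecoveryInput:
    """Inputs to the ¹³C-recovery computation.

    ``auc_co2_ape_min`` is the RBC ¹³CO₂ enrichment AUC in APE × min.
    ``normalization`` is the RBC→breath correlation factor (0.90 for the
    glutamine tracer, 0.98 for glucose).
    """

    auc_co2_ape_min: float
    r_co2_mmol_kg_h: float = 48.0
    t_hours: float = 5.0
    normalization: float = 0.90
    mode: str = "dimensional"

    def __post_init__(self) -> None:
        if self.auc_co2_ape_min < 0:
            raise ValueError("AUC must be non-negative")
        if self.r_co2_mmol_kg_h <= 0 or self.t_hours <= 0:
            raise ValueError("r_co2 and t must be positive")
        if not (0.0 < self.normalization <= 1.0):
            raise ValueError("normalization factor must be in (0, 1]")
        if self.mode not in ("dimensional", "paper_literal"):
            raise ValueError("mode must be 'dimensional' or 'paper_literal'")


@dataclass(frozen=True)
class KineticResult:
    """Per-animal kinetic endpoints for one tracer study."""

    animal_id: str
    compound: str
    ra_mmol_kg_h: float | None = None
    rec_pct: float | None = None
    rec_mode: str = "dimensional"
    conversion_pct: float | None = None
    flags: tuple[str, ...] = ()


def dose_to_mmol(dose: TracerDose) -> float:
    """Tracer dose D in mmol per kg bodyweight: mg/kg ÷ (g/mol)."""
    return dose.tracer_mg_per_kg / dose.molar_mass_g_per_mol


def tracer_excess_13c(dose: TracerDose) -> float:
    """Excess ¹³C delivered by the tracer, mmol ¹³C per kg bodyweight.

    ``D × n_labeled × (purity − natural abundance)``. The carrier bolus is at
    natural abundance — identical to the basal plasma reference — and so
    contributes zero excess.
    """
    purity_frac = dose.purity_atom_pct / 100.0
    if purity_frac <= dose.natural_abundance:
        raise ValueError("tracer purity at or below natural abundance")
    return dose_to_mmol(dose) * dose.n_labeled * (purity_frac - dose.natural_abundance)


def rate_of_appearance(d_mmol_kg: float, auc_mpe_h: float) -> float:
    """Ra = D / AUC with AUC converted from MPE×h to mole-fraction-excess×h.

    MPE is percent-scale, hence ``Ra = D / (AUC/100)`` in mmol/(kg × h).
    """
    if auc_mpe_h <= 0:
        raise ValueError("Ra undefined for non-positive AUC")
    return d_mmol_kg / (auc_mpe_h / 100.0)


def c13_recovery(inp: RecoveryInput, excess_13c_dose_mmol_kg: float) -> float:
    """Percent of the dosed excess ¹³C recovered as ¹³CO₂.

    Dimensional mode (default)::

        n(¹³C in CO₂) = AUC(¹³CO₂)[APE×h]/100 × r(CO₂)        [mmol/kg]
        REC% = n(¹³C in CO₂) / n(¹³C in dose) × 100 / normalization

    ``paper_literal`` mode multiplies ``n`` additionally by the sampling
    period ``t_hours``, matching the source equation as printed; with the
    default t = 5 h it returns exactly 5× the dimensional value.
    """
    if excess_13c_dose_mmol_kg <= 0:
        raise ValueError("excess 13C dose must be positive")
    auc_ape_h = inp.auc_co2_ape_min / 60.0
    n_co2 = auc_ape_h / 100.0 * inp.r_co2_mmol_kg_h
    if inp.mode == "paper_literal":
        n_co2 *= inp.t_hours
    return n_co2 / excess_13c_dose_mmol_kg * 100.0 / inp.normalization


def gluconeogenic_conversion(auc_m3_glc: float, auc_m5_gln: float) -> float:
    """Conversion % = 100 × AUC(m+3 Glc) / AUC(m+5 Gln).

    Both AUCs must share a time unit (min or h); the units cancel.
    """
    if auc_m5_gln <= 0:
        raise ValueError("conversion undefined for non-positive glutamine AUC")
    if auc_m3_glc < 0:
        raise ValueError("numerator AUC must be non-negative")
    return 100.0 * auc_m3_glc / auc_m5_gln
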