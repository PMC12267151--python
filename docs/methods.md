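# Methods

This note records the modeling choices behind pigtracer: what is computed,
under which assumptions, which defaults matter, and where the approach has
known limits.

## Study conditions

The package models an oral-bolus tracer protocol in suckling piglets: a
−15 min basal blood sample, bolus at t = 0, and samples at 30, 60, 90, 120,
150, 180, 210, 240 and 300 min. Two tracer studies are represented —
[U-¹³C₅]glutamine (10 mg/kg BW, 99.5 atom%, with 0.33 g/kg carrier Gln) and
[U-¹³C₆]glucose (10 mg/kg BW, 99 atom%, with 0.4 g/kg carrier Glc) — plus
sugar-probe tests (lactulose 0.75 g/kg, mannitol 0.3 g/kg, xylose 0.4 g/kg).
The cohort is a 2×2 factorial (birthweight class LBW 0.8–1.2 kg / NBW
1.4–1.8 kg × supplementation Gln / water) with cells of 12/12/11/11 animals
drawn as littermate pairs from 18 litters.

## Enrichment calibration

Isotopologue ratios are converted to MPE by ordinary least squares with
intercept, regressing the known standard enrichments (0–2.5 MPE) on the
measured ratios. The intercept absorbs the natural-abundance offset of the
ratio; whether the instrument calibration should be forced through the
origin is an open choice and OLS-with-intercept is the conventional one for
multi-point MS calibrations. Predictions outside the standard range are
flagged `extrapolated` rather than rejected (observed plasma peaks,
≈0.5–1.2 MPE, lie inside the range); predictions more than one residual SD
below zero are clamped to 0 and flagged. Note that with six standards the
residual SD carries only 4 degrees of freedom, so a ±3·SE interval around
the fitted slope covers the truth with probability ≈0.96 (Student t₄), not
the ≈0.997 of a known-σ interval.

δ¹³C values are converted to atom fraction with the VPDB ratio
R = 0.0111802 (overridable); APE is the difference to the animal's basal
sample, ×100. Baseline correction subtracts the −15 min value from every
point; it is idempotent, and negative corrected values are kept (they are
unbiased noise around zero) but flagged.

## Peak fitting

Bolus curves are fitted with three families that together span the shapes
an oral dose produces:

* **Bateman** (first-order absorption–elimination), parameters A, k_a, k_e
  and lag t₀; T_max = t₀ + ln(k_a/k_e)/(k_a−k_e) in closed form, equal-rate
  limit A·τ·e^(−kτ) handled explicitly; AUC analytic.
* **log-normal peak** A·exp(−ln²(t/t_c)/(2σ²)) — peak A at t_c.
* **gamma variate** A·(t/t_p)^α·e^(α(1−t/t_p)) — peak A at t_p.

Each family is fitted by Levenberg–Marquardt on log-parameters (positivity
by construction; the Bateman lag maps through a scaled sigmoid onto
[0, first sample)) from five deterministic moment-based starts, with
analytic Jacobians, a 1e−10 tolerance on the sum of squares and at most 500
iterations per start. The winner is the lowest AICc (k = n_params + 1 for
the residual variance), ties broken by fewer parameters, then by family
order.

**Admissibility guard.** With no sample before 30 min, the area under the
rising limb is constrained only by the family shape, and fits that place the
peak well before the first observation are pure extrapolation — on sharp
curves (T_max ≈ 30 min) such fits occur for nearly half of noisy replicates
and inflate the AUC by several percent. A candidate fit is therefore
inadmissible when its analytic T_max falls below half the first post-bolus
sampling time or beyond the integration window. With the guard, the
model-based AUC is unbiased to within a few tenths of a percent across the
study's curve shapes at 5% measurement noise.

If no family converges (or none is admissible), the empirical summary is
used: maximal observed point, earliest time of the maximum on plateaus, and
trapezoid AUC, flagged `converged = false`.

AUC is integrated over the fixed window 0–300 min (the sampling period);
the extrapolated tail beyond 300 min is excluded. The model-based AUC is
the default; the trapezoid AUC (with an implied zero at t = 0, the
post-baseline-correction convention) is always available. For peaks at or
after the second sample the two agree within a few percent; for a peak at
the first sample the trapezoid's triangular head deterministically
undershoots by ≈5%.

Curve fitting operates on percent-scale units (MPE/APE) or concentrations;
conversions to mole-fraction happen only in the kinetics layer.

## Kinetic endpoints

* **Ra = D/(AUC/100)** in mmol/(kg·h), D = dose(mg/kg)/M(labeled species)
  (151.16 g/mol for ¹³C₅-Gln, 186.18 for ¹³C₆-Glc — the labeled masses, ≈3%
  above the unlabeled ones), AUC in MPE×h. The ÷100 reflects MPE being
  percent-scale; with these doses and observed AUCs of ≈1–3 MPE×h it is the
  only convention that produces rates of the observed magnitude
  (≈2–7 mmol/(kg·h)).
* **¹³C recovery**: the dimensionally consistent form
  n(¹³C) = (AUC in APE×h)/100 × r(CO₂) is the default; r(CO₂) =
  48 mmol/(kg·h) is taken as a constant for suckling piglets. The
  `paper_literal` mode multiplies additionally by the sampling period
  t = 5 h, reproducing the published equation verbatim for audit; that form
  over-counts by exactly the factor t (its output is 5× the dimensional
  value) and its absolute scale should not be compared across protocols
  with different sampling periods. Neither mode is claimed to reproduce the
  study's printed recovery percentages, which cannot be reconstructed from
  the printed group means and the stated r(CO₂) basis alone. Excess ¹³C in
  the dose is D × n_labeled × (purity − 0.0111); the carrier is at natural
  abundance — the same level as the basal plasma reference — and
  contributes zero excess.
* **Gluconeogenic conversion** is the plain AUC quotient (m+3 glucose over
  m+5 glutamine, ×100); units cancel.

## Sugar-probe tests

Concentrations below the LOQ (lactulose 0.03, mannitol 0.06, xylose
0.01 mmol/L) are flagged and stored at LOQ/2 — the standard simple
substitution for sparse censoring; flags are preserved so users can drop
instead. Values exactly at the LOQ are retained. The substitution is
downward only for readings in [LOQ/2, LOQ); a reading below LOQ/2 is raised
to LOQ/2. An all-censored series (the expected lactulose outcome when the
intestinal barrier is intact) yields `all_below_loq` and no summary; the
lactulose:mannitol ratio is reported only when both AUCs are quantifiable.
Summaries reuse the tracer peak-fit machinery unchanged, so sugars and
tracers share one E_max/T_max/AUC implementation.

## Design statistics

Power for each main effect of the balanced 2×2 design uses the noncentral F
distribution with numerator df = levels − 1, denominator df = N − ab (the
cells model with interaction) and noncentrality λ = f²·N. Under this
convention the study effect sizes (f = 0.5 birthweight, f = 0.45
supplementation, α = 0.05, power 0.80) require 9 and 11 animals per group
respectively — 11 overall, the supplementation effect binding. The
denominator-df convention of published power tools varies; this one is the
natural match for a two-factor-with-interaction analysis and is verified
against a 20,000-replicate simulated-ANOVA oracle in the tests.

Outliers are flagged (never removed) outside Q1 − 1.5·IQR / Q3 + 1.5·IQR
within each factorial cell, quartiles by linear interpolation (type 7);
cells with fewer than four values are skipped. BMI = BW/CRL²,
PI = BW/CRL³, ADG = ΔBW/Δdays over the requested age window.

## Synthetic cohort

The generator emulates the study, not the animal: curves are Bateman by
construction, with group-level targets defaulting to the study's printed
group means. For plasma tracers the group T_max and the AUC implied by the
group Ra (AUC = D/Ra on the percent scale) are matched exactly; the shape
ratio k_a/k_e is then solved so the peak height matches the group E_max —
the AUC/E_max quotient is monotone in the ratio, so a root exists whenever
the target lies in the family's reachable band. The printed ¹³C₆-glucose
E_max/T_max/Ra triple is narrower than any Bateman curve allows, so there
the near-symmetric limit is used, AUC stays exact and the realized E_max
(recorded in the truth table) is lower than printed. CO₂ curves are delayed
Bateman shapes (lag 15 min Gln, 30 min Glc) matching the printed CO₂ AUCs;
the true recovery is derived from them through the dimensional relation.
The m+3 glucose AUC is the printed conversion percentage applied to the
glutamine AUC. Mannitol has no printed kinetic table; plausible defaults
(E_max ≈ 0.3 mmol/L at 90–100 min) are fixed once. Lactulose is generated
below its LOQ, mirroring the intact-barrier outcome.

Per-animal parameters multiply the cell-level curve by a log-normal
amplitude (animal CV 0.20 plus a litter intercept of SD 0.10 on the log
scale — the order of between-animal spread the printed SEMs imply) and a
log-normal time dilation (CV 0.10) that moves T_max but preserves shape.
The drift terms make the draws mean-preserving on the Ra = D/AUC scale, so
truth-table cell means are unbiased for the configured group Ra (verified
by direct Monte Carlo; E_max and AUC cell means correspondingly inflate by
≈e^(σ²)). Measurement noise is multiplicative log-normal,
×exp(σZ − σ²/2) with σ² = ln(1 + CV²), mean-preserving on the enrichment
scale, default CV 0.05; the basal sample gets absolute noise (SD
0.002 percent units). Draw order is fixed (cells → animals → analytes), so
one seed reproduces byte-identical tables.

What the generator does **not** emulate: mechanistic CO₂ kinetics
(the delayed Bateman is a shape, not a convolution through bicarbonate
pools), milk-intake tracer dilution (available as a hook, off by default),
assay drift, missing samples, or non-Bateman curve shapes. Passing recovery
tests therefore demonstrate that the estimation pipeline is correct and
unbiased under the stated noise model — not that real curves are Bateman.

## Numerical choices

* Integration window fixed at [0, 300] min; trapezoid prepends an implied
  zero at t = 0.
* AICc ties broken toward fewer parameters, then family order
  (bateman < lognormal_peak < gamma_variate).
* Empirical T_max on plateaus: earliest time of the maximum.
* Gamma-variate exponent clamped at 0 (its true value is ≤ 0; floating
  rounding near x = 1 would otherwise overflow at large α).
* The Bateman equal-rate branch activates at |k_a − k_e| < 1e−9·max(k).
* Pipeline CSVs are written with `%.10g` floats and fixed line endings;
  manifests record sha256 checksums of every output, and deterministic
  stages re-run to identical checksums.

## Problem sizes

The default simulated cohort is the study-sized 46 animals. The parameter-
recovery analysis in the acceptance tests uses 250 animals per cell (1000
total) with the two plasma-tracer analytes, enough to resolve sub-percent
estimator bias while keeping a full run in the order of two minutes.

## Known limitations

* With no sample before 30 min, the rising-limb area is model-dependent;
  the admissibility guard removes the resulting bias but individual sharp
  curves still carry ≈4–5% AUC uncertainty at 5% noise.
* The published recovery equation is implemented in both a dimensional and
  a literal form; reconciling their absolute scale with the study's printed
  recovery percentages is not possible from group-level data (the r(CO₂)
  basis — per kg, per metabolic weight, or time-averaged — is
  undetermined).
* Group comparisons (mixed models with litter random effects, post-hoc
  tests) are deliberately out of scope; the pipeline emits tidy per-animal
  tables for the statistics tool of choice.
* Whether published AUC values of this protocol family are model-based or
  trapezoidal is generally unstated; both are computed, the model-based
  value is the default, and the choice is recorded in the run manifest.
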