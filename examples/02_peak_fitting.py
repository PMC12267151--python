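"""Fit peak models to a bolus enrichment curve and extract Emax/Tmax/AUC.

Simulates one noisy glutamine-tracer curve on the study's 10-point sampling
schedule and fits the three peak families (Bateman, log-normal, gamma
variate), reporting the AICc-selected summary and the model-free trapezoid
AUC for comparison.
"""

import numpy as np

from pigtracer import auc_trapezoid, fit_peak_model, summarize_fit
from pigtracer.simulate import (
    SCHEDULE_MIN,
    bateman_from_targets,
    simulate_enrichment_curve,
)

# curve shaped to the reference group summaries: Emax 1.18 MPE, Tmax 31.3 min,
# AUC 148.1 MPE*min (the AUC a group rate of appearance of 2.68 mmol/(kg*h)
# implies for the glutamine tracer dose)
A, ka, ke = bateman_from_targets(emax=1.18, tmax=31.3, auc=148.1)
rng = np.random.default_rng(7)
curve = simulate_enrichment_curve(
    {"A": A, "ka": ka, "ke": ke}, SCHEDULE_MIN, noise_cv=0.05, rng=rng,
    animal_id="pig-1", analyte="Gln_m5",
)

fit = fit_peak_model(curve)
rec = summarize_fit(fit)
print(f"winning family : {rec['family']}")
print(f"Emax           : {rec['Emax']:.3f} MPE   (true 1.18)")
print(f"Tmax           : {rec['Tmax_min']:.1f} min   (true 31.3)")
print(f"AUC (model)    : {rec['AUC_unit_min']:.1f} MPE*min (true 148.1)")
print(f"AUC (trapezoid): {auc_trapezoid(*curve.post_bolus):.1f} MPE*min")
# Emax/Tmax describe the height and timing of the absorption peak; the AUC
# feeds the rate-of-appearance computation. The trapezoid slightly
# undershoots sharp peaks because nothing is sampled before 30 min.
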