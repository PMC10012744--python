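"""Pool per-cohort hazard ratios of a median-split prognostic marker.

Each training cohort contributes a univariable Cox hazard ratio (high vs
low marker) with a 95% CI. The CI is back-converted to the standard
error of the log HR and the cohorts are combined by inverse-variance
fixed-effect meta-analysis. The pooled HR and its precision are what the
scoring model turns into a signature weight, w = (1 - HR) / SE.
"""

import math

from ticscore import StudyEffect, compute_weight, pool_fixed, se_from_ci

# (HR, CI low, CI high) of the high-vs-low split in four cohorts
cohorts = [(0.41, 0.17, 0.99), (0.31, 0.17, 0.55),
           (0.31, 0.16, 0.58), (0.33, 0.18, 0.59)]

studies = [
    StudyEffect(f"cohort{i}", math.log(hr), se_from_ci(hr, lo, hi))
    for i, (hr, lo, hi) in enumerate(cohorts)
]
meta = pool_fixed(studies, signature_name="example_signature")
lo, hi = meta.ci95

print(f"pooled HR = {meta.pooled_hr:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"p = {meta.p:.2e}, Q = {meta.q:.2f}, I^2 = {meta.i2:.2f}")
print(f"weight w = (1 - HR)/SE = {compute_weight(meta):.3f}")
# HR < 1 in every cohort, so the pooled effect is protective and the
# resulting weight is positive: high enrichment raises the score.
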