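"""Full derivation loop on a synthetic multi-cohort study.

Simulates 4 training cohorts plus one held-out cohort in which 8 of 20
gene-set activities drive the recurrence hazard (|b| = 0.8, alternating
sign), derives the score — ssGSEA per signature, per-cohort Cox on the
median split, fixed-effect pooling, P < 0.05 selection, w = (1 - HR)/SE
— and evaluates it on the held-out cohort.
"""

from ticscore import (
    SimulationConfig,
    build_tics_model,
    recovery_report,
    simulate_study,
)

cfg = SimulationConfig(seed=20230314)
study = simulate_study(cfg)
model = build_tics_model(study.training, study.gene_sets)

print("selected signatures and weights:")
for name, w in zip(model.signatures, model.weights):
    b = study.truth.effects[name]
    print(f"  {name}: w = {w:+.2f}   (true hazard coefficient b = {b:+.1f})")

rep = recovery_report(model, study.truth, study.validation[0], study.gene_sets)
print(f"\nplanted recovered: {rep['frac_planted_selected']:.0%}, "
      f"null false positives: {rep['frac_null_selected']:.0%}")
print(f"held-out high-vs-low HR = {rep['held_out_hr_high_vs_low']:.2f}")
print(f"held-out C-index = {rep['held_out_c_index']:.3f}, "
      f"3-year AUC = {rep['held_out_auc']:.3f}")
# Protective signatures (b < 0) should get positive weights; HR < 1 and
# C-index > 0.5 on the held-out cohort mean the score generalizes.
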