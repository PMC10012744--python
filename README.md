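# ticscore

Tumor immune contexture scoring for recurrence prediction in prostate
cancer — a reusable implementation of the derivation and evaluation of a
weighted immune-signature score (the tumor immune contexture score,
TICS) from multi-cohort transcriptome data.

## Who this is for

Researchers deriving or validating prognostic gene-signature scores from
bulk expression cohorts with right-censored time-to-event outcomes
(e.g. biochemical recurrence-free survival after radical
prostatectomy), and anyone who needs the individual building blocks:
single-sample GSEA, per-cohort Cox effects of a median-split marker,
inverse-variance meta-analysis, and an IPCW/concordance-based survival
evaluation suite.

## The method

Given gene-set signatures *S₁…S₉₂* and a collection of training cohorts
with expression and recurrence follow-up:

1. **ssGSEA** — for each sample, genes are z-scored across the cohort
   and ranked; the enrichment score of signature *Sᵢ* is the integral of
   the difference between the rank-weighted in-set ECDF (weights
   *rᵅ*, *r = N − position + 1*, α = 0.25 by default) and the uniform
   out-of-set ECDF.
2. **Per-cohort effects** — each signature's enrichment is dichotomized
   at the cohort median and a univariable Cox model of the high-vs-low
   indicator gives a log hazard ratio with standard error.
3. **Meta-analysis** — cohort effects are pooled by inverse-variance
   fixed-effect meta-analysis on the log-HR scale; signatures with
   pooled *P* < 0.05 are selected.
4. **The score** — each selected signature receives the weight

   *wᵢ = (1 − HRᵢ) / SE(log HRᵢ)*

   and a sample's score is TICS = Σᵢ *wᵢ* · ESᵢ. Protective signatures
   (HR < 1) push the score up, adverse ones down, each scaled by the
   precision of its pooled effect.
5. **Evaluation** — Kaplan–Meier/log-rank of the median split,
   uni/multivariable Cox, Harrell's C and optimism-corrected Somers'
   *D*ₓᵧ, IPCW time-dependent AUC with paired-bootstrap model
   comparison, calibration by risk bins, Youden cut-off selection, and
   VIF/condition-number multicollinearity checks.

A synthetic multi-cohort generator (latent signature activities driving
a Weibull proportional-hazards recurrence process, with per-cohort
location shifts and right censoring) makes the whole pipeline testable
end to end without any external download.

## Worked example

`examples/02_simulate_train_evaluate.py` simulates 4 training cohorts
plus one held-out cohort (n = 150 each, 2000 genes, 20 signatures, 8
with planted hazard effects |b| = 0.8), derives the model and evaluates
it:

```
selected signatures and weights:
  SIG00: w = +4.50   (true hazard coefficient b = -0.8)
  SIG01: w = -9.25   (true hazard coefficient b = +0.8)
  ...
planted recovered: 100%, null false positives: 0%
held-out high-vs-low HR = 0.10
held-out C-index = 0.855, 3-year AUC = 0.925
```

Every planted protective signature (b < 0) receives a positive weight
and every adverse one a negative weight; the held-out hazard ratio far
below 1 and C-index well above 0.5 show the derived score generalizes
to a cohort it never saw. The other examples show the meta-pooling
arithmetic on published per-cohort hazard ratios
(`01_meta_pooling.py`) and the survival evaluation toolbox
(`03_survival_toolbox.py`).

## Command line

The same stages are available as a thin CLI:

```bash
tics simulate --seed 7 --out sim/
tics train    --config train.yaml --out model/
tics score    --expr cohort.tsv --gmt sets.gmt --model model/model.json --out scores/
tics evaluate --scores scores/scores.tsv --clinical clinical.tsv --out eval/
tics report   --model model/model.json --truth sim/truth.json \
              --expr sim/SYN04_expr.tsv --clinical sim/SYN04_clinical.tsv \
              --gmt sim/gene_sets.gmt --out report/
```

Each output directory contains a `run.json` provenance block (resolved
config, hash, seed).

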