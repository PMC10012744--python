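# Methods

## The model

The score is a linear combination of single-sample gene-set enrichment
scores, TICS = Σᵢ wᵢ·ESᵢ, with weights derived from a meta-analysis of
per-cohort prognostic effects. The derivation assumes (i) expression is
log-scale and pre-normalized within each cohort; (ii) recurrence times
follow a proportional-hazards model given signature activity; (iii)
cohorts are independent and their effects estimate a common log hazard
ratio (fixed-effect pooling). Nothing is shared across cohorts except
the gene-set definitions: z-scoring, the median split, and later the
risk-group cut-off are all computed within each cohort, which is what
makes the score usable across microarray and RNA-seq platforms without
batch correction.

## ssGSEA variant

For one sample, genes are sorted by (z-scored) expression descending,
ties broken by lexical gene identifier so results do not depend on input
order. With rank weight r = N − position + 1 and exponent α, the
in-set running ECDF is P_in(i) = Σ_{j≤i, j∈S} r_jᵅ / Σ_{j∈S} r_jᵅ and
the out-set ECDF is the uniform count fraction; the enrichment score is
the sum over all positions of P_in − P_out (the "integral" statistic,
not the max-deviation KS form). Choices:

- **α = 0.25** (default). The weighting exponent is a free parameter of
  the method; 0.25 is its canonical default. α = 0 gives a pure rank
  statistic, invariant under strictly increasing transforms; both are
  exposed via `SsgseaParams`.
- **No cross-sample rescaling of ES.** Each sample's score depends only
  on its own ranking, so a sample's TICS does not change when other
  samples enter or leave the cohort.
- **Gene z-scoring uses the population sd** (divide by n). The choice
  is immaterial to ranks within a sample; it is fixed and documented so
  scores are bit-reproducible. Zero-variance genes become all-zero rows.
- **Values equal to the median go to "low"** in every dichotomization —
  one fixed, testable tie rule.
- Signatures are intersected with the measured gene universe; sets
  retaining fewer than `min_size = 3` genes are dropped (an enrichment
  score over one or two genes is dominated by single-gene noise).

## Meta-analytic weights

Per cohort and signature, a univariable Cox model (Efron ties) of the
median-split indicator (high = 1) yields a log HR and SE. Cohorts pool
by inverse variance on the log-HR scale: weights 1/SE², pooled SE =
(Σw)^(-1/2); Cochran's Q and I² are reported. Fixed-effect pooling is
the default because re-deriving the published pooled values from the
published per-cohort values reproduces them (training 0.328
[0.237–0.454] vs printed 0.32 [0.24–0.45]; validation 0.452 vs 0.45);
DerSimonian–Laird random effects is available as an option. Signature
selection keeps pooled P < 0.05 with no multiplicity correction
(mirroring the original selection rule; a BH flag could be added but is
deliberately not the default), optionally also requiring a consistent
HR direction in every cohort. The weight is w = (1 − HR)/SE where SE is
the standard error of the *pooled log* hazard ratio — the quantity
meta-analysis natively produces; the alternative reading (SE on the
natural-HR scale) would only rescale weights monotonically. Signatures
with fewer than two successfully fitted cohorts are excluded.

Printed CIs are back-converted to SEs as (ln hi − ln lo)/3.92, using
the conventional 1.96 to match how such intervals are printed.

## Survival statistics

Kaplan–Meier, log-rank and Cox fits stand on lifelines (Newton
precision tightened to 1e-9 so the analytically solvable 3-subject
instance reproduces β = ln 2 ⁄ 2 to ~1e-10); Harrell's C comes from
scikit-survival (ties in score count 1/2). Composed here:

- **IPCW time-dependent AUC** (cumulative cases / dynamic controls):
  cases are events at or before the horizon weighted 1/G(T−), controls
  are subjects event-free past it weighted 1/G(τ), with G the
  Kaplan–Meier estimate of the censoring distribution. With no
  censoring this is exactly the Mann–Whitney AUC; the tests verify
  equality with scikit-survival's independent estimator to 1e-10.
- **Model comparison**: paired bootstrap over subjects of the AUC
  difference of two markers, two-sided p from the normal approximation
  of the bootstrap distribution; a degenerate (zero-variance) bootstrap
  gives p = 1.
- **Optimism-corrected Dxy**: Dxy = 2C − 1; optimism is the mean over B
  bootstrap refits of (bootstrap Dxy − that fit's Dxy on the original
  data); resamples with zero events are redrawn and logged.
- **Calibration**: subjects binned by quantiles of the linear
  predictor; predicted = mean Breslow-baseline model survival at the
  horizon per bin; observed = per-bin Kaplan–Meier. Empty bins reduce
  the bin count with a log message.
- **Youden cut-off**: exhaustive search over midpoints of adjacent
  unique scores; ties in J break toward higher sensitivity.
- Cox orientation conventions: larger `score` = higher risk everywhere;
  the TICS is protective, so evaluations negate it. Separation is
  detected as |log HR| > 10 after convergence and raised as an error
  naming the covariate; constant or exactly collinear columns are
  rejected before fitting.

## Synthetic study conditions

The generator plants a latent activity z_k ~ N(0,1) per signature and
sample; member genes are loading·z_k + cohort offset + noise, and the
hazard is Weibull-PH with linear predictor Σ b_k z_k. Defaults define
the reference study: 4 training + 1 held-out cohorts of n = 150, 2000
genes, 20 signatures of 50 genes, 8 planted effects of |b| = 0.8 with
alternating sign. Values the study description leaves open were fixed
once at field-plausible levels: loading 1.0 and noise sd 1.0 (per-gene
signal-to-noise 1, attenuated further by the 50-gene averaging inside
ssGSEA); cohort location-shift sd 0.5 (platform differences comparable
to half the biological noise); Weibull shape 1.5 (non-exponential but
proportional hazards, so the Cox model is correctly specified while the
KM machinery sees a non-constant hazard); baseline scale 0.002/month^1.5
(median baseline recurrence near 48 months); administrative horizon 120
months plus an independent exponential censor whose default rate
(0.0132/month) was set by the bundled numerical calibration to give
roughly half the subjects censored, typical of biochemical-recurrence
series. Optional clinical covariates (age, PSA, Gleason, pT/pN/margin)
are drawn weakly correlated with the true risk so that subgroup and
added-value analyses have realistic confounding.

What the generator does **not** emulate: probe-level microarray noise,
count-based RNA-seq sampling, gene–gene correlation beyond the planted
factors, non-proportional hazards, and informative censoring. Passing
recovery tests therefore demonstrates the pipeline's statistical
machinery is correct and well calibrated under its own assumptions —
not that the published biological findings replicate; those require the
original accession-controlled cohorts.

## Problem sizes and determinism

Tests run on scaled-down studies (3–4 cohorts of 60–150 samples,
200–2000 genes) chosen so the whole suite completes in well under half
an hour; the reference recovery run uses the full study conditions
above. All randomness flows through `numpy.random.default_rng` seeded
from the config (`[seed, cohort_index]` per cohort), so every artifact
is bit-reproducible; bootstrap routines take explicit seeds and record
them in provenance blocks.

## Known limitations

- Gene identifiers are matched by upper-cased symbol only; no ID
  mapping across annotation versions.
- The Cox implementation excludes time-varying covariates, competing
  risks, frailty and penalization.
- The within-cohort median cut-off means individual group labels depend
  on cohort composition (scores themselves do not).
- Fixed-effect pooling assumes a common true effect across platforms;
  heterogeneity is reported (Q, I²) but does not switch the default.
- The IPCW AUC assumes censoring independent of the marker.
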