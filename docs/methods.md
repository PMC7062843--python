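# Methods

## Model and procedure

The package estimates a per-subject severity score y (an integer on the
1–10 calibrated-severity scale) from resting-state functional connectivity
and quantifies which connections the estimate relies on.

**Severity scores.** The proxy calibrated severity score is a pure lookup:
a calibration table partitions (module, age band, raw ADOS-total range)
cells into severity levels 1–10, and a subject's score is the level of the
unique cell containing their (module, age, ADOS social+communication
total).  Age bands and raw ranges are treated as *closed* intervals; the
convention is exercised at every boundary in the tests.  Whether ages
should be floored before matching is unspecified in the source procedure;
the module takes age as given.  Subjects matching no cell raise a
structured "uncalibratable" error and are listed, never imputed or silently
dropped.  The published calibration is not redistributable, so the package
ships a format validator and a synthetic stand-in table
(`data/synthetic_calibration_table.csv`, clearly labelled synthetic); real
analyses plug in the published CSV.

**Edge features.** Per subject, ROI mean time series (timepoints × n ROIs)
are pairwise Pearson-correlated; the correlation is mapped through Fisher's
z = arctanh(r); the strict upper triangle is vectorized in a fixed
canonical order (row-major, ascending atlas indices), giving
n(n−1)/2 features — 6670 for the 116-ROI AAL atlas.  Zero-variance ROI
series are a hard error naming the ROI (real preprocessing precludes them;
silent NaNs would poison downstream selection).  |r| is clipped to
1 − 1e−7 before arctanh so degenerate perfectly-correlated inputs stay
finite; clipping is logged.

**Selection.** Within each training set, edge j gets
r_j = corr(x_j, y) and a two-sided p-value from
t = r√(n−2)/√(1−r²) on n−2 df.  Edges with p strictly below the threshold
survive ("fell below" ⇒ strict).  Two-sidedness matches the presence of
both positively and negatively correlated informative edges; no
multiple-testing correction is applied by design — the filter is a
hyperparameter-controlled screen, not an inference.  Constant edges get
(r = 0, p = 1) to keep shapes stable.

**Threshold choice.** The default threshold is 0.0023, the operating point
of the final protocol.  Two grid searches are provided: stage 1 runs a
nested leave-one-out loop on the training set over 100 candidates
(0.0005–0.05, step 0.0005) minimizing inner-prediction MSE; stage 2
evaluates 11 refined candidates (0.002–0.003, step 0.0001) by running the
outer CV directly and maximizing prediction R.  Ties break toward the
smaller threshold (fewer features, more conservative).  Stage 1 is
quadratic in the sample size and off by default.

**Regression.** Linear ε-SVR: minimize ½‖w‖² + C Σ(ξ+ξ*) under the ε-tube
constraints, with C = 1 and ε = 0.1 (the conventional libsvm defaults; ε
is exposed since only C is pinned by convention).  The solve delegates to
the libsvm SMO backend via scikit-learn; the package's contract is
objective-level and is enforced in tests by independent oracles:
10,000-point random-search non-improvability, KKT multiplier
reconstruction (|β| ≤ C, stationarity w = −Σβᵢxᵢ, Σβᵢ = 0 within 1e−3),
and a brute-force scan of the bias for the zero-design case.  Features are
not standardized by default — Fisher-z edges share a scale — but an opt-in
flag exists, with the scaler folded back so the model remains affine in
raw features.

**Evaluation.** Leave-one-out CV is the primary scheme; seeded repeated
k-fold (default 10×10) is the robustness check.  Selection is recomputed
inside every fold from training subjects only; a no-leakage audit
(recomputing each stored mask from the stored training indices) is part of
the test suite.  Metrics are Pearson R between cross-validated estimates
and observed scores (averaged over repeats for k-fold), MAE and MSE in
score units.  Constant predictions leave R undefined (NaN) with MAE/MSE
still reported.

**Contributions.** Edge contribution = fraction of folds selecting the
edge; for repeated k-fold the denominator is the total fold count across
repeats, keeping the [0, 1] scale comparable with leave-one-out.  ROI
contribution = sum of incident edge contributions, min–max normalized over
ROIs incident to ≥ 1 selected edge (ROIs with none are excluded, matching
how such tables are reported); if all included ROIs tie, the tied nonzero
value maps to 1.0.  Division summaries split total contribution into
percentage shares.  Two schemes partition edges (intra/inter-network;
hemisphere classes: inter-hemispheric, left, right, cerebellar — an edge
with a cerebellum or vermis endpoint is cerebellar regardless of sides).
Two schemes are endpoint-keyed (six networks; six lobes, with prefrontal
folded into Frontal and vermis into Cerebellum): an edge spanning two
divisions gives half its contribution to each, a within-division edge
gives all of it.  The half-weight rule is one consistent reading of
"contribution of the connectivities whose ROIs are within the division";
it is the choice that makes every scheme sum to 100%.  The
positive/negative split uses the sign of each edge's *full-sample*
correlation with the scores — a post-hoc descriptive, not a
cross-validated quantity, and labelled as such in the outputs.

## Synthetic cohorts: what they emulate and what they do not

Each subject draws an integer severity s uniformly on 1–10 (the calibrated
scale the real pipeline regresses).  A planted edge (i, j) has target
correlation r(s) = base + slope·(s − 5.5), realized exactly by a
shared-latent construction (x_i = √ρ·g + √(1−ρ)·e_i, ρ = |r|, sign on one
channel), which preserves unit marginal variance.  Planted edges are
ROI-disjoint so every target is exactly realizable; correlations are
planted on the raw series (r → z is monotone, so sign and ordering claims
transfer to z).  Optional measurement noise is added and rescaled to keep
unit variance, attenuating planted correlations by 1/(1+σ²).

Defaults are the package's study conditions: 116 ROIs, 200 timepoints,
150 subjects, ten planted edges (five positive, five negative slopes) with
slope 0.0085 and base correlation 0.1.  The slope was set by a priori
power analysis so the population correlation between a planted edge's
z-value and severity is ≈ 0.33 — the top of the 0.23–0.33 band in which
edge–severity correlations of *selected* edges concentrate in this kind of
analysis.  Planted edges emulate detectable structure, and ≈ 0.33 is the
level the pipeline's own p < 0.0023 filter recovers with ≈ 0.9 power at
n ≈ 150; lower in the band, fold-stability recovery is intrinsically
unstable and a recovery test would measure sampling luck rather than
correctness.

The generator makes no attempt at scanner physics, head motion,
hemodynamic autocorrelation, site effects, or spatially structured noise;
non-planted ROIs are independent white noise.  Passing tests therefore
demonstrate that the pipeline's statistics behave as designed under the
model's assumptions (exchangeable subjects, temporally white unit-variance
series, linear edge–severity relation); they do not certify performance on
real fMRI, where preprocessing, autocorrelation (which inflates the
effective z noise above 1/√(T−3)) and site heterogeneity all matter.
Phenotype tables are generated to be consistent with the synthetic
calibration table, optionally inverted from given severities so that
calibration recovers them exactly — this makes the demo exercise the
scoring stage end to end.

## Numerical choices

- Fisher clip 1 − 1e−7; p-values clipped into (0, 1]; correlation values
  clipped to [−1, 1] after floating-point accumulation.
- Strict p < threshold; grid-search ties → smallest threshold.
- SVR tolerance 1e−6 (tighter than the solver default so KKT checks at
  1e−3–1e−4 are meaningful); slack monotonicity in C holds to ~1e−3.
- Degenerate cases are errors, not NaNs: constant y, zero-variance ROI,
  empty ROI label, empty selected feature set, all-zero contributions.
- The pipeline analyzes exactly the edge matrix it serializes (written,
  then re-read), so a rerun from the written file is bit-identical to the
  original run; manifests carry SHA-256 hashes of all outputs.
- Repeated k-fold derives all fold assignments from one seeded splitter;
  the pipeline master seed also seeds cohort generation and phenotype
  synthesis (offset by one to decouple the streams).

## Known limitations

- The null distribution of cross-validated R after fold-wise selection is
  wide: on zero-signal cohorts with n = 100 and threshold 0.0023 the
  acceptance batch measures sd(R) ≈ 0.3 (the same spread occurs with pure
  iid Gaussian features).  Leave-one-out folds share nearly all subjects,
  so the ~15 spurious edges surviving the filter are almost identical
  across folds and selection variance is only partially removed.  Single
  null-cohort R values of ±0.3–0.5 are therefore expected behaviour of the
  statistic, not evidence of signal; judgments about real data should rest
  on permutation tests or the repeated k-fold scheme, not on one LOOCV R.
- The six-network and lobe assignment of the packaged AAL-116 annotation
  is a best-effort reconstruction: entries appearing in published
  edge/ROI tables for this analysis are pinned exactly (including
  counter-intuitive ones, e.g. the precentral gyri carrying a DMN label);
  the remainder follow conventional network membership.  Users should
  override the CSV when a definitive assignment is available.
- Stage-1 threshold search is O(n²) SVR fits per candidate grid and is
  practical only for small cohorts; the default protocol (fixed threshold
  or stage-2 grid) matches how the final operating point is chosen.
- The labeled-volume path handles one volume per call; it exists to
  validate ROI-mean extraction, not as a batch imaging front end.
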