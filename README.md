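# connsev

Connectome-based estimation of autism symptom severity from resting-state
functional connectivity, with fold-stability analysis of which connections
drive the estimate.

## The problem

Clinical severity in autism spectrum disorder is usually expressed as a
calibrated severity score (CSS, 1–10) derived from ADOS assessments.  Given
resting-state fMRI for a cohort of patients, the question is whether
whole-brain functional connectivity carries enough information to estimate
that score per subject — and, if so, *which* connections carry it.

`connsev` implements the full analysis as a reusable, tested library for
researchers working with ROI time series (e.g. AAL-parcellated rs-fMRI):

1. **Severity scoring** — the proxy CSS is looked up from a pluggable
   Gotham-style calibration table by matching the ADOS social+communication
   total, the subject's age, and the ADOS module.
2. **Edge features** — ROI time series (116 AAL regions by default) are
   pairwise Pearson-correlated, variance-stabilized with Fisher's
   r-to-z transform (z = arctanh r), and the strict upper triangle is
   vectorized into 116·115/2 = **6670** edge features per subject.
3. **Feature selection, nested in CV** — inside every cross-validation
   fold, each edge is scored against the observed scores by Pearson
   correlation; edges with two-sided p < threshold (default **0.0023**)
   survive.  Grid procedures for choosing the threshold are included:
   a nested-LOOCV stage over 0.0005–0.05 (step 0.0005, minimum MSE) and a
   refined stage over 0.002–0.003 (step 0.0001, maximum cross-validated R).
4. **Regression** — linear ε-SVR (C = 1, ε = 0.1) on the selected edges:
   f(x) = wᵀx + b minimizing ½‖w‖² + C Σ(ξᵢ + ξᵢ\*) subject to the ε-tube
   constraints.
5. **Evaluation and contributions** — leave-one-out or repeated 10-fold CV
   reports R, MAE and MSE; each edge's **contribution** is the fraction of
   folds that selected it; ROI contributions are min–max-normalized sums of
   incident edge contributions; division summaries give percentage shares
   by intra/inter-network, six functional networks (DMN, EAN, SMN, Visual,
   SBN, Cerebel), hemisphere class, and six brain lobes, split by the sign
   of each edge's correlation with severity.
6. **Synthetic cohorts** — a generator plants edges whose correlation
   varies linearly with a known severity score via a shared-latent
   construction, so selection, regression and contribution analysis can be
   validated against ground truth without any imaging data.

## Worked example

Run the self-contained demo (synthetic 150-subject cohort, 116 ROIs, 200
timepoints, ten planted edges, full pipeline including calibration):

```bash
connsev demo --out demo_run --seed 2
```

which prints the leave-one-out metrics

```json
{
  "MAE": 1.9709329594410223,
  "MSE": 5.383380550237084,
  "R": 0.5542419482085393,
  "R_p": 1.8697816137776256e-13
}
```

i.e. the cross-validated estimates correlate R = 0.55 with the observed
scores (p ≈ 2e-13) and miss by 1.97 severity points on average, with ~23
edges selected per fold.  `demo_run/edges.csv` starts with the most stable
edges, e.g.

```
edge_id,roi1,name1,...,full_sample_r,contribution,sign,intra_network,hemisphere_class
3,1,PreCG.L,...,0.341353,1.000000,positive,True,LH
1725,17,ROL.L,...,0.307780,1.000000,positive,False,LH
```

— edge 3 is the planted pair (1, 5) and 1725 the planted pair (17, 23),
selected in 100% of folds (`contribution` = 1.00).  `demo_run/` also holds
per-ROI contributions (`rois.csv`), division shares
(`divisions_*.csv`, each summing to 100%), per-fold selections, the edge
matrix, and a `manifest.json` with config, seeds and output hashes that
makes the run bit-exactly reproducible (`connsev report --run-dir demo_run`
verifies this).

The same stages are available programmatically:

```python
from connsev import synthetic, features, evaluation

spec = synthetic.study_spec(n_subjects=150, seed=2)
subjects, truth = synthetic.generate_cohort(spec)
X = features.cohort_edge_matrix([s.timeseries for s in subjects])
y = truth.true_scores.astype(float)
run = evaluation.run_cv(X, y, threshold=0.0023)
print(evaluation.cv_metrics(run, y))
contrib = evaluation.edge_contributions(run)
```

Other subcommands: `simulate` (write a synthetic cohort), `calibrate`
(score a phenotype CSV), `features` (time series → edge matrix),
`fit-evaluate` (run from a YAML config).

The packaged calibration table is a synthetic stand-in with the correct
format; for real analyses supply the published lookup via
`--table`/`calibration_path`.  The packaged 116-ROI annotation
(hemisphere, lobe, six-network membership) can likewise be overridden with
`annotation_path`.

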