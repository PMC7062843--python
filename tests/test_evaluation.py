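"""Tests for cross-validation, metrics and contribution analyses."""

import numpy as np
import pandas as pd
import pytest

from connsev import evaluation, features
from connsev.evaluation import (
    CvRun,
    CvScheme,
    FoldResult,
    all_division_summaries,
    audit_no_leakage,
    cv_metrics,
    division_summary,
    edge_contributions,
    metrics,
    roi_contributions,
    report_tables,
    run_cv,
)
from connsev.svr import SvrConfig, SvrModel


def make_run(masks, n_edges, scheme=CvScheme("loocv")):
    """Assemble a CvRun from explicit per-fold selection masks."""
    dummy = SvrModel(w=np.zeros(1), b=0.0, config=SvrConfig())
    folds = [
        FoldResult(f, 0, np.array([0]), np.array([0]),
                   np.asarray(m, dtype=bool), 0.0023, dummy)
        for f, m in enumerate(masks)
    ]
    return CvRun(scheme=scheme, n_subjects=len(masks), n_edges=n_edges,
                 threshold=0.0023, predictions=np.zeros(len(masks)), folds=folds)


class TestRunCv:
    def test_loocv_fold_structure(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        run = run_cv(X, y, CvScheme("loocv"))
        assert run.n_folds == len(y)
        tested = np.concatenate([f.test_idx for f in run.folds])
        assert sorted(tested) == list(range(len(y)))
        assert all(len(f.test_idx) == 1 for f in run.folds)

    def test_kfold_repeats_structure(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        run = run_cv(X, y, CvScheme("kfold", k=10, repeats=10, seed=1))
        assert run.n_folds == 100
        counts = np.zeros(len(y), dtype=int)
        for f in run.folds:
            counts[f.test_idx] += 1
        assert np.all(counts == 10)  # each subject tested once per repeat

    def test_selection_ignores_held_out_score(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        run = run_cv(X, y, CvScheme("loocv"))
        y2 = y.copy()
        y2[5] += 4  # perturb one subject's observed score
        run2 = run_cv(X, y2, CvScheme("loocv"))
        fold = next(f for f in run.folds if f.test_idx[0] == 5)
        fold2 = next(f for f in run2.folds if f.test_idx[0] == 5)
        assert np.array_equal(fold.mask, fold2.mask)

    def test_no_leakage_audit(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        run = run_cv(X, y, CvScheme("loocv"))
        assert audit_no_leakage(run, X, y)

    def test_empty_selection_aborts_with_diagnostics(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        with pytest.raises(evaluation.FoldSelectionError, match="fold 0"):
            run_cv(X, y, CvScheme("loocv"), threshold=1e-30)

    def test_reproducible_from_seed(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        a = run_cv(X, y, CvScheme("kfold", k=5, repeats=2, seed=42))
        b = run_cv(X, y, CvScheme("kfold", k=5, repeats=2, seed=42))
        assert np.array_equal(a.predictions, b.predictions)
        for fa, fb in zip(a.folds, b.folds):
            assert np.array_equal(fa.mask, fb.mask)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.arange(10, dtype=float)
        m = metrics(y, y)
        assert m["R"] == pytest.approx(1.0)
        assert m["MAE"] == 0.0 and m["MSE"] == 0.0

    def test_constant_shift(self):
        y = np.arange(10, dtype=float)
        m = metrics(y + 1, y)
        assert m["R"] == pytest.approx(1.0)
        assert m["MAE"] == pytest.approx(1.0)
        assert m["MSE"] == pytest.approx(1.0)

    def test_constant_predictions_undefined_r_valid_mae(self):
        y = np.arange(10, dtype=float)
        m = metrics(np.full(10, 4.5), y)
        assert np.isnan(m["R"])
        assert m["MAE"] == pytest.approx(2.5)

    def test_kfold_metrics_average_over_repeats(self, small_cohort_Xy):
        X, y, _ = small_cohort_Xy
        run = run_cv(X, y, CvScheme("kfold", k=5, repeats=3, seed=0))
        m = cv_metrics(run, y)
        per_rep = [metrics(run.predictions[r], y)["MAE"] for r in range(3)]
        assert m["MAE"] == pytest.approx(np.mean(per_rep))


class TestEdgeContributions:
    def test_ratios(self):
        # edge 0 selected in all 4 folds, edge 1 never, edge 2 in 3 of 4
        masks = [[1, 0, 1], [1, 0, 1], [1, 0, 1], [1, 0, 0]]
        c = edge_contributions(make_run(masks, 3))
        assert c.tolist() == [1.0, 0.0, 0.75]

    def test_fraction_of_100_folds(self):
        masks = [[1]] * 87 + [[0]] * 13
        c = edge_contributions(make_run(masks, 1))
        assert c[0] == pytest.approx(0.87)


class TestRoiContributions:
    def test_single_edge_degenerate_normalization(self):
        # one selected edge (1,2) with contribution c: both ROIs tie -> 1.0
        pair_index = features.canonical_pairs(4)
        contribs = np.zeros(len(pair_index))
        contribs[0] = 0.6  # edge (1,2)
        rc = roi_contributions(contribs, pair_index, 4)
        assert sorted(rc.index) == [1, 2]
        assert np.allclose(rc.values, 1.0)

    def test_star_pattern_minmax(self):
        # hub ROI 1 incident to three unit-contribution edges, leaves to one
        pair_index = features.canonical_pairs(4)
        contribs = np.zeros(len(pair_index))
        for j in (2, 3, 4):
            contribs[features.edge_id(1, j, 4)] = 1.0
        rc = roi_contributions(contribs, pair_index, 4)
        assert rc[1] == pytest.approx(1.0)   # raw 3 -> max
        assert rc[2] == rc[3] == rc[4] == pytest.approx(0.0)  # raw 1 -> min

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            roi_contributions(np.zeros(6), features.canonical_pairs(4), 4)


@pytest.fixture(scope="module")
def toy_edge_ann(annotation):
    return features.annotate_edges(features.canonical_pairs(116), annotation)


class TestDivisionSummary:
    def test_all_intra_network(self, toy_edge_ann):
        contribs = np.zeros(len(toy_edge_ann))
        eid = features.edge_id(79, 80, 116)  # HES.L-HES.R, intra-SMN
        contribs[eid] = 1.0
        signs = np.full(len(contribs), -1)
        df = division_summary(contribs, signs, toy_edge_ann, "intra_inter")
        intra = df.set_index("division").loc["intra-network"]
        assert intra["share_pct"] == pytest.approx(100.0)
        assert intra["negative_pct"] == pytest.approx(100.0)

    def test_two_edges_sixty_forty(self, toy_edge_ann):
        contribs = np.zeros(len(toy_edge_ann))
        contribs[features.edge_id(79, 80, 116)] = 0.6   # intra-network
        contribs[features.edge_id(23, 57, 116)] = 0.4   # inter-network
        signs = np.ones(len(contribs))
        df = division_summary(contribs, signs, toy_edge_ann, "intra_inter")
        shares = df.set_index("division")["share_pct"]
        assert shares["intra-network"] == pytest.approx(60.0)
        assert shares["inter-network"] == pytest.approx(40.0)

    def test_endpoint_half_weight_attribution(self, toy_edge_ann):
        # one inter-network DMN-SMN edge: half its contribution to each
        contribs = np.zeros(len(toy_edge_ann))
        contribs[features.edge_id(23, 57, 116)] = 0.8
        signs = np.ones(len(contribs))
        df = division_summary(contribs, signs, toy_edge_ann, "network")
        shares = df.set_index("division")["share_pct"]
        assert shares["DMN"] == pytest.approx(50.0)
        assert shares["SMN"] == pytest.approx(50.0)

    @pytest.mark.parametrize("scheme", evaluation.DIVISION_SCHEMES)
    def test_shares_sum_to_100_and_sign_split_consistent(self, toy_edge_ann, scheme):
        rng = np.random.default_rng(0)
        contribs = np.zeros(len(toy_edge_ann))
        sel = rng.choice(len(contribs), size=40, replace=False)
        contribs[sel] = rng.uniform(0.1, 1.0, size=40)
        signs = rng.choice([-1, 1], size=len(contribs))
        df = division_summary(contribs, signs, toy_edge_ann, scheme)
        assert df["share_pct"].sum() == pytest.approx(100.0, abs=0.01)
        assert np.allclose(df["positive_pct"] + df["negative_pct"], df["share_pct"])

    def test_invariant_to_edge_order(self, toy_edge_ann):
        rng = np.random.default_rng(1)
        contribs = np.zeros(len(toy_edge_ann))
        sel = rng.choice(len(contribs), size=20, replace=False)
        contribs[sel] = rng.uniform(0.1, 1, size=20)
        signs = rng.choice([-1, 1], size=len(contribs))
        base = division_summary(contribs, signs, toy_edge_ann, "network")
        perm = rng.permutation(len(contribs))
        ann_perm = toy_edge_ann.iloc[perm].reset_index(drop=True)
        other = division_summary(contribs[perm], signs[perm], ann_perm, "network")
        pd.testing.assert_frame_equal(base, other)

    def test_unknown_scheme(self, toy_edge_ann):
        with pytest.raises(ValueError, match="unknown division scheme"):
            division_summary(np.ones(len(toy_edge_ann)), np.ones(len(toy_edge_ann)),
                             toy_edge_ann, "voxel")


@pytest.fixture(scope="module")
def study_run():
    from connsev import synthetic
    spec = synthetic.study_spec(40, seed=21, n_timepoints=150)
    subjects, truth = synthetic.generate_cohort(spec)
    X = features.cohort_edge_matrix([s.timeseries for s in subjects])
    y = truth.true_scores.astype(float)
    run = run_cv(X, y, CvScheme("loocv"), threshold=0.01)
    return run, X, y


class TestReportTables:
    def test_deterministic_and_complete(self, study_run, annotation, tmp_path):
        run, X, y = study_run
        e1, r1 = report_tables(run, X, y, annotation)
        e2, r2 = report_tables(run, X, y, annotation)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        e1.to_csv(p1, index=False)
        e2.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()
        contribs = edge_contributions(run)
        assert len(e1) == int((contribs > 0).sum())
        assert e1["edge_id"].is_unique

    def test_column_contract(self, study_run, annotation):
        e, r = report_tables(*study_run, annotation)
        assert list(e.columns) == [
            "edge_id", "roi1", "name1", "lobe1", "network1",
            "roi2", "name2", "lobe2", "network2",
            "full_sample_r", "contribution", "sign",
            "intra_network", "hemisphere_class",
        ]
        assert list(r.columns) == ["roi_index", "name", "hemisphere", "lobe",
                                   "network", "contribution"]
        assert r["contribution"].iloc[0] == pytest.approx(1.0)

    def test_sorted_by_sign_then_contribution(self, study_run, annotation):
        e, _ = report_tables(*study_run, annotation)
        sign_order = {"positive": 0, "negative": 1}
        keys = [(sign_order[s], -c) for s, c in zip(e["sign"], e["contribution"])]
        assert keys == sorted(keys)


def test_loocv_vs_kfold_contribution_consistency(small_cohort_Xy):
    """Edge stability ranks agree between leave-one-out and 10-fold x 10."""
    from scipy.stats import spearmanr
    X, y, _ = small_cohort_Xy
    c_loo = edge_contributions(run_cv(X, y, CvScheme("loocv")))
    c_kf = edge_contributions(run_cv(X, y, CvScheme("kfold", k=10, repeats=10, seed=3)))
    ever = (c_loo > 0) | (c_kf > 0)
    rho = spearmanr(c_loo[ever], c_kf[ever]).statistic
    assert rho > 0.8
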