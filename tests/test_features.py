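"""Tests for edge-feature construction: ROI means, Pearson, Fisher z,
canonical vectorization and edge annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connsev import features
from connsev.features import (
    DegenerateSeriesError,
    annotate_edges,
    canonical_pairs,
    edge_id,
    fisher_z,
    load_annotation,
    n_edges,
    pearson_matrix,
    roi_mean_timeseries,
    unvectorize,
    vectorize_upper,
)


def brute_force_pearson(ts):
    """Textbook covariance/sd formula, independent of np.corrcoef."""
    T, R = ts.shape
    out = np.empty((R, R))
    for a in range(R):
        for b in range(R):
            xa, xb = ts[:, a] - ts[:, a].mean(), ts[:, b] - ts[:, b].mean()
            out[a, b] = (xa * xb).sum() / np.sqrt((xa**2).sum() * (xb**2).sum())
    return out


class TestRoiMeans:
    def test_hand_computed_two_voxel_mean(self):
        # voxel series (1, 3) and (3, 5) -> ROI mean (2, 4)
        vol = np.zeros((1, 3, 1, 2))
        vol[0, 0, 0] = [1, 3]
        vol[0, 1, 0] = [3, 5]
        labels = np.array([[[1], [1], [0]]])
        out = roi_mean_timeseries(vol, labels, 1)
        assert np.array_equal(out[:, 0], [2.0, 4.0])

    def test_single_voxel_roi_is_identity(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((30, 4))
        from connsev.synthetic import generate_labeled_volume
        vol, labels = generate_labeled_volume(4, 1, ts)
        assert np.allclose(roi_mean_timeseries(vol, labels, 4), ts)

    def test_empty_roi_error_lists_roi(self):
        vol = np.zeros((1, 2, 1, 5))
        labels = np.array([[[1], [1]]])
        with pytest.raises(ValueError, match=r"\[2\]"):
            roi_mean_timeseries(vol, labels, 2)


class TestPearson:
    def test_self_correlation_is_one(self):
        ts = np.random.default_rng(1).standard_normal((50, 3))
        assert np.allclose(np.diag(pearson_matrix(ts)), 1.0)

    def test_anticorrelated_column(self):
        ts = np.random.default_rng(2).standard_normal((50, 2))
        ts[:, 1] = -ts[:, 0]
        assert pearson_matrix(ts)[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            T = int(rng.integers(5, 40))
            R = int(rng.integers(2, 6))
            ts = rng.standard_normal((T, R))
            assert np.abs(pearson_matrix(ts) - brute_force_pearson(ts)).max() < 1e-12

    def test_zero_variance_column_error_names_roi(self):
        ts = np.random.default_rng(4).standard_normal((20, 3))
        ts[:, 1] = 2.5
        with pytest.raises(DegenerateSeriesError, match=r"\[2\]"):
            pearson_matrix(ts)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson_matrix(np.ones((2, 3)))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_matches_log_form_oracle(self):
        # 0.5 * ln((1+r)/(1-r)) evaluated at r = 0.5
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.999))
    @settings(deadline=None, max_examples=50)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-14)

    def test_tanh_round_trip_on_dense_grid(self):
        z = np.linspace(-5, 5, 2001)
        assert np.abs(fisher_z(np.tanh(z)) - z).max() < 1e-10

    def test_perfect_correlation_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_strictly_increasing(self):
        r = np.linspace(-0.99, 0.99, 500)
        assert np.all(np.diff(fisher_z(r)) > 0)


class TestVectorize:
    def test_116_rois_yield_6670_edges(self):
        m = unvectorize(np.arange(n_edges(116), dtype=float), 116)
        assert vectorize_upper(m).shape == (6670,)

    def test_three_rois_canonical_order(self):
        m = np.array([[0, 12, 13], [12, 0, 23], [13, 23, 0]], dtype=float)
        assert vectorize_upper(m).tolist() == [12, 13, 23]
        assert canonical_pairs(3).tolist() == [[1, 2], [1, 3], [2, 3]]

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        assert np.array_equal(unvectorize(vectorize_upper(m), 10), m)

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_upper(m)

    @pytest.mark.parametrize("n", [2, 3, 10, 116])
    def test_edge_count_identity(self, n):
        assert len(canonical_pairs(n)) == n * (n - 1) // 2

    def test_edge_id_bijection_at_116(self):
        pairs = canonical_pairs(116)
        ids = [edge_id(i, j, 116) for i, j in pairs]
        assert ids == list(range(6670))


class TestAnnotation:
    def test_packaged_annotation_valid(self, annotation):
        assert len(annotation) == 116
        assert set(annotation["network"]) == set(features.NETWORKS)
        vermis = annotation[annotation["hemisphere"] == "none"]
        assert (vermis["lobe"] == "Vermis").all()

    def test_duplicate_roi_rejected(self, annotation, tmp_path):
        bad = annotation.copy()
        bad.loc[1, "roi_index"] = 1
        path = tmp_path / "ann.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="roi_index"):
            load_annotation(path)

    def test_heschl_pair_intra_network_inter_hemispheric(self, annotation):
        # HES.L(79) - HES.R(80): both SMN, opposite hemispheres
        edges = annotate_edges(canonical_pairs(116), annotation)
        e = edges[edges["edge_id"] == edge_id(79, 80, 116)].iloc[0]
        assert e["name1"] == "HES.L" and e["name2"] == "HES.R"
        assert e["intra_network"] and e["network1"] == "SMN"
        assert e["hemisphere_class"] == "inter-hemispheric"

    def test_sfgmed_pocg_inter_network_left_hemisphere(self, annotation):
        # SFGmed.L(23) - PoCG.L(57): DMN vs SMN, both left
        edges = annotate_edges(canonical_pairs(116), annotation)
        e = edges[edges["edge_id"] == edge_id(23, 57, 116)].iloc[0]
        assert e["name1"] == "SFGmed.L" and e["name2"] == "PoCG.L"
        assert not e["intra_network"]
        assert {e["network1"], e["network2"]} == {"DMN", "SMN"}
        assert e["hemisphere_class"] == "LH"

    def test_vermis_edge_is_cerebellar(self, annotation):
        edges = annotate_edges(canonical_pairs(116), annotation)
        e = edges[edges["edge_id"] == edge_id(1, 112, 116)].iloc[0]
        assert e["hemisphere_class"] == "cerebellar"

    def test_missing_roi_rejected(self, annotation):
        with pytest.raises(ValueError, match="missing ROI"):
            annotate_edges(np.array([[1, 200]]), annotation)


def test_edge_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    X = rng.standard_normal((4, n_edges(5)))
    features.write_edge_matrix(tmp_path / "edges.tsv", X, ["a", "b", "c", "d"])
    ids, X2, pairs = features.read_edge_matrix(tmp_path / "edges.tsv")
    assert ids == ["a", "b", "c", "d"]
    assert np.allclose(X, X2)
    assert np.array_equal(pairs, canonical_pairs(5))
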