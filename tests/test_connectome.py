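import numpy as np
import pandas as pd
import pytest

from fcstrat.connectome import (
    EdgeIndex,
    FCDataset,
    ROITimeSeries,
    build_design,
    default_roi_labels,
    devectorize,
    fc_from_timeseries,
    fisher_z,
    pearson_fc,
    read_fc_table,
    residualize,
    standardize_dataset,
    standardize_subject,
    vectorize_upper,
    write_fc_table,
)
from fcstrat.simulate import generate_timeseries_from_cov


class TestEdgeIndex:
    def test_94_rois_give_4371_edges(self):
        idx = EdgeIndex(tuple(default_roi_labels(94)))
        assert idx.n_edges == 4371
        assert idx.roi_labels[0] == "Precentral_L"

    def test_three_rois_order(self):
        idx = EdgeIndex(("A", "B", "C"))
        assert idx.pairs == ((0, 1), (0, 2), (1, 2))
        assert idx.edge_labels == ["A--B", "A--C", "B--C"]

    def test_position_is_bijective(self):
        idx = EdgeIndex(tuple(default_roi_labels(10)))
        positions = [idx.position(i, j) for i, j in idx.pairs]
        assert positions == list(range(idx.n_edges))
        assert idx.position(3, 1) == idx.position(1, 3)

    def test_label_round_trip(self):
        idx = EdgeIndex(("x", "y", "z", "w"))
        assert EdgeIndex.from_edge_labels(idx.edge_labels).roi_labels == idx.roi_labels


class TestPearsonFisher:
    def test_duplicated_and_negated_columns(self, rng):
        base = rng.normal(size=50)
        ts = ROITimeSeries(
            np.column_stack([base, base, -base + 1, rng.normal(size=50)]),
            ("a", "b", "c", "d"),
        )
        c = pearson_fc(ts)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        assert np.allclose(c, c.T)
        assert np.all(np.diag(c) == 1.0)

    def test_constant_column_names_roi(self, rng):
        ts = ROITimeSeries(
            np.column_stack([rng.normal(size=20), np.full(20, 3.0)]),
            ("ok", "flat"),
        )
        with pytest.raises(ValueError, match="flat"):
            pearson_fc(ts)

    def test_known_correlation_recovered(self):
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        ts = generate_timeseries_from_cov(cov, 10_000, seed=5)
        r = np.corrcoef(ts, rowvar=False)[0, 1]
        assert r == pytest.approx(0.6, abs=0.03)  # Fisher-z SE ~ 1/sqrt(T-3)

    def test_fisher_z_values(self):
        assert fisher_z(0.0) == 0.0
        # brute force: 0.5 * ln((1 + r) / (1 - r))
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        r = np.linspace(-0.9, 0.9, 7)
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_fisher_z_rejects_unit_correlation(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestVectorize:
    def test_lengths(self):
        idx94 = EdgeIndex(tuple(default_roi_labels(94)))
        assert vectorize_upper(np.eye(94), idx94).shape == (4371,)
        idx3 = EdgeIndex(("a", "b", "c"))
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        assert list(vectorize_upper(m, idx3)) == [1.0, 2.0, 3.0]

    def test_round_trip(self, rng):
        idx = EdgeIndex(tuple(default_roi_labels(8)))
        vec = rng.normal(size=idx.n_edges)
        mat = devectorize(vec, idx)
        assert np.allclose(vectorize_upper(mat, idx), vec)

    def test_dimension_mismatch(self):
        idx = EdgeIndex(("a", "b", "c"))
        with pytest.raises(ValueError):
            vectorize_upper(np.eye(4), idx)


class TestStandardize:
    def test_population_sd_values(self):
        out = standardize_subject(np.array([1.0, 2.0, 3.0]))
        assert out == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_mean_zero_and_affine_invariance(self, rng):
        v = rng.normal(size=100)
        out = standardize_subject(v)
        assert abs(out.mean()) < 1e-10
        assert out.std() == pytest.approx(1.0)
        assert np.allclose(standardize_subject(3.5 * v - 2.0), out)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            standardize_subject(np.ones(5))

    def test_stage_transitions_forward_only(self, rng):
        idx = EdgeIndex(("a", "b", "c"))
        data = FCDataset(rng.normal(size=(4, 3)), idx, list("wxyz"),
                         stage="fisher_z")
        std = standardize_dataset(data)
        assert std.stage == "standardized"
        with pytest.raises(ValueError, match="stage"):
            standardize_dataset(std)  # cannot go backwards

    def test_per_edge_mode(self, rng):
        idx = EdgeIndex(("a", "b", "c"))
        data = FCDataset(rng.normal(size=(20, 3)), idx,
                         [f"s{i}" for i in range(20)], stage="fisher_z")
        out = standardize_dataset(data, mode="per_edge")
        assert np.allclose(out.matrix.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(out.matrix.std(axis=0), 1, atol=1e-10)


class TestResidualize:
    @staticmethod
    def _dataset(rng, n=60, n_roi=6):
        idx = EdgeIndex(tuple(default_roi_labels(n_roi)))
        cov = pd.DataFrame({
            "age": rng.uniform(6, 30, n),
            "sex": rng.choice(["male", "female"], n),
            "full_iq": rng.normal(100, 15, n),
            "mean_fd": rng.uniform(0.05, 0.4, n),
            "site": rng.choice(["s1", "s2", "s3"], n),
        })
        data = FCDataset(rng.normal(size=(n, idx.n_edges)), idx,
                         [f"s{i}" for i in range(n)], stage="fisher_z")
        return standardize_dataset(data), cov

    def test_residuals_orthogonal_to_design(self, rng):
        data, cov = self._dataset(rng)
        res = residualize(data, cov)
        X, _ = build_design(cov)
        for j in range(X.shape[1]):
            c = np.corrcoef(X[:, j], res.matrix, rowvar=False)[0, 1:]
            assert np.max(np.abs(c)) < 1e-8

    def test_per_site_means_zero(self, rng):
        data, cov = self._dataset(rng)
        res = residualize(data, cov)
        for s in cov["site"].unique():
            m = res.matrix[(cov["site"] == s).to_numpy()].mean(axis=0)
            assert np.max(np.abs(m)) < 1e-8

    def test_planted_covariate_effect_removed(self, rng):
        data, cov = self._dataset(rng, n=200)
        beta = 0.8
        age_std = (cov["age"] - cov["age"].mean()) / cov["age"].std()
        mat = data.matrix.copy()
        mat[:, 0] += beta * age_std.to_numpy()
        planted = FCDataset(mat, data.edge_index, data.subject_ids,
                            stage="standardized")
        pre = np.corrcoef(age_std, mat[:, 0])[0, 1]
        post = np.corrcoef(age_std, residualize(planted, cov).matrix[:, 0])[0, 1]
        assert abs(pre) > 0.5
        assert abs(post) < 1e-8

    def test_rank_deficiency_names_column(self, rng):
        data, cov = self._dataset(rng)
        cov["dup"] = cov["age"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            residualize(data, cov)


class TestTimeSeriesPath:
    def test_identity_covariance_correlations_small(self):
        ts = generate_timeseries_from_cov(np.eye(6), 10_000, seed=0)
        c = np.corrcoef(ts, rowvar=False)
        off = c[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_timeseries_from_cov(np.eye(3), 1, seed=0)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(ValueError, match="semidefinite"):
            generate_timeseries_from_cov(bad, 100, seed=0)

    def test_fc_from_timeseries_round_trip(self, rng):
        labels = ("r1", "r2", "r3", "r4")
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.5
        ts_set = [
            ROITimeSeries(generate_timeseries_from_cov(cov, 4000, seed=i),
                          labels, subject_id=f"s{i}")
            for i in range(3)
        ]
        data = fc_from_timeseries(ts_set)
        assert data.stage == "fisher_z"
        assert data.matrix.shape == (3, 6)
        # edge (r1, r2) should be near arctanh(0.5) for every subject
        pos = data.edge_index.position(0, 1)
        assert np.allclose(data.matrix[:, pos], np.arctanh(0.5), atol=0.06)


class TestFCTableIO:
    def test_round_trip(self, tmp_path, rng):
        idx = EdgeIndex(tuple(default_roi_labels(5)))
        data = FCDataset(rng.normal(size=(4, idx.n_edges)), idx,
                         [f"s{i}" for i in range(4)], stage="fisher_z")
        path = tmp_path / "fc.tsv"
        write_fc_table(data, path)
        back = read_fc_table(path)
        assert back.subject_ids == data.subject_ids
        assert np.allclose(back.matrix, data.matrix)
        assert back.edge_index.roi_labels == idx.roi_labels
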