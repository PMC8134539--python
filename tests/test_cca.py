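import warnings

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

from fcstrat.cca import (
    eta_squared,
    fit_cca,
    label_severity,
    parametric_eta_p,
    permutation_suite,
    silhouette_scan,
    ward_cluster,
)
from fcstrat.config import PipelineConfig
from fcstrat.simulate import SimParams, generate_cohort
from fcstrat.connectome import standardize_dataset


def _oracle_correlations(X, Y, n_comp=3):
    """Canonical correlations by direct eigendecomposition of
    Sxx^-1 Sxy Syy^-1 Syx (independent of the SVD route)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx, Syy, Sxy = Xc.T @ Xc, Yc.T @ Yc, Xc.T @ Yc
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.linalg.eigvals(M).real)[::-1][:n_comp]
    return np.sqrt(np.clip(ev, 0.0, 1.0))


class TestFitCCA:
    def test_eta_identity(self):
        assert eta_squared(0.0734) == pytest.approx(0.9266)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(8):
            n = int(rng.integers(15, 51))
            k = int(rng.integers(4, 11))
            X = rng.standard_normal((n, k))
            Y = rng.standard_normal((n, 3))
            res = fit_cca(X, Y)
            assert np.allclose(res.correlations, _oracle_correlations(X, Y),
                               atol=1e-8)

    def test_identity_case_y_mixed_from_x(self, rng):
        X = rng.standard_normal((40, 6))
        A = rng.standard_normal((3, 3)) + 2 * np.eye(3)  # invertible mixing
        Y = X[:, :3] @ A
        res = fit_cca(X, Y)
        assert np.allclose(res.correlations, 1.0, atol=1e-8)
        assert res.wilks_lambda == pytest.approx(0.0, abs=1e-8)

    def test_invariants(self, rng):
        X = rng.standard_normal((60, 10))
        Y = rng.standard_normal((60, 3))
        res = fit_cca(X, Y)
        R = res.correlations
        assert np.all((R >= 0) & (R <= 1))
        assert np.all(np.diff(R) <= 1e-12)  # descending
        assert res.wilks_lambda == pytest.approx(np.prod(1 - R**2))
        assert res.eta_sq == pytest.approx(1 - res.wilks_lambda)
        c = np.corrcoef(res.subject_scores, rowvar=False)
        assert np.max(np.abs(c - np.eye(3))) < 1e-8

    def test_scores_are_x_side_variates(self, rng):
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 3))
        res = fit_cca(X, Y)
        Xc = X - X.mean(axis=0)
        recon = Xc @ res.x_weights
        # same up to column scaling (scores are unit-norm)
        for j in range(3):
            r = np.corrcoef(recon[:, j], res.subject_scores[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 3))
        Y[:, 2] = Y[:, 0] + Y[:, 1]  # rank 2
        with pytest.raises(ValueError, match="rank"):
            fit_cca(X, Y)
        with pytest.raises(ValueError, match="columns"):
            fit_cca(X[:, :2], rng.standard_normal((20, 3)))


class TestWardCluster:
    def test_separated_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 1, size=(30, 3))
        b = rng.normal(10, 1, size=(20, 3))
        labels = ward_cluster(np.vstack([a, b]), 2)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_n_equals_k_singletons(self, rng):
        pts = rng.normal(size=(5, 2))
        labels = ward_cluster(pts, 5)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_linkage_heights_monotone(self, rng):
        pts = rng.normal(size=(40, 3))
        Z = linkage(pts, method="ward")
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_deterministic(self, rng):
        pts = rng.normal(size=(50, 3))
        assert np.array_equal(ward_cluster(pts, 3), ward_cluster(pts, 3))


class TestSilhouetteScan:
    def test_two_tight_blobs(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (30, 3)),
                         rng.normal(5, 0.1, (25, 3))])
        by_k, chosen = silhouette_scan(pts)
        assert chosen == 2
        assert by_k[2] > 0.8

    def test_three_blobs(self, rng):
        centers = np.array([[0, 0, 0], [8, 0, 0], [4, 7, 0]])
        pts = np.vstack([rng.normal(c, 0.3, (20, 3)) for c in centers])
        _, chosen = silhouette_scan(pts)
        assert chosen == 3

    def test_single_gaussian_low_silhouette(self, rng):
        pts = rng.normal(size=(250, 3))
        by_k, _ = silhouette_scan(pts)
        assert max(by_k.values()) < 0.3


class TestLabelSeverity:
    def test_higher_mean_cluster_is_severe(self):
        totals = np.array([14.0, 14.0, 11.0, 11.0, 11.0, 11.0])
        clusters = np.array([1, 1, 2, 2, 2, 2])
        part = label_severity(clusters, totals)
        assert list(part.labels[:2]) == ["severe", "severe"]
        assert part.n_severe == 2

    def test_invariant_to_cluster_id_relabeling(self):
        totals = np.array([14.0, 13.0, 9.0, 10.0, 9.5, 8.5])
        clusters = np.array([1, 1, 2, 2, 2, 2])
        a = label_severity(clusters, totals)
        b = label_severity(3 - clusters, totals)
        assert np.array_equal(a.labels, b.labels)

    def test_equal_means_tie_to_smaller_cluster(self):
        totals = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
        clusters = np.array([1, 1, 2, 2, 2])
        with pytest.warns(UserWarning, match="equal mean"):
            part = label_severity(clusters, totals)
        assert part.n_severe == 2


class TestPermutationSuite:
    def test_strong_structure_minimal_p(self, discovery_matrix):
        disc, sub, totals = discovery_matrix
        cfg = PipelineConfig(n_permutations=199, rng_seed=1)
        cca, part = permutation_suite(disc, sub, totals, cfg)
        assert cca.p_eta_sq == pytest.approx(1 / 200)
        assert part.p_permutation <= 0.01
        assert cca.adj_eta_sq <= cca.eta_sq
        assert part.n_severe + part.n_mild == disc.n_subjects
        # severe subgroup has the higher mean total by construction
        sev = totals[part.labels == "severe"].mean()
        mld = totals[part.labels == "mild"].mean()
        assert sev > mld

    def test_zero_permutations_rejected(self, discovery_matrix):
        disc, sub, totals = discovery_matrix
        cfg = PipelineConfig(rng_seed=1)
        cfg.n_permutations = 0
        with pytest.raises(ValueError):
            permutation_suite(disc, sub, totals, cfg)

    def test_adj_eta_near_zero_on_null(self):
        """Mean-null shrinkage calibrates away selection+CCA optimism."""
        meds = []
        cfg = PipelineConfig(n_permutations=99, rng_seed=0)
        for rep in range(50):
            p = SimParams.null_cohort(n_roi=25, n_discovery=60, n_control=0,
                                      n_validation=0, seed=3000 + rep)
            c = generate_cohort(p)
            data = standardize_dataset(c.fc)
            sub = c.phenotypes[
                ["ados_comm", "ados_social", "ados_rrb"]].to_numpy(float)
            tot = c.phenotypes["ados_total"].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cca, _ = permutation_suite(
                    data, sub, tot, cfg,
                    rng=np.random.default_rng(rep),
                    compute_cluster_null=False)
            meds.append(cca.adj_eta_sq)
        assert abs(np.median(meds)) < 0.05

    def test_naive_parametric_p_exists_and_small_on_planted(self,
                                                            discovery_matrix):
        disc, sub, totals = discovery_matrix
        cfg = PipelineConfig(n_permutations=19, rng_seed=0)
        cca, _ = permutation_suite(disc, sub, totals, cfg,
                                   compute_cluster_null=False)
        p = parametric_eta_p(cca, disc.n_subjects, len(cca.selected_edges))
        assert 0.0 <= p < 0.05
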