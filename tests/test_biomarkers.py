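import warnings

import numpy as np
import pandas as pd
import pytest

from fcstrat.biomarkers import (
    age_band,
    align_and_composite,
    graded_change_test,
    groupwise_tests,
    stratified_rerun,
)
from fcstrat.connectome import EdgeIndex, FCDataset, default_roi_labels
from fcstrat.stats import two_sample_t_matrix, bh_fdr


def _dataset(rng, n, n_roi=8, stage="residualized"):
    idx = EdgeIndex(tuple(default_roi_labels(n_roi)))
    return FCDataset(rng.normal(size=(n, idx.n_edges)), idx,
                     [f"s{i}" for i in range(n)], stage=stage)


class TestGroupwiseTests:
    def test_null_significant_count_near_zero(self, rng):
        counts = []
        for _ in range(20):
            data = _dataset(rng, 60)
            t = groupwise_tests(data, [f"s{i}" for i in range(30)],
                                [f"s{i}" for i in range(30, 60)], q=0.05)
            counts.append(int(t["significant"].sum()))
        assert np.mean(counts) < 2.0

    def test_planted_markers_recovered(self, rng):
        # 1-SD shift on 25 marker edges, n = 91 vs 574
        recovered = []
        for _ in range(10):
            idx = EdgeIndex(tuple(default_roi_labels(32)))  # 496 edges
            E = idx.n_edges
            mark = rng.choice(E, 25, replace=False)
            X = rng.normal(size=(91 + 574, E))
            X[:91, mark] += 1.0
            data = FCDataset(X, idx, [f"s{i}" for i in range(665)],
                             stage="residualized")
            t = groupwise_tests(data, [f"s{i}" for i in range(91)],
                                [f"s{i}" for i in range(91, 665)], q=0.05)
            sig = set(t.loc[t["significant"], "edge"])
            recovered.append(len(sig & set(mark)) / 25)
        assert np.median(recovered) >= 0.9

    def test_rows_sorted_by_p(self, rng):
        data = _dataset(rng, 40)
        t = groupwise_tests(data, [f"s{i}" for i in range(20)],
                            [f"s{i}" for i in range(20, 40)])
        assert t["p_two_tailed"].is_monotonic_increasing

    def test_edge_subset_restricts_universe(self, rng):
        data = _dataset(rng, 40)
        subset = np.array([0, 5, 9])
        t = groupwise_tests(data, [f"s{i}" for i in range(20)],
                            [f"s{i}" for i in range(20, 40)],
                            edge_subset=subset)
        assert set(t["edge"]) == set(subset)

    def test_signs_match_t(self, rng):
        data = _dataset(rng, 30)
        t = groupwise_tests(data, [f"s{i}" for i in range(15)],
                            [f"s{i}" for i in range(15, 30)])
        assert np.array_equal(t["sign"].to_numpy(),
                              np.sign(t["t"].to_numpy()).astype(int))


class TestComposite:
    def test_all_positive_signs_is_row_sum(self, rng):
        data = _dataset(rng, 10)
        edges = np.array([0, 3, 7])
        comp = align_and_composite(data, edges, np.ones(3))
        assert np.allclose(comp, data.matrix[:, edges].sum(axis=1))

    def test_negation_invariance(self, rng):
        data = _dataset(rng, 10)
        edges = np.array([1, 4])
        signs = np.array([1.0, -1.0])
        base = align_and_composite(data, edges, signs)
        flipped = FCDataset(data.matrix.copy(), data.edge_index,
                            data.subject_ids, stage=data.stage)
        flipped.matrix[:, 4] *= -1
        assert np.allclose(
            align_and_composite(flipped, edges, signs * np.array([1, -1])),
            base)

    def test_single_negative_edge(self):
        idx = EdgeIndex(("a", "b", "c"))
        data = FCDataset(np.array([[1.0, 0, 0], [-2.0, 0, 0]]), idx,
                         ["s1", "s2"], stage="residualized")
        comp = align_and_composite(data, [0], [-1.0])
        assert list(comp) == [-1.0, 2.0]

    def test_empty_edge_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            align_and_composite(_dataset(rng, 5), [], [])


class TestGradedChange:
    @staticmethod
    def _labels(n_sev, n_mild, n_ctrl):
        return np.array(["severe"] * n_sev + ["mild"] * n_mild
                        + ["control"] * n_ctrl)

    def test_planted_ordering_detected(self, rng):
        lab = self._labels(40, 60, 80)
        comp = rng.normal(0, 1, 180)
        comp[lab == "severe"] += 1.2
        comp[lab == "mild"] += 0.6
        res = graded_change_test(comp, lab)
        assert res["graded_change"]
        assert res["severe_vs_mild"].t > 0
        assert res["mild_vs_control"].t > 0

    def test_null_verdict_rate_small(self, rng):
        lab = self._labels(30, 40, 50)
        hits = 0
        for _ in range(200):
            comp = rng.normal(size=120)
            hits += graded_change_test(comp, rng.permutation(lab))[
                "graded_change"]
        # independence of the two one-tailed tests bounds the rate near
        # alpha^2 = 0.0025; allow generous Monte-Carlo room
        assert hits <= 4

    def test_identical_severe_mild_gives_zero_t(self, rng):
        lab = self._labels(20, 20, 20)
        comp = np.concatenate([np.arange(20.0), np.arange(20.0),
                               rng.normal(size=20)])
        res = graded_change_test(comp, lab)
        assert res["severe_vs_mild"].t == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError, match="control"):
            graded_change_test(rng.normal(size=10), self._labels(5, 5, 0))


class TestStratified:
    def test_age_bands_partition(self):
        ages = [6.0, 12.0, 12.01, 18.0, 18.5, 30.0]
        bands = [age_band(a) for a in ages]
        assert bands == ["children", "children", "adolescents", "adolescents",
                         "adults", "adults"]

    def test_fd_filter_and_age_strata(self, rng):
        n = 120
        data = _dataset(rng, n)
        phen = pd.DataFrame({
            "subject_id": data.subject_ids,
            "age": rng.uniform(6, 30, n),
            "sex": rng.choice(["male", "female"], n),
            "mean_fd": rng.uniform(0.05, 0.45, n),
        })
        a = data.subject_ids[:50]
        b = data.subject_ids[50:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            by_age = stratified_rerun(data, phen, a, b, strata="age")
            by_fd = stratified_rerun(data, phen, a, b, strata="fd",
                                     fd_cutoff=0.2)
        assert set(by_age) <= {"children", "adolescents", "adults"}
        for name, table in by_age.items():
            assert len(table) == data.edge_index.n_edges
        if by_fd:
            kept = phen.set_index("subject_id")["mean_fd"] <= 0.2
            n_a = sum(kept.loc[s] for s in a)
            assert by_fd[f"fd<=0.2"]["t"].notna().all()
            assert n_a >= 2

    def test_homogeneous_effect_consistent_across_strata(self, rng):
        n = 300
        data = _dataset(rng, n, n_roi=10)
        data.matrix[: n // 2, 0] += 1.0  # same shift at every age
        phen = pd.DataFrame({
            "subject_id": data.subject_ids,
            "age": rng.uniform(6, 30, n),
            "sex": ["male"] * n,
            "mean_fd": rng.uniform(0.05, 0.45, n),
        })
        a = data.subject_ids[: n // 2]
        b = data.subject_ids[n // 2:]
        by_age = stratified_rerun(data, phen, a, b, strata="age")
        ds = [t.set_index("edge").loc[0, "cohens_d"] for t in by_age.values()]
        assert np.max(ds) - np.min(ds) < 0.8  # sampling error only


class TestFDRCalibration:
    def test_split_sample_fdr_controlled(self, rng):
        # group A and B drawn from one population: any rejection is false
        false_any = 0
        for _ in range(30):
            X = rng.normal(size=(80, 300))
            res = two_sample_t_matrix(X[:40], X[40:])
            reject, _ = bh_fdr(res["p_two_tailed"], q=0.05)
            false_any += reject.sum() > 0
        # P(any false rejection) <= q under BH for independent tests
        assert false_any / 30 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 30)
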