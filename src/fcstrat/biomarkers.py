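"""Subgroup-specific edges versus controls and the graded-change composite.

Each ASD subgroup (severe, mild) is compared against controls edge-wise with
covariate-controlled pooled t-tests and BH-FDR over the full edge universe.
Surviving edges are sign-aligned (edges weaker in patients are multiplied by
-1) and summed per subject into a composite whose severe-vs-mild and
mild-vs-control contrasts test the graded-change hypothesis: the same edges,
with the same directions, separate severe from mild and mild from control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .connectome import FCDataset
from .stats import TestResult, bh_fdr, two_sample_t, two_sample_t_matrix

__all__ = [
    "groupwise_tests",
    "align_and_composite",
    "graded_change_test",
    "stratified_rerun",
    "age_band",
]


def groupwise_tests(
    data: FCDataset,
    group_a_ids,
    group_b_ids,
    covariates: pd.DataFrame | None = None,
    q: float = 0.05,
    edge_subset: np.ndarray | None = None,
    comparison: str = "",
) -> pd.DataFrame:
    """Edge-wise pooled t-tests of group A vs group B with BH-FDR at q.

    ``edge_subset`` restricts both the tests and the FDR universe (used for
    the severe-vs-mild screen over the 100 top-selected edges); by default
    the universe is every edge in the dataset.  Covariates, if given, must be
    indexed by subject_id and are residualized jointly across both groups.
    Rows are sorted by p ascending.
    """
    A = data.subset(list(group_a_ids))
    B = data.subset(list(group_b_ids))
    if A.n_subjects < 2 or B.n_subjects < 2:
        raise ValueError("each group needs at least 2 subjects")
    edges = (
        np.arange(data.edge_index.n_edges)
        if edge_subset is None
        else np.asarray(edge_subset, dtype=int)
    )
    cov = None
    if covariates is not None:
        from .connectome import build_design

        cov_df = covariates.loc[list(group_a_ids) + list(group_b_ids)]
        cov, _ = build_design(cov_df)
    res = two_sample_t_matrix(A.matrix[:, edges], B.matrix[:, edges], cov)
    reject, p_adj = bh_fdr(res["p_two_tailed"], q=q)
    labels = data.edge_index.edge_labels
    pairs = data.edge_index.pairs
    table = pd.DataFrame(
        {
            "edge": edges,
            "edge_label": [labels[e] for e in edges],
            "region_1": [data.edge_index.roi_labels[pairs[e][0]] for e in edges],
            "region_2": [data.edge_index.roi_labels[pairs[e][1]] for e in edges],
            "t": res["t"],
            "cohens_d": res["cohens_d"],
            "p_two_tailed": res["p_two_tailed"],
            "p_adjusted": p_adj,
            "significant": reject,
            "sign": np.sign(res["t"]).astype(int),
            "comparison": comparison,
        }
    )
    return table.sort_values("p_two_tailed", kind="mergesort").reset_index(drop=True)


def align_and_composite(
    data: FCDataset, edge_ids, signs
) -> np.ndarray:
    """Per-subject sign-aligned sum over an edge set.

    Edges with a negative defining t-statistic carry sign -1, so the
    composite hypothesis is a graded *increase* from control through mild to
    severe.  Invariant under jointly negating any edge's values and sign.
    """
    edge_ids = np.asarray(edge_ids, dtype=int)
    signs = np.asarray(signs, dtype=float)
    if edge_ids.size == 0:
        raise ValueError("empty edge set")
    if edge_ids.shape != signs.shape:
        raise ValueError("edge_ids and signs must align")
    if not np.all(np.isin(signs, (-1.0, 1.0))):
        raise ValueError("signs must be +-1")
    return data.matrix[:, edge_ids] @ signs


def graded_change_test(
    composite: np.ndarray,
    labels,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """severe-vs-mild and mild-vs-control t-tests on the composite.

    The graded-change verdict requires both one-tailed tests significant in
    the increasing direction (severe > mild > control), at alpha = 0.05.
    """
    comp = np.asarray(composite, dtype=float)
    lab = np.asarray(labels)
    groups = {g: comp[lab == g] for g in ("severe", "mild", "control")}
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")

    def _cov_rows(g1, g2):
        if covariates is None:
            return None
        from .connectome import build_design

        mask = np.concatenate([np.flatnonzero(lab == g1), np.flatnonzero(lab == g2)])
        mat, _ = build_design(covariates.iloc[mask])
        return mat

    sev_mild = two_sample_t(groups["severe"], groups["mild"],
                            _cov_rows("severe", "mild"))
    mild_ctrl = two_sample_t(groups["mild"], groups["control"],
                             _cov_rows("mild", "control"))
    verdict = (
        sev_mild.t > 0
        and sev_mild.p_one_tailed < 0.05
        and mild_ctrl.t > 0
        and mild_ctrl.p_one_tailed < 0.05
    )
    return {
        "severe_vs_mild": sev_mild,
        "mild_vs_control": mild_ctrl,
        "graded_change": verdict,
    }


def age_band(age: float) -> str:
    """Children 6-12, adolescents (12, 18], adults (18, 30]; boundary ages
    fall in the younger band."""
    if age <= 12:
        return "children"
    if age <= 18:
        return "adolescents"
    return "adults"


def stratified_rerun(
    data: FCDataset,
    phenotypes: pd.DataFrame,
    group_a_ids,
    group_b_ids,
    strata: str = "age",
    fd_cutoff: float = 0.2,
    covariates: pd.DataFrame | None = None,
    q: float = 0.05,
    edge_subset: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Re-run groupwise tests within strata (age bands, sex) or after a
    stricter FD filter; strata with < 2 subjects per group are skipped with a
    warning.  Returns stratum name -> biomarker table."""
    phen = phenotypes.set_index("subject_id")
    if strata == "age":
        key = phen["age"].map(age_band)
        names = ["children", "adolescents", "adults"]
    elif strata == "sex":
        key = phen["sex"].astype(str).str.lower()
        names = sorted(key.loc[list(group_a_ids) + list(group_b_ids)].unique())
    elif strata == "fd":
        key = (phen["mean_fd"] <= fd_cutoff).map(
            {True: f"fd<={fd_cutoff}", False: "dropped"}
        )
        names = [f"fd<={fd_cutoff}"]
    else:
        raise ValueError(f"unknown strata {strata!r}")

    out: dict[str, pd.DataFrame] = {}
    for name in names:
        a = [s for s in group_a_ids if key.loc[s] == name]
        b = [s for s in group_b_ids if key.loc[s] == name]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"stratum {name!r} has < 2 subjects per group; skipped",
                          stacklevel=2)
            continue
        out[name] = groupwise_tests(
            data, a, b, covariates=covariates,
            q=q, edge_subset=edge_subset, comparison=name,
        )
    return out
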