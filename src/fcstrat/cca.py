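"""CCA between screened edges and ADOS subscales, selection-aware permutation
inference, Ward clustering of component scores, and silhouette model selection.

The central inferential device is the *whole-pipeline* permutation: at every
iteration the subscale rows (and the totals that travel with them) are
shuffled jointly, the top-k edge screen is re-run, the CCA is re-fit and the
clustering is re-done, so the empirical null for every statistic carries the
full selection and fitting optimism.  eta^2 = 1 - Wilks' Lambda is the overall
association; adj-eta^2 shrinks it against the mean of its permutation null:

    adj-eta^2 = (eta^2_obs - mean eta^2_null) / (1 - mean eta^2_null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .config import PipelineConfig
from .connectome import FCDataset
from .screening import rank_standardize, screen_top_k_from_ranks, spearman_screen
from .stats import TestResult, permutation_p, two_sample_t

__all__ = [
    "CCAResult",
    "PartitionResult",
    "fit_cca",
    "eta_squared",
    "parametric_eta_p",
    "permutation_suite",
    "ward_cluster",
    "silhouette_scan",
    "label_severity",
]


@dataclass
class CCAResult:
    x_weights: np.ndarray  # (k, 3)
    y_weights: np.ndarray  # (3, 3)
    correlations: np.ndarray  # R_1 >= R_2 >= R_3
    wilks_lambda: float
    eta_sq: float
    subject_scores: np.ndarray  # (n, 3) edge-side variates
    selected_edges: np.ndarray | None = None
    adj_eta_sq: float | None = None
    null_eta_sq: np.ndarray | None = None
    null_correlations: np.ndarray | None = None  # (B, 3)
    p_eta_sq: float | None = None
    p_correlations: np.ndarray | None = None


@dataclass
class PartitionResult:
    labels: np.ndarray  # 'severe' / 'mild' per discovery subject
    linkage: np.ndarray | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    ados_contrast: TestResult | None = None
    p_permutation: float | None = None
    null_t: np.ndarray | None = None
    components_used: list[int] | None = None

    @property
    def n_severe(self) -> int:
        return int(np.sum(self.labels == "severe"))

    @property
    def n_mild(self) -> int:
        return int(np.sum(self.labels == "mild"))


def eta_squared(wilks_lambda: float) -> float:
    """Multivariate explained variance eta^2 = 1 - Wilks' Lambda."""
    if not 0.0 <= wilks_lambda <= 1.0:
        raise ValueError("Wilks' Lambda must lie in [0, 1]")
    return 1.0 - wilks_lambda


def _orth_basis(M: np.ndarray, tol_factor: float = 1e-10):
    """Economy SVD with rank truncation; returns (Q, S_r, Vt_r, rank)."""
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    if S.size == 0 or S[0] == 0:
        return U[:, :0], S[:0], Vt[:0], 0
    rank = int(np.sum(S > tol_factor * S[0] * max(M.shape)))
    return U[:, :rank], S[:rank], Vt[:rank], rank


def fit_cca(X: np.ndarray, Y: np.ndarray, n_components: int = 3) -> CCAResult:
    """Canonical correlation analysis via the SVD-of-orthonormal-bases route.

    Columns of X and Y are centered; rank deficiency on either side is
    handled by pseudo-inverse truncation (no ridge).  Canonical correlations
    are the singular values of Qx' Qy; subject scores are the X-side
    variates, mutually orthogonal by construction.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[1] < n_components:
        raise ValueError(f"need at least {n_components} X columns")
    if Y.shape[1] < n_components:
        raise ValueError(f"need at least {n_components} Y columns")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, Sx, Vxt, rx = _orth_basis(Xc)
    Qy, Sy, Vyt, ry = _orth_basis(Yc)
    if ry < n_components:
        raise ValueError(f"rank(Y) = {ry} < {n_components}; subscales collinear")
    if rx < n_components:
        raise ValueError(f"rank(X) = {rx} < {n_components}")
    U, S, Vt = np.linalg.svd(Qx.T @ Qy, full_matrices=False)
    R = np.clip(S[:n_components], 0.0, 1.0)
    x_weights = Vxt.T @ ((1.0 / Sx)[:, None] * U[:, :n_components])
    y_weights = Vyt.T @ ((1.0 / Sy)[:, None] * Vt[:n_components].T)
    scores = Qx @ U[:, :n_components]
    wilks = float(np.prod(1.0 - R**2))
    return CCAResult(
        x_weights=x_weights,
        y_weights=y_weights,
        correlations=R,
        wilks_lambda=wilks,
        eta_sq=eta_squared(wilks),
        subject_scores=scores,
    )


def parametric_eta_p(result: CCAResult, n: int, p: int, q: int = 3) -> float:
    """Bartlett chi-square p-value for Wilks' Lambda (the *naive* CCA test).

    Ignores the edge-selection step, so it is anticonservative whenever the
    X columns were screened on the same sample; kept as the comparison arm
    for the permutation calibration.
    """
    lam = max(result.wilks_lambda, np.finfo(float).tiny)
    stat = -(n - 1 - (p + q + 1) / 2.0) * np.log(lam)
    return float(sps.chi2.sf(stat, p * q))


def ward_cluster(scores: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative Ward clustering on Euclidean distances; k-cluster cut.

    Deterministic given input order (scipy breaks distance ties by index
    order).  Returns integer labels 1..k.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    Z = linkage(scores, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def silhouette_scan(
    scores: np.ndarray, k_range=range(2, 11)
) -> tuple[dict[int, float], int]:
    """Mean silhouette width (Euclidean) for each k; argmax with ties to the
    smaller k.  Singleton clusters take silhouette 0 (sklearn convention)."""
    scores = np.asarray(scores, dtype=float)
    ks = list(k_range)
    if scores.shape[0] <= max(ks):
        raise ValueError("need more points than the largest k")
    by_k: dict[int, float] = {}
    for k in ks:
        labels = ward_cluster(scores, k)
        by_k[k] = float(silhouette_score(scores, labels, metric="euclidean"))
    chosen = min(by_k, key=lambda k: (-by_k[k], k))
    return by_k, chosen


def label_severity(
    cluster_labels: np.ndarray,
    ados_total: np.ndarray,
    covariates=None,
) -> PartitionResult:
    """Map a two-cluster labeling to severe/mild by mean ADOS total.

    The cluster with the higher mean total is 'severe'; the two-sample t of
    totals (severe vs mild, optional covariate control) is attached.  The
    permutation p must come from the whole-pipeline null, not this t alone.
    """
    cl = np.asarray(cluster_labels)
    totals = np.asarray(ados_total, dtype=float)
    ids = np.unique(cl)
    if len(ids) != 2:
        raise ValueError("severity labeling needs exactly two clusters")
    m = {c: totals[cl == c].mean() for c in ids}
    if m[ids[0]] == m[ids[1]]:
        warnings.warn("equal mean ADOS totals; smaller cluster labeled severe",
                      stacklevel=2)
        sizes = {c: np.sum(cl == c) for c in ids}
        severe_id = min(ids, key=lambda c: (sizes[c], c))
    else:
        severe_id = max(ids, key=lambda c: m[c])
    labels = np.where(cl == severe_id, "severe", "mild")
    sev_t, mld_t = totals[labels == "severe"], totals[labels == "mild"]
    if sev_t.std() == 0 and mld_t.std() == 0:
        # degenerate totals (e.g. tie case): no contrast to test
        return PartitionResult(labels=labels, ados_contrast=None)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        order = np.concatenate([np.flatnonzero(labels == "severe"),
                                np.flatnonzero(labels == "mild")])
        contrast = two_sample_t(
            totals[labels == "severe"], totals[labels == "mild"], cov[order]
        )
    else:
        contrast = two_sample_t(totals[labels == "severe"], totals[labels == "mild"])
    return PartitionResult(labels=labels, ados_contrast=contrast)


def permutation_suite(
    data: FCDataset,
    subscales: np.ndarray,
    ados_total: np.ndarray,
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
    covariates=None,
    compute_cluster_null: bool = True,
) -> tuple[CCAResult, PartitionResult]:
    """Observed screen+CCA+cluster plus the whole-pipeline permutation null.

    Each iteration jointly permutes the subscale rows and the totals, then
    re-runs the top-k screen (k = observed selection size), the CCA, and —
    when ``compute_cluster_null`` — the Ward two-cluster partition with its
    severe-vs-mild t on the permuted totals.  Iterations that fail are
    resampled, capped at 1% of the requested count.
    """
    cfg.validate()
    B = cfg.n_permutations
    if B < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    X = data.matrix
    Y = np.asarray(subscales, dtype=float)
    totals = np.asarray(ados_total, dtype=float)
    n = X.shape[0]

    screen = spearman_screen(
        X,
        Y,
        threshold=cfg.screening_p_threshold,
        k_mode="threshold",
        min_edges=cfg.min_screened_edges,
    )
    sel = screen.selected
    cca = fit_cca(X[:, sel], Y)
    cca.selected_edges = sel
    part = label_severity(ward_cluster(cca.subject_scores, 2), totals, covariates)

    zx = rank_standardize(X)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    null_eta = np.empty(B)
    null_R = np.empty((B, 3))
    null_t = np.empty(B) if compute_cluster_null else None
    failures = 0
    max_failures = max(1, int(0.01 * B))
    b = 0
    while b < B:
        perm = rng.permutation(n)
        try:
            Yp = Y[perm]
            tp = totals[perm]
            sel_b = screen_top_k_from_ranks(zx, Yp, screen.k)
            cca_b = fit_cca(X[:, sel_b], Yp)
            null_eta[b] = cca_b.eta_sq
            null_R[b] = cca_b.correlations
            if compute_cluster_null:
                cl = ward_cluster(cca_b.subject_scores, 2)
                frag = label_severity(cl, tp, cov)
                if frag.ados_contrast is None:
                    raise ValueError("degenerate permuted totals")
                null_t[b] = frag.ados_contrast.t
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than {max_failures} failed permutation iterations"
                )
            continue
        b += 1

    cca.null_eta_sq = null_eta
    cca.null_correlations = null_R
    mean_null = float(null_eta.mean())
    if mean_null >= 1.0 - 1e-12:
        # k >= n saturates every fit (eta^2 = 1); shrinkage is undefined
        warnings.warn("permutation null saturated at eta^2 = 1; "
                      "adj-eta^2 undefined", stacklevel=2)
        cca.adj_eta_sq = float("nan")
    else:
        cca.adj_eta_sq = (cca.eta_sq - mean_null) / (1.0 - mean_null)
    cca.p_eta_sq = permutation_p(cca.eta_sq, null_eta, tail="upper")
    cca.p_correlations = np.array(
        [permutation_p(cca.correlations[i], null_R[:, i], tail="upper")
         for i in range(3)]
    )

    # components entering the final clustering: all three when each is
    # individually significant at 0.05, otherwise the significant subset
    comps = [i for i in range(3) if cca.p_correlations[i] < 0.05]
    if 0 < len(comps) < 3:
        part = label_severity(
            ward_cluster(cca.subject_scores[:, comps], 2), totals, covariates
        )
    else:
        comps = comps or [0, 1, 2]
    part.components_used = comps
    if compute_cluster_null:
        part.null_t = null_t
        part.p_permutation = permutation_p(part.ados_contrast.t, null_t, tail="upper")
    sil_by_k, chosen = silhouette_scan(cca.subject_scores)
    part.silhouette_by_k = sil_by_k
    part.chosen_k = chosen
    return cca, part
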