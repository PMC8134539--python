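"""Spearman screening of edges against the three ADOS subscales.

An edge is a candidate when its Spearman rank correlation with at least one
subscale reaches P < 0.005 (min-p over the three subscales, no multiplicity
correction at this stage; the downstream whole-pipeline permutation absorbs
the selection).  Permutation re-runs use top-k mode with k fixed to the
observed selection size so that the feature-to-sample ratio is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = ["ScreenResult", "spearman_screen", "rank_standardize", "spearman_exact_p"]


@dataclass
class ScreenResult:
    rho: np.ndarray  # (n_edges, n_subscales)
    p: np.ndarray  # (n_edges, n_subscales)
    min_p: np.ndarray  # (n_edges,)
    selected: np.ndarray  # edge positions, ascending
    k: int
    threshold: float | None
    mode: str


def rank_standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centered and scaled to unit population SD.

    After this transform, Spearman's rho between original columns is the
    plain inner product Zx.T @ Zy / n — which makes permutation re-screens a
    single matrix multiply.
    """
    X = np.asarray(X, dtype=float)
    ranks = sps.rankdata(X, axis=0)
    ranks = ranks - ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column; Spearman correlation undefined")
    return ranks / sd


def _rho_p(zx: np.ndarray, zy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = zx.shape[0]
    rho = zx.T @ zy / n
    rho = np.clip(rho, -1.0, 1.0)
    # two-sided p via the t-approximation on df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    return rho, p


def spearman_screen(
    X: np.ndarray,
    subscales: np.ndarray,
    threshold: float = 0.005,
    k_mode: str = "threshold",
    k: int | None = None,
    min_edges: int = 0,
) -> ScreenResult:
    """Select edges associated with at least one ADOS subscale.

    threshold mode keeps every edge with min-p < threshold (at least
    ``min_edges`` by smallest min-p, for degenerate draws); top_k mode keeps
    exactly the k smallest-min-p edges, ties broken by edge position.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(subscales, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects for the t-approximation")
    if Y.shape[0] != n:
        raise ValueError("subscale rows must match subjects")
    zx = rank_standardize(X)
    zy = rank_standardize(Y)  # raises on a constant subscale
    rho, p = _rho_p(zx, zy)
    min_p = p.min(axis=1)
    order = np.lexsort((np.arange(len(min_p)), min_p))
    if k_mode == "threshold":
        selected = np.flatnonzero(min_p < threshold)
        if len(selected) < min_edges:
            selected = np.sort(order[:min_edges])
        k_out = len(selected)
    elif k_mode == "top_k":
        if k is None:
            raise ValueError("top_k mode requires k")
        if k > X.shape[1]:
            raise ValueError("k exceeds the number of edges")
        selected = np.sort(order[:k])
        k_out = k
    else:
        raise ValueError(f"unknown k_mode {k_mode!r}")
    return ScreenResult(
        rho=rho,
        p=p,
        min_p=min_p,
        selected=selected,
        k=k_out,
        threshold=threshold if k_mode == "threshold" else None,
        mode=k_mode,
    )


def screen_top_k_from_ranks(zx: np.ndarray, Y: np.ndarray, k: int) -> np.ndarray:
    """Fast top-k re-screen for permutation iterations.

    ``zx`` is the rank-standardized edge matrix (precomputed once; edge ranks
    do not change when the subscales are permuted).
    """
    zy = rank_standardize(Y)
    _, p = _rho_p(zx, zy)
    min_p = p.min(axis=1)
    order = np.lexsort((np.arange(len(min_p)), min_p))
    return np.sort(order[:k])


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p for Spearman's rho at tiny n (<= 8).

    Test-support oracle for validating the t-approximation; enumerates all
    n! orderings of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total
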