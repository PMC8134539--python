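"""Shared statistical kernels.

Two-sample t-tests with optional covariate control, Cohen's D, correlation
significance, Benjamini-Hochberg FDR and empirical permutation p-values.
The pooled-variance (Student) form is used throughout because it is the form
whose effect size obeys the identity D = t * sqrt(1/n1 + 1/n2), which the
rest of the pipeline relies on when converting between t and D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "two_sample_t_matrix",
    "d_from_t",
    "corr_significance",
    "bh_fdr",
    "permutation_p",
]


@dataclass(frozen=True)
class TestResult:
    """Result of a pooled-variance two-sample t-test.

    ``p_one_tailed`` is the one-sided p-value in the direction of the
    observed effect, i.e. ``p_two_tailed / 2``.  ``q`` counts nuisance
    covariates removed before the test (df = n1 + n2 - 2 - q).
    """

    t: float
    df: int
    p_two_tailed: float
    p_one_tailed: float
    cohens_d: float
    n1: int
    n2: int
    q: int = 0


def _residualize_joint(y: np.ndarray, covariates: np.ndarray) -> tuple[np.ndarray, int]:
    """OLS residuals of y on [intercept, covariates]; returns (residuals, q)."""
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != y.shape[0]:
        raise ValueError("covariate rows must match number of observations")
    design = np.column_stack([np.ones(len(y)), c])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid, c.shape[1]


def two_sample_t(
    x1,
    x2,
    covariates=None,
) -> TestResult:
    """Pooled-variance two-sample t-test with optional covariate control.

    With covariates the two groups are residualized *jointly* on
    [intercept + covariates] and the test is run on the residuals with the
    degrees of freedom reduced by the number of covariate columns.
    Cohen's D is recovered via D = t * sqrt(1/n1 + 1/n2), which for the
    plain test equals the mean difference over the pooled SD.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    q = 0
    if covariates is not None:
        y = np.concatenate([x1, x2])
        resid, q = _residualize_joint(y, covariates)
        x1, x2 = resid[:n1], resid[n1:]
    df = n1 + n2 - 2 - q
    if df < 1:
        raise ValueError("non-positive degrees of freedom")
    ss = np.sum((x1 - x1.mean()) ** 2) + np.sum((x2 - x2.mean()) ** 2)
    sp2 = ss / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (x1.mean() - x2.mean()) / se
    p_two = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        t=float(t),
        df=int(df),
        p_two_tailed=float(p_two),
        p_one_tailed=float(p_two / 2.0),
        cohens_d=float(d_from_t(t, n1, n2)),
        n1=n1,
        n2=n2,
        q=q,
    )


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled t and Cohen's D from group summary statistics (sample SDs)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p_two = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        t=float(t),
        df=int(df),
        p_two_tailed=float(p_two),
        p_one_tailed=float(p_two / 2.0),
        cohens_d=float(d_from_t(t, n1, n2)),
        n1=n1,
        n2=n2,
    )


def two_sample_t_matrix(
    X1: np.ndarray,
    X2: np.ndarray,
    covariates=None,
) -> dict[str, np.ndarray]:
    """Vectorized pooled two-sample t across columns (edges).

    X1: (n1, m), X2: (n2, m).  Covariates, if given, are an (n1+n2, q)
    design shared by all columns; residualization is joint as in
    :func:`two_sample_t`.  Returns arrays t, df (scalar), p_two, p_one,
    cohens_d of length m.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    q = 0
    if covariates is not None:
        Y = np.vstack([X1, X2])
        resid, q = _residualize_joint(Y, covariates)
        X1, X2 = resid[:n1], resid[n1:]
    df = n1 + n2 - 2 - q
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    ss = ((X1 - m1) ** 2).sum(axis=0) + ((X2 - m2) ** 2).sum(axis=0)
    sp2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p_two = 2.0 * sps.t.sf(np.abs(t), df)
    return {
        "t": t,
        "df": df,
        "p_two_tailed": p_two,
        "p_one_tailed": p_two / 2.0,
        "cohens_d": t * np.sqrt(1.0 / n1 + 1.0 / n2),
        "n1": n1,
        "n2": n2,
        "q": q,
    }


def d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's D implied by a pooled-variance t: D = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    return float(t) * float(np.sqrt(1.0 / n1 + 1.0 / n2))


def corr_significance(r: float, n: int, tails: int = 1) -> tuple[float, float]:
    """Significance of a Pearson correlation via t = r*sqrt(n-2)/sqrt(1-r^2).

    Returns (t, p) with df = n - 2; ``tails=1`` gives the one-sided p in the
    direction of r, ``tails=2`` the two-sided p.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("n must be >= 3")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    if tails == 1:
        p = sps.t.sf(abs(t), df) if r != 0 else 0.5
    else:
        p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q -> (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def permutation_p(observed: float, null_values, tail: str = "upper") -> float:
    """Add-one empirical permutation p-value.

    upper: (1 + #{null >= obs}) / (1 + B); lower analogously; two-sided
    compares absolute values.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size < 1:
        raise ValueError("need at least one null value")
    if tail == "upper":
        count = np.sum(null >= observed)
    elif tail == "lower":
        count = np.sum(null <= observed)
    elif tail == "two":
        count = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((1 + count) / (1 + null.size))
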