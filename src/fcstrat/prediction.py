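"""SVM prediction of ADOS total scores from severity-discriminating edges.

Features are the edges most different between the severe and mild subgroups
(BH-FDR over the screened set, capped at the 20 smallest p).  An RBF-kernel
SVM with fixed default hyperparameters (cost 1, kernel width 1/n_features)
predicts the integer totals under seeded 10-fold cross-validation — treating
the integer totals as class labels by default, with a regression mode as the
statistically natural alternative — and is then applied unchanged to a
held-out validation group.

Note the deliberate optimism of the in-sample design: feature selection uses
subgroup labels derived from the full discovery sample, so the pooled CV
correlation is biased upward; the held-out validation group is the honest
check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVC, SVR

from .config import PipelineConfig
from .connectome import FCDataset
from .stats import corr_significance
from . import biomarkers

__all__ = ["PredictionResult", "select_top_features", "cv_predict", "external_validate"]


@dataclass
class PredictionResult:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    t: float
    p_one_tailed: float
    fold_assignment: np.ndarray | None = None
    model_config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.observed)


def select_top_features(
    data: FCDataset,
    screened_edges,
    severity_labels,
    discovery_ids,
    covariates=None,
    q: float = 0.05,
    cap: int = 20,
) -> np.ndarray:
    """Edges most different between severe and mild, FDR-screened and capped.

    Tests run over the screened edge set only (that set is the FDR universe);
    survivors are ordered by p (ties by edge position) and truncated at
    ``cap``.  Raises if nothing survives.
    """
    labels = np.asarray(severity_labels)
    ids = list(discovery_ids)
    severe = [s for s, l in zip(ids, labels) if l == "severe"]
    mild = [s for s, l in zip(ids, labels) if l == "mild"]
    table = biomarkers.groupwise_tests(
        data,
        severe,
        mild,
        covariates=covariates,
        q=q,
        edge_subset=np.asarray(screened_edges, dtype=int),
        comparison="severe_vs_mild",
    )
    surv = table[table["significant"]]
    if surv.empty:
        raise ValueError(
            "no edge survives FDR at q={}; consider a larger q or more "
            "discriminative screening".format(q)
        )
    return surv["edge"].to_numpy(int)[:cap]


def _corr_with_guard(predicted: np.ndarray, observed: np.ndarray):
    """Pearson r with its one-tailed significance; degenerate predictions
    (zero variance) give r = nan, perfect correlation gives p = 0."""
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan"), float("nan"), float("nan")
    r = float(np.corrcoef(predicted, observed)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        return r, float("inf") if r > 0 else float("-inf"), 0.0
    t, p = corr_significance(r, len(observed), tails=1)
    return r, t, p


def _make_model(mode: str, n_features: int):
    # LIBSVM defaults: C = 1, RBF kernel with gamma = 1 / n_features
    if mode == "classification":
        return SVC(C=1.0, kernel="rbf", gamma=1.0 / n_features)
    if mode == "regression":
        return SVR(C=1.0, kernel="rbf", gamma=1.0 / n_features)
    raise ValueError(f"unknown svm_mode {mode!r}")


def cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig | None = None,
    rng_seed: int | None = None,
) -> PredictionResult:
    """Seeded k-fold cross-validated prediction of ADOS totals.

    Folds are as equal as possible (260 subjects with 10 folds gives the
    234-train / 26-test split throughout); every subject is predicted exactly
    once.  Classification mode requires >= 2 classes in each training fold.
    """
    cfg = (cfg or PipelineConfig()).validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if len(y) != n:
        raise ValueError("y must match rows of X")
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    predicted = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for fold, (train, test) in enumerate(kf.split(X)):
        y_train = y[train]
        if cfg.svm_mode == "classification" and len(np.unique(y_train)) < 2:
            raise ValueError(
                "training fold has a single class; use svm_mode='regression'"
            )
        model = _make_model(cfg.svm_mode, m)
        model.fit(X[train], y_train.astype(int) if cfg.svm_mode == "classification"
                  else y_train)
        predicted[test] = model.predict(X[test])
        fold_of[test] = fold
    r, t, p = _corr_with_guard(predicted, y)
    return PredictionResult(
        predicted=predicted,
        observed=y,
        r=r,
        t=t,
        p_one_tailed=p,
        fold_assignment=fold_of,
        model_config={
            "svm_mode": cfg.svm_mode,
            "C": 1.0,
            "kernel": "rbf",
            "gamma": 1.0 / m,
            "n_folds": cfg.n_folds,
            "rng_seed": seed,
        },
    )


def external_validate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> PredictionResult:
    """Fit on the full training group, predict the held-out group.

    The test features must be in the same edge order as the training
    features.
    """
    cfg = (cfg or PipelineConfig()).validate()
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and test feature counts differ")
    if len(y_test) < 2:
        raise ValueError("correlation undefined for a single test subject")
    model = _make_model(cfg.svm_mode, X_train.shape[1])
    model.fit(
        X_train,
        y_train.astype(int) if cfg.svm_mode == "classification" else y_train,
    )
    predicted = model.predict(X_test)
    r, t, p = _corr_with_guard(predicted, y_test)
    return PredictionResult(
        predicted=predicted,
        observed=y_test,
        r=r,
        t=t,
        p_one_tailed=p,
        model_config={
            "svm_mode": cfg.svm_mode,
            "C": 1.0,
            "kernel": "rbf",
            "gamma": 1.0 / X_train.shape[1],
        },
    )
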