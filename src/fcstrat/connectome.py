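"""From ROI time series to standardized, covariate-residualized edge vectors.

The connectome representation used throughout the pipeline is the upper
triangle of the ROI-by-ROI Pearson correlation matrix, Fisher z-transformed,
standardized within subject, and optionally residualized on nuisance
covariates (age, sex, full IQ, mean framewise displacement and site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AAL2_94_LABELS",
    "EdgeIndex",
    "ROITimeSeries",
    "FCDataset",
    "pearson_fc",
    "fisher_z",
    "vectorize_upper",
    "devectorize",
    "standardize_subject",
    "standardize_dataset",
    "residualize",
    "build_design",
    "fc_from_timeseries",
    "read_fc_table",
    "write_fc_table",
    "default_roi_labels",
]

_STAGES = ("raw_r", "fisher_z", "standardized", "residualized")

# Cortical + subcortical parcels of the AAL atlas, 2nd edition (47 bilateral
# pairs, cerebellum excluded), left hemisphere listed before right.
_AAL2_BASE = [
    "Precentral", "Frontal_Sup_2", "Frontal_Mid_2", "Frontal_Inf_Oper",
    "Frontal_Inf_Tri", "Frontal_Inf_Orb_2", "Rolandic_Oper", "Supp_Motor_Area",
    "Olfactory", "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "OFCmed",
    "OFCant", "OFCpost", "OFClat", "Insula", "Cingulate_Ant", "Cingulate_Mid",
    "Cingulate_Post", "Hippocampus", "ParaHippocampal", "Amygdala", "Calcarine",
    "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid", "Occipital_Inf",
    "Fusiform", "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]
AAL2_94_LABELS = [f"{name}_{side}" for name in _AAL2_BASE for side in ("L", "R")]


def default_roi_labels(n_roi: int) -> list[str]:
    """AAL-2 names for the 94-region parcellation, generic labels otherwise."""
    if n_roi == 94:
        return list(AAL2_94_LABELS)
    return [f"ROI_{i + 1:03d}" for i in range(n_roi)]


@dataclass(frozen=True)
class EdgeIndex:
    """Bijection between ROI pairs (i, j), i < j, and edge vector positions.

    Positions are 0-based internally; edge labels join the two ROI names with
    ``--`` for reports and table headers.
    """

    roi_labels: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self):
        r = len(self.roi_labels)
        if r < 2:
            raise ValueError("need at least 2 ROIs")
        object.__setattr__(
            self,
            "pairs",
            tuple((i, j) for i in range(r) for j in range(i + 1, r)),
        )

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)

    @property
    def n_edges(self) -> int:
        r = self.n_roi
        return r * (r - 1) // 2

    def position(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("self-pairs are not edges")
        i, j = min(i, j), max(i, j)
        r = self.n_roi
        if not 0 <= i < j < r:
            raise ValueError("ROI index out of range")
        return i * (2 * r - i - 1) // 2 + (j - i - 1)

    @property
    def edge_labels(self) -> list[str]:
        lab = self.roi_labels
        return [f"{lab[i]}--{lab[j]}" for i, j in self.pairs]

    @classmethod
    def from_edge_labels(cls, labels) -> "EdgeIndex":
        """Reconstruct an index from 'A--B' headers written by this package."""
        roi: list[str] = []
        for lab in labels:
            a, sep, b = lab.partition("--")
            if not sep:
                raise ValueError(f"malformed edge label {lab!r}")
            for name in (a, b):
                if name not in roi:
                    roi.append(name)
        idx = cls(tuple(roi))
        if idx.edge_labels != list(labels):
            raise ValueError("edge labels are not in canonical upper-triangle order")
        return idx


@dataclass(frozen=True)
class ROITimeSeries:
    """T x R matrix of per-ROI mean BOLD time series for one subject."""

    values: np.ndarray
    roi_labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be 2-D (timepoints x ROIs)")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 timepoints for a correlation")
        if v.shape[1] != len(self.roi_labels):
            raise ValueError("column count does not match ROI labels")
        if not np.isfinite(v).all():
            raise ValueError("time series contain non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class FCDataset:
    """Subjects x edges matrix of connectivity values with stage bookkeeping.

    ``stage`` moves only forward through raw_r -> fisher_z -> standardized ->
    residualized.
    """

    matrix: np.ndarray
    edge_index: EdgeIndex
    subject_ids: list[str]
    stage: str = "raw_r"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (subjects x edges)")
        if self.matrix.shape[1] != self.edge_index.n_edges:
            raise ValueError("edge count does not match the edge index")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject ids")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def _advance(self, new_matrix: np.ndarray, new_stage: str) -> "FCDataset":
        if _STAGES.index(new_stage) <= _STAGES.index(self.stage):
            raise ValueError(f"cannot move stage {self.stage!r} -> {new_stage!r}")
        return FCDataset(new_matrix, self.edge_index, list(self.subject_ids), new_stage)

    def subset(self, subject_ids) -> "FCDataset":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [pos[s] for s in subject_ids]
        except KeyError as e:
            raise KeyError(f"unknown subject id {e.args[0]!r}") from None
        return replace(
            self, matrix=self.matrix[rows], subject_ids=list(subject_ids)
        )


def pearson_fc(ts: ROITimeSeries) -> np.ndarray:
    """R x R Pearson correlation matrix of the ROI time series."""
    v = ts.values
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s): {', '.join(bad)}")
    c = np.corrcoef(v, rowvar=False)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def fisher_z(r):
    """Fisher variance-stabilizing transform arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1: diagonal or degenerate correlation leaked in")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def vectorize_upper(mat: np.ndarray, idx: EdgeIndex) -> np.ndarray:
    """Upper triangle (i < j) of a symmetric matrix in edge-index order."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (idx.n_roi, idx.n_roi):
        raise ValueError("matrix dimensions do not match the edge index")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(idx.n_roi, k=1)
    return mat[iu]


def devectorize(vec: np.ndarray, idx: EdgeIndex, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (diagonal filled with ``diagonal``)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (idx.n_edges,):
        raise ValueError("vector length does not match the edge index")
    mat = np.full((idx.n_roi, idx.n_roi), diagonal, dtype=float)
    iu = np.triu_indices(idx.n_roi, k=1)
    mat[iu] = vec
    mat.T[iu] = vec
    return mat


def standardize_subject(vec: np.ndarray) -> np.ndarray:
    """Within-subject z-scores over the edge vector (population SD, ddof=0)."""
    vec = np.asarray(vec, dtype=float)
    sd = vec.std()
    if sd == 0:
        raise ValueError("zero variance across edges; cannot standardize")
    return (vec - vec.mean()) / sd


def standardize_dataset(data: FCDataset, mode: str = "within_subject") -> FCDataset:
    """Standardize a fisher_z-stage dataset.

    ``within_subject`` (default): each subject's 4,371-edge vector to mean 0,
    SD 1.  ``per_edge``: each edge z-scored across subjects instead — the
    alternative reading of standardizing "across subjects and sites".
    """
    if data.stage != "fisher_z":
        raise ValueError("standardization expects a fisher_z-stage dataset")
    m = data.matrix
    if mode == "within_subject":
        out = np.vstack([standardize_subject(row) for row in m])
    elif mode == "per_edge":
        sd = m.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance edge; cannot standardize per edge")
        out = (m - m.mean(axis=0)) / sd
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return data._advance(out, "standardized")


def build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (no intercept) from a covariate frame.

    Numeric columns pass through; ``sex`` maps to a male indicator; ``site``
    expands to drop-first indicator columns.  Returns (matrix, column names).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for col in covariates.columns:
        s = covariates[col]
        if col == "site":
            sites = sorted(s.astype(str).unique())
            counts = s.value_counts()
            singles = [st for st in sites if counts.get(st, 0) == 1]
            if singles:
                warnings.warn(
                    f"site(s) with a single subject: {', '.join(map(str, singles))}",
                    stacklevel=2,
                )
            for st in sites[1:]:  # drop-first encoding
                cols.append((s.astype(str) == st).to_numpy(float))
                names.append(f"site[{st}]")
        elif col == "sex":
            cols.append((s.astype(str).str.lower() == "male").to_numpy(float))
            names.append("sex[male]")
        else:
            cols.append(pd.to_numeric(s).to_numpy(float))
            names.append(col)
    if not cols:
        raise ValueError("empty covariate frame")
    return np.column_stack(cols), names


def residualize(data: FCDataset, covariates: pd.DataFrame) -> FCDataset:
    """OLS-residualize every edge on intercept + covariates (+ site dummies).

    The design must be full rank after drop-first site encoding; offending
    columns are named in the error.  Residuals are exactly orthogonal to
    every design column (up to numerical precision).
    """
    if data.stage != "standardized":
        raise ValueError("residualization expects a standardized dataset")
    if len(covariates) != data.n_subjects:
        raise ValueError("covariate rows must match dataset subjects")
    X, names = build_design(covariates)
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns via pivoted QR on the centered design
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        keep = np.abs(np.diag(r)) > 1e-8 * abs(r[0, 0])
        dropped = [(["intercept"] + names)[p] for p, k in zip(piv, keep) if not k]
        raise ValueError(f"rank-deficient design; collinear column(s): {dropped}")
    beta, *_ = np.linalg.lstsq(design, data.matrix, rcond=None)
    resid = data.matrix - design @ beta
    return data._advance(resid, "residualized")


def fc_from_timeseries(ts_set, roi_labels=None) -> FCDataset:
    """Pearson -> Fisher-z edge vectors for a collection of ROITimeSeries."""
    ts_set = list(ts_set)
    if not ts_set:
        raise ValueError("empty time-series collection")
    labels = tuple(roi_labels) if roi_labels is not None else ts_set[0].roi_labels
    idx = EdgeIndex(labels)
    rows, ids = [], []
    for ts in ts_set:
        if ts.roi_labels != labels:
            raise ValueError(f"ROI labels differ for subject {ts.subject_id!r}")
        rows.append(fisher_z(vectorize_upper(pearson_fc(ts), idx)))
        ids.append(ts.subject_id)
    return FCDataset(np.vstack(rows), idx, ids, stage="fisher_z")


def write_fc_table(data: FCDataset, path) -> None:
    """TSV with subject_id first column and 'A--B' edge labels as header."""
    df = pd.DataFrame(data.matrix, columns=data.edge_index.edge_labels)
    df.insert(0, "subject_id", data.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_fc_table(path, stage: str = "fisher_z") -> FCDataset:
    """Read a TSV written by :func:`write_fc_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("FC table must have a subject_id column")
    ids = df["subject_id"].tolist()
    edges = [c for c in df.columns if c != "subject_id"]
    idx = EdgeIndex.from_edge_labels(edges)
    return FCDataset(df[edges].to_numpy(float), idx, ids, stage=stage)
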