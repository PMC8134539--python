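"""Concordance between the FC-based partition and ADOS-cutoff partitions.

For each integer cutoff the subjects are split into severe (total >= cutoff
by default) and mild, and compared with the connectivity-derived partition
via the percentage of agreement (PoA), sensitivity (severe called severe)
and specificity (mild called mild), under either partition as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Confusion", "threshold_partition", "confusion_metrics", "cutoff_sweep"]


@dataclass(frozen=True)
class Confusion:
    poa: float
    sensitivity: float  # reference-severe called severe; NaN if undefined
    specificity: float  # reference-mild called mild; NaN if undefined
    tp: int
    fn: int
    fp: int
    tn: int


def threshold_partition(ados_total, cutoff: float, rule: str = "ge") -> np.ndarray:
    """Severe iff total >= cutoff ('ge', default) or > cutoff ('gt')."""
    totals = np.asarray(ados_total, dtype=float)
    if np.any(np.isnan(totals)):
        raise ValueError("ADOS totals must be present for a cutoff partition")
    if rule == "ge":
        severe = totals >= cutoff
    elif rule == "gt":
        severe = totals > cutoff
    else:
        raise ValueError("rule must be 'ge' or 'gt'")
    return np.where(severe, "severe", "mild")


def confusion_metrics(reference, test) -> Confusion:
    """2x2 agreement between two severe/mild labelings of the same subjects.

    An empty reference class leaves the corresponding rate undefined (NaN),
    never 0.
    """
    ref = np.asarray(reference)
    tst = np.asarray(test)
    if ref.shape != tst.shape:
        raise ValueError("labelings must have equal length")
    for arr, name in ((ref, "reference"), (tst, "test")):
        bad = set(np.unique(arr)) - {"severe", "mild"}
        if bad:
            raise ValueError(f"{name} labels must be severe/mild, got {bad}")
    tp = int(np.sum((ref == "severe") & (tst == "severe")))
    fn = int(np.sum((ref == "severe") & (tst == "mild")))
    fp = int(np.sum((ref == "mild") & (tst == "severe")))
    tn = int(np.sum((ref == "mild") & (tst == "mild")))
    n = tp + fn + fp + tn
    poa = (tp + tn) / n if n else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return Confusion(poa, sens, spec, tp, fn, fp, tn)


def cutoff_sweep(
    fc_labels,
    ados_total,
    cutoff_range: tuple[int, int] = (9, 17),
    rule: str = "ge",
) -> pd.DataFrame:
    """One row per integer cutoff with both reference orientations.

    Columns suffixed ``_cutoff_ref`` take the ADOS-cutoff partition as
    reference; ``_fc_ref`` takes the FC-based partition as reference.  PoA is
    reference-invariant and reported once.
    """
    fc = np.asarray(fc_labels)
    lo, hi = int(cutoff_range[0]), int(cutoff_range[1])
    rows = []
    for c in range(lo, hi + 1):
        cut = threshold_partition(ados_total, c, rule=rule)
        m_cut_ref = confusion_metrics(cut, fc)
        m_fc_ref = confusion_metrics(fc, cut)
        rows.append(
            {
                "cutoff": c,
                "poa": m_cut_ref.poa,
                "sensitivity_cutoff_ref": m_cut_ref.sensitivity,
                "specificity_cutoff_ref": m_cut_ref.specificity,
                "sensitivity_fc_ref": m_fc_ref.sensitivity,
                "specificity_fc_ref": m_fc_ref.specificity,
                "n_severe_cutoff": int(np.sum(cut == "severe")),
                "n_severe_fc": int(np.sum(fc == "severe")),
            }
        )
    return pd.DataFrame(rows)
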