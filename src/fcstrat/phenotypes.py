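"""Phenotype table IO, ADOS total recomputation and inclusion filters.

A phenotype table is a pandas DataFrame with one row per subject and the
columns listed in :data:`MANDATORY_COLUMNS` / :data:`NUMERIC_COLUMNS`.  ADOS
totals are recomputed as Communication + Social Interaction (the Restricted/
Stereotyped Behaviors subscale never enters the total).  Inclusion filtering
assigns each row to one of four groups: ``discovery`` (ASD, all three
subscales present), ``validation`` (ASD, total present but >=1 subscale
missing), ``control``, or ``excluded``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "MANDATORY_COLUMNS",
    "NUMERIC_COLUMNS",
    "FilterReport",
    "load_phenotypes",
    "write_phenotypes",
    "compute_ados_total",
    "recompute_totals",
    "apply_inclusion_filters",
]

MANDATORY_COLUMNS = ("subject_id", "site", "diagnosis")
NUMERIC_COLUMNS = (
    "age",
    "full_iq",
    "mean_fd",
    "ados_comm",
    "ados_social",
    "ados_rrb",
    "ados_total",
)


@dataclass
class FilterReport:
    """Per-rule exclusion counts; counts sum to rows excluded."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.removed.values())


def load_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV; empty numeric cells become NaN, row order kept."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate subject_id(s): {', '.join(map(str, dup))}")
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df.reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def compute_ados_total(comm, social):
    """ADOS total = Communication + Social Interaction; NaN if either missing.

    The Restricted/Stereotyped Behaviors subscale is deliberately not used.
    """
    comm = np.asarray(comm, dtype=float)
    social = np.asarray(social, dtype=float)
    if np.any(comm[~np.isnan(comm)] < 0) or np.any(social[~np.isnan(social)] < 0):
        raise ValueError("ADOS subscale scores must be non-negative")
    total = comm + social
    return float(total) if total.ndim == 0 else total


def recompute_totals(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute ados_total where both subscales are present; keep the
    provided total for rows with incomplete subscales."""
    out = df.copy()
    if "ados_total" not in out.columns:
        out["ados_total"] = np.nan
    comm = out.get("ados_comm", pd.Series(np.nan, index=out.index))
    social = out.get("ados_social", pd.Series(np.nan, index=out.index))
    recomputed = compute_ados_total(comm.to_numpy(float), social.to_numpy(float))
    have_both = ~np.isnan(recomputed)
    out.loc[have_both, "ados_total"] = recomputed[have_both]
    return out


def apply_inclusion_filters(
    df: pd.DataFrame, cfg: PipelineConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Assign discovery/validation/control/excluded labels.

    Order of operations: individual-level bounds (age, IQ, FD) and the ADOS
    severity floor first, then the per-site minimum count of surviving ASD
    subjects, then the discovery/validation split and the control-site rule.
    """
    cfg = (cfg or PipelineConfig()).validate()
    out = recompute_totals(df)
    report = FilterReport(n_input=len(out))
    assign = pd.Series("excluded", index=out.index, dtype=object)
    reason = pd.Series("", index=out.index, dtype=object)

    def numeric(col):
        if col in out.columns:
            return out[col].to_numpy(float)
        return np.full(len(out), np.nan)

    age = numeric("age")
    iq = numeric("full_iq")
    fd = numeric("mean_fd")
    total = numeric("ados_total")
    is_asd = out["diagnosis"].astype(str).str.upper().eq("ASD").to_numpy()

    alive = np.ones(len(out), dtype=bool)

    def exclude(mask, rule):
        mask = mask & alive
        report.removed[rule] = int(mask.sum())
        reason[mask] = rule
        alive[mask] = False

    lo, hi = cfg.age_range
    exclude(np.isnan(age) | (age < lo) | (age > hi), "age_out_of_range")
    exclude(np.isnan(iq) | (iq < cfg.iq_min), "iq_below_minimum")
    exclude(np.isnan(fd) | (fd > cfg.fd_threshold), "fd_above_threshold")
    exclude(is_asd & np.isnan(total), "ados_total_missing")
    exclude(is_asd & (total <= cfg.ados_min_exclusive), "ados_total_too_low")

    # site rule: ASD subjects only count at sites with >= min_asd_per_site
    # surviving ASD subjects
    site = out["site"].astype(str)
    asd_alive = alive & is_asd
    site_counts = site[asd_alive].value_counts()
    small_sites = set(site_counts[site_counts < cfg.min_asd_per_site].index)
    exclude(asd_alive & site.isin(small_sites).to_numpy(), "site_too_few_asd")

    has_all_subscales = np.ones(len(out), dtype=bool)
    for col in ("ados_comm", "ados_social", "ados_rrb"):
        has_all_subscales &= ~np.isnan(numeric(col))

    asd_alive = alive & is_asd
    discovery = asd_alive & has_all_subscales
    validation = asd_alive & ~has_all_subscales & ~np.isnan(total)
    exclude(asd_alive & ~discovery & ~validation, "ados_subscales_unusable")

    if cfg.validation_site_disjoint:
        disc_sites = set(site[discovery])
        drop = validation & site.isin(disc_sites).to_numpy()
        validation = validation & ~drop
        exclude(drop, "validation_site_overlap")

    # controls only from sites contributing discovery subjects
    ctrl_alive = alive & ~is_asd
    disc_sites = set(site[discovery])
    exclude(ctrl_alive & ~site.isin(disc_sites).to_numpy(), "control_site_unused")
    control = alive & ~is_asd

    assign[discovery] = "discovery"
    assign[validation] = "validation"
    assign[control] = "control"
    out["group_assignment"] = assign
    out["exclusion_reason"] = reason

    for grp in ("discovery", "validation", "control"):
        n = int((assign == grp).sum())
        report.group_sizes[grp] = n
        if n == 0:
            warnings.warn(f"group {grp!r} is empty after filtering", stacklevel=2)
    report.group_sizes["excluded"] = int((assign == "excluded").sum())
    return out, report
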