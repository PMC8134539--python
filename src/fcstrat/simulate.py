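"""Synthetic multi-site cohorts with planted canonical and subgroup structure.

The generator emulates the data structure the pipeline assumes: a discovery
group of ASD subjects with complete ADOS subscales, a control group without
ADOS scores, and a validation group with totals but incomplete subscales,
spread over several sites with additive site offsets on the edges.

A low-rank latent clinical trait z (3 dimensions) drives both sides of the
canonical structure: subscale j is a monotone integer mapping of
rho_j * z_j + sqrt(1 - rho_j^2) * noise (so rho_j, the
``canonical_strength``, is the implied population canonical correlation when
the edges measure z well), and each signal edge loads on one latent
dimension.  The two severity subgroups are a genuine latent mixture: a
randomly chosen ``severe_frac`` of patients carries an additive shift along
the severity direction (z_1 + z_2)/sqrt(2), the combination that drives the
ADOS total.  ``latent_subgroup_shift`` is the gap between the two mixture
components in units of the within-subgroup SD; each latent dimension is
re-normalized to unit total variance so the canonical strengths keep their
meaning.  The subgroups are therefore separated in the clinical trait
itself, not merely by a threshold on a continuous trait (a threshold plants
no recoverable cluster structure).  Severe-marker edges additionally shift by
``subgroup_separation`` noise-SDs for severe subjects, graded
severe > mild > control; mild-marker edges realize the complementary
mild > severe > control ordering.  Covariates (age, IQ, sex, FD) have small
linear loadings onto every edge, and each site adds an edge-specific offset —
both are what makes residualization consequential downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    EdgeIndex,
    FCDataset,
    ROITimeSeries,
    default_roi_labels,
    devectorize,
    write_fc_table,
)

__all__ = [
    "SimParams",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_timeseries_from_cov",
    "cohort_to_timeseries",
    "write_fixture",
    "load_fixture",
]

# instrument ranges: Communication 0-10, Social Interaction 0-14, RRB 0-8
_SUBSCALE_CENTER = (4.0, 7.0, 4.0)
_SUBSCALE_SCALE = (2.0, 3.0, 2.0)
_SUBSCALE_MAX = (10, 14, 8)


@dataclass
class SimParams:
    n_discovery: int = 260
    n_validation: int = 29
    n_control: int = 574
    n_sites: int = 10
    n_validation_sites: int = 2
    n_roi: int = 94
    n_timepoints: int = 200
    latent_dim: int = 3
    n_signal_edges: int = 60
    n_severe_marker_edges: int = 25
    n_mild_marker_edges: int = 15
    canonical_strength: tuple[float, ...] = (0.8, 0.8, 0.7)
    signal_loading: float = 0.9
    subgroup_separation: float = 2.0
    latent_subgroup_shift: float = 16.0
    severe_graded_fraction: float = 0.4
    mild_marker_pattern: tuple[float, float] = (1.0, 0.5)
    severe_frac: float = 0.3
    site_sd: float = 0.2
    noise_sd: float = 0.5
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": 0.010,
            "full_iq": 0.005,
            "sex": 0.05,
            "mean_fd": 0.20,
        }
    )
    male_frac_asd: float = 0.9
    male_frac_control: float = 0.7
    seed: int = 0

    def validate(self) -> "SimParams":
        if self.n_discovery < 1:
            raise ValueError("n_discovery must be >= 1")
        for name in ("n_validation", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites < 1 or self.n_roi < 2:
            raise ValueError("n_sites >= 1 and n_roi >= 2 required")
        if not all(0.0 <= c < 1.0 for c in self.canonical_strength):
            raise ValueError("canonical_strength entries must lie in [0, 1)")
        if len(self.canonical_strength) != self.latent_dim:
            raise ValueError("canonical_strength length must equal latent_dim")
        n_edges = self.n_roi * (self.n_roi - 1) // 2
        planted = (
            self.n_signal_edges
            + self.n_severe_marker_edges
            + self.n_mild_marker_edges
        )
        if planted > n_edges:
            raise ValueError("planted edge sets exceed the number of edges")
        if not 0.0 < self.severe_frac < 1.0:
            raise ValueError("severe_frac must lie in (0, 1)")
        return self

    @property
    def n_edges(self) -> int:
        return self.n_roi * (self.n_roi - 1) // 2

    @classmethod
    def null_cohort(cls, **overrides) -> "SimParams":
        """Parameters with every planted effect switched off (calibration).

        Edges carry only baseline, site offsets, covariate effects and noise;
        ADOS scores are independent of the edges.
        """
        defaults = dict(
            canonical_strength=(0.0, 0.0, 0.0),
            signal_loading=0.0,
            subgroup_separation=0.0,
            latent_subgroup_shift=0.0,
            mild_marker_pattern=(0.0, 0.0),
            severe_graded_fraction=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    signal_edge_ids: np.ndarray
    severe_marker_edge_ids: np.ndarray
    mild_marker_edge_ids: np.ndarray
    true_subgroup_label: np.ndarray  # per discovery subject, severe/mild
    true_latent_scores: np.ndarray  # (n_discovery, latent_dim)
    implied_canonical_correlations: np.ndarray
    severe_marker_signs: np.ndarray
    mild_marker_signs: np.ndarray


@dataclass
class Cohort:
    phenotypes: pd.DataFrame
    fc: FCDataset
    ground_truth: GroundTruth
    params: SimParams


def _draw_covariates(rng, n, group, params):
    age = np.clip(rng.normal(15.0, 5.5, n), 6.0, 30.0)
    iq = np.clip(
        rng.normal(105.0 if group != "control" else 114.0,
                   16.0 if group != "control" else 12.6, n),
        70.0, 160.0,
    )
    male_frac = (
        params.male_frac_control if group == "control" else params.male_frac_asd
    )
    sex = np.where(rng.random(n) < male_frac, "male", "female")
    fd = np.clip(0.12 + np.abs(rng.normal(0.0, 0.08, n)), 0.01, 0.5)
    return age, iq, sex, fd


def _draw_patient_scores(rng, n, params, severe_mask):
    """Latent scores and integer ADOS subscales with total forced > 7.

    Severe subjects get the latent mixture shift along (z_1 + z_2)/sqrt(2)
    before the subscale mapping.  Subjects whose clipped total lands at <= 7
    are redrawn (labels kept fixed); if the effect scales make > 7
    essentially unreachable the generator refuses.
    """
    rho = np.asarray(params.canonical_strength, dtype=float)
    f = params.severe_frac
    # per-dimension mixture gap (within-SD units); dims 0 and 1 split the
    # severity-direction gap, and each dim is renormalized to unit variance
    a = params.latent_subgroup_shift / np.sqrt(2.0)
    norm = np.sqrt(a * a * f * (1.0 - f) + 1.0)
    # anchored at the mild group: mild patients sit at the control level of
    # the latent trait (z = 0), severe patients above both, so signal edges
    # carry the graded severe > mild ~ control pattern rather than placing
    # controls between the subgroups
    shift = np.zeros((n, params.latent_dim))
    raised = severe_mask.astype(float) * a
    shift[:, 0] = raised
    shift[:, 1] = raised
    scale = np.ones(params.latent_dim)
    scale[0] = scale[1] = 1.0 / norm
    z = np.empty((n, params.latent_dim))
    sub = np.empty((n, 3), dtype=int)
    need = np.arange(n)
    for attempt in range(200):
        m = len(need)
        z_try = (rng.standard_normal((m, params.latent_dim)) + shift[need]) * scale
        eps = rng.standard_normal((m, 3))
        core = rho * z_try[:, :3] + np.sqrt(1.0 - rho**2) * eps
        scaled = np.asarray(_SUBSCALE_CENTER) + np.asarray(_SUBSCALE_SCALE) * core
        s = np.clip(np.rint(scaled), 0, _SUBSCALE_MAX).astype(int)
        ok = (s[:, 0] + s[:, 1]) > 7
        z[need[ok]] = z_try[ok]
        sub[need[ok]] = s[ok]
        need = need[~ok]
        if len(need) == 0:
            break
    else:
        raise ValueError(
            "could not draw ADOS totals > 7; increase the subscale effect scale"
        )
    return z, sub


def generate_cohort(params: SimParams | None = None) -> Cohort:
    """Draw a full synthetic cohort; see the module docstring for the model."""
    params = (params or SimParams()).validate()
    rng = np.random.default_rng(params.seed)
    E = params.n_edges
    idx = EdgeIndex(tuple(default_roi_labels(params.n_roi)))

    # disjoint planted edge sets
    chosen = rng.choice(
        E,
        size=params.n_signal_edges
        + params.n_severe_marker_edges
        + params.n_mild_marker_edges,
        replace=False,
    )
    signal = np.sort(chosen[: params.n_signal_edges])
    severe_mark = np.sort(
        chosen[params.n_signal_edges: params.n_signal_edges
               + params.n_severe_marker_edges]
    )
    mild_mark = np.sort(chosen[params.n_signal_edges
                               + params.n_severe_marker_edges:])

    # signal-edge loadings: round-robin over latent dimensions, random sign
    loadings = np.zeros((E, params.latent_dim))
    dims = np.arange(len(signal)) % params.latent_dim
    loadings[signal, dims] = params.signal_loading * rng.choice(
        (-1.0, 1.0), size=len(signal)
    )
    severe_signs = rng.choice((-1.0, 1.0), size=len(severe_mark))
    mild_signs = rng.choice((-1.0, 1.0), size=len(mild_mark))

    # groups, sites, covariates
    n_d, n_v, n_c = params.n_discovery, params.n_validation, params.n_control
    main_sites = [f"site{j + 1:02d}" for j in range(params.n_sites)]
    val_sites = [f"vsite{j + 1:02d}" for j in range(params.n_validation_sites)]
    groups = ["discovery"] * n_d + ["control"] * n_c + ["validation"] * n_v
    site_col = (
        [main_sites[i % params.n_sites] for i in range(n_d)]
        + [main_sites[i % params.n_sites] for i in range(n_c)]
        + [val_sites[i % max(1, params.n_validation_sites)] for i in range(n_v)]
    )
    n_total = n_d + n_c + n_v

    age = np.empty(n_total)
    iq = np.empty(n_total)
    sex = np.empty(n_total, dtype=object)
    fd = np.empty(n_total)
    sl = slice(0, n_d)
    age[sl], iq[sl], sex[sl], fd[sl] = _draw_covariates(rng, n_d, "asd", params)
    sl = slice(n_d, n_d + n_c)
    age[sl], iq[sl], sex[sl], fd[sl] = _draw_covariates(rng, n_c, "control", params)
    sl = slice(n_d + n_c, n_total)
    age[sl], iq[sl], sex[sl], fd[sl] = _draw_covariates(rng, n_v, "asd", params)

    # planted severity subgroup: exact severe_frac of discovery patients,
    # chosen at random; latent mixture shift applied inside the score draw
    n_sev = int(round(params.severe_frac * n_d))
    sev_mask = np.zeros(n_d, dtype=bool)
    sev_mask[rng.choice(n_d, size=n_sev, replace=False)] = True
    subgroup = np.where(sev_mask, "severe", "mild")
    sev_mask_val = rng.random(n_v) < params.severe_frac if n_v else np.zeros(0, bool)
    subgroup_val = np.where(sev_mask_val, "severe", "mild")

    z_disc, sub_disc = _draw_patient_scores(rng, n_d, params, sev_mask)
    z_val, sub_val = (
        _draw_patient_scores(rng, n_v, params, sev_mask_val) if n_v else
        (np.zeros((0, params.latent_dim)), np.zeros((0, 3), dtype=int))
    )

    # edge matrix
    baseline = rng.normal(0.2, 0.3, E)
    site_offsets = {
        s: rng.normal(0.0, params.site_sd, E)
        for s in main_sites + val_sites
    }
    cov_load = {
        name: rng.normal(0.0, scale, E)
        for name, scale in params.covariate_effects.items()
    }
    z_all = np.vstack([z_disc, np.zeros((n_c, params.latent_dim)), z_val])
    is_severe = np.concatenate(
        [subgroup == "severe", np.zeros(n_c, bool), subgroup_val == "severe"]
    )
    is_patient = np.concatenate([np.ones(n_d, bool), np.zeros(n_c, bool),
                                 np.ones(n_v, bool)])

    M = baseline + z_all @ loadings.T
    sep = params.subgroup_separation * params.noise_sd
    # severe markers: graded severe > mild > control along the marker sign
    M[:, severe_mark] += np.outer(
        np.where(is_severe, sep, np.where(is_patient,
                                          params.severe_graded_fraction * sep, 0.0)),
        severe_signs,
    )
    mild_hi, mild_lo = params.mild_marker_pattern
    M[:, mild_mark] += np.outer(
        np.where(is_patient & ~is_severe, mild_hi * params.noise_sd,
                 np.where(is_severe, mild_lo * params.noise_sd, 0.0)),
        mild_signs,
    )
    # standardized covariates -> edge loadings
    cov_std = {
        "age": (age - age.mean()) / age.std(),
        "full_iq": (iq - iq.mean()) / iq.std(),
        "sex": (sex == "male").astype(float),
        "mean_fd": (fd - fd.mean()) / fd.std(),
    }
    for name, load in cov_load.items():
        M += np.outer(cov_std[name], load)
    for i, s in enumerate(site_col):
        M[i] += site_offsets[s]
    M += rng.normal(0.0, params.noise_sd, M.shape)

    subject_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    phen = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "site": site_col,
            "diagnosis": ["ASD" if p else "control" for p in is_patient],
            "age": np.round(age, 2),
            "sex": sex,
            "full_iq": np.round(iq, 1),
            "mean_fd": np.round(fd, 4),
            "ados_comm": np.full(n_total, np.nan),
            "ados_social": np.full(n_total, np.nan),
            "ados_rrb": np.full(n_total, np.nan),
            "ados_total": np.full(n_total, np.nan),
            "group_assignment": groups,
        }
    )
    phen.loc[: n_d - 1, ["ados_comm", "ados_social", "ados_rrb"]] = sub_disc
    phen.loc[: n_d - 1, "ados_total"] = sub_disc[:, 0] + sub_disc[:, 1]
    if n_v:
        vi = phen.index[n_d + n_c:]
        # validation: totals known, one subscale missing (emulates the
        # incomplete-subscale records that define the group)
        phen.loc[vi, "ados_total"] = sub_val[:, 0] + sub_val[:, 1]
        phen.loc[vi, "ados_comm"] = sub_val[:, 0].astype(float)
        phen.loc[vi, "ados_social"] = np.nan
        phen.loc[vi, "ados_rrb"] = sub_val[:, 2].astype(float)

    fc = FCDataset(M, idx, subject_ids, stage="fisher_z")
    truth = GroundTruth(
        signal_edge_ids=signal,
        severe_marker_edge_ids=severe_mark,
        mild_marker_edge_ids=mild_mark,
        true_subgroup_label=subgroup,
        true_latent_scores=z_disc,
        implied_canonical_correlations=np.asarray(params.canonical_strength),
        severe_marker_signs=severe_signs,
        mild_marker_signs=mild_signs,
    )
    return Cohort(phenotypes=phen, fc=fc, ground_truth=truth, params=params)


def generate_timeseries_from_cov(
    cov: np.ndarray, T: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """T x R Gaussian time series whose population covariance is ``cov``.

    The sample correlation converges to the correlation implied by cov as T
    grows.  cov must be symmetric positive-semidefinite; T >= 3 so that a
    correlation is estimable.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance is not positive semidefinite")
    if T < 3:
        raise ValueError("need T >= 3 timepoints for a correlation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((T, cov.shape[0])) @ root.T


def _implied_correlation(edge_values: np.ndarray, idx: EdgeIndex,
                         scale: float = 3.0) -> np.ndarray:
    """Map a subject's edge vector to a valid correlation matrix.

    tanh(v / scale) keeps entries in (-1, 1); the nearest-PSD projection
    (eigenvalue clipping + diagonal renormalization) makes it a proper
    correlation matrix.
    """
    C = devectorize(np.tanh(edge_values / scale), idx, diagonal=1.0)
    w, V = np.linalg.eigh(C)
    if w.min() < 1e-6:
        C = (V * np.clip(w, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def cohort_to_timeseries(
    cohort: Cohort, T: int | None = None, scale: float = 3.0,
    rng: np.random.Generator | None = None,
):
    """Emit per-subject ROI time series realizing each subject's edge values.

    Returns (list of ROITimeSeries, implied FCDataset) where the implied
    dataset holds the exact Fisher-z edge values of the (PSD-corrected)
    population correlation each time series was drawn from — the T -> inf
    limit of the estimated connectome.
    """
    params = cohort.params
    T = T if T is not None else params.n_timepoints
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    idx = cohort.fc.edge_index
    iu = np.triu_indices(idx.n_roi, k=1)
    ts_set = []
    implied = np.empty_like(cohort.fc.matrix)
    for i, sid in enumerate(cohort.fc.subject_ids):
        C = _implied_correlation(cohort.fc.matrix[i], idx, scale)
        ts = generate_timeseries_from_cov(C, T, rng)
        ts_set.append(ROITimeSeries(ts, idx.roi_labels, subject_id=sid))
        implied[i] = np.arctanh(np.clip(C[iu], -1 + 1e-12, 1 - 1e-12))
    implied_fc = FCDataset(implied, idx, list(cohort.fc.subject_ids),
                           stage="fisher_z")
    return ts_set, implied_fc


def write_fixture(cohort: Cohort, out_dir, timeseries: bool = False,
                  T: int | None = None) -> dict[str, Path]:
    """Write phenotype CSV, FC TSV and ground-truth JSON (optionally
    per-subject time-series TSVs); round-trips through the package readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.csv",
        "fc": out / "fc.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    cohort.phenotypes.to_csv(paths["phenotypes"], index=False)
    write_fc_table(cohort.fc, paths["fc"])
    gt = cohort.ground_truth
    payload = {
        "signal_edge_ids": gt.signal_edge_ids.tolist(),
        "severe_marker_edge_ids": gt.severe_marker_edge_ids.tolist(),
        "mild_marker_edge_ids": gt.mild_marker_edge_ids.tolist(),
        "true_subgroup_label": gt.true_subgroup_label.tolist(),
        "true_latent_scores": gt.true_latent_scores.tolist(),
        "implied_canonical_correlations":
            gt.implied_canonical_correlations.tolist(),
        "severe_marker_signs": gt.severe_marker_signs.tolist(),
        "mild_marker_signs": gt.mild_marker_signs.tolist(),
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cohort.params).items()},
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    if timeseries:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        ts_set, _ = cohort_to_timeseries(cohort, T=T)
        for ts in ts_set:
            pd.DataFrame(ts.values, columns=list(ts.roi_labels)).to_csv(
                ts_dir / f"{ts.subject_id}.tsv", sep="\t", index=False
            )
        paths["timeseries"] = ts_dir
    return paths


def load_fixture(out_dir) -> Cohort:
    """Reload a fixture written by :func:`write_fixture`."""
    from .connectome import read_fc_table
    from .phenotypes import load_phenotypes

    out = Path(out_dir)
    phen = load_phenotypes(out / "phenotypes.csv")
    fc = read_fc_table(out / "fc.tsv", stage="fisher_z")
    with open(out / "ground_truth.json") as fh:
        d = json.load(fh)
    params_d = d.pop("params")
    for key in ("canonical_strength", "mild_marker_pattern"):
        params_d[key] = tuple(params_d[key])
    truth = GroundTruth(
        signal_edge_ids=np.asarray(d["signal_edge_ids"], dtype=int),
        severe_marker_edge_ids=np.asarray(d["severe_marker_edge_ids"], dtype=int),
        mild_marker_edge_ids=np.asarray(d["mild_marker_edge_ids"], dtype=int),
        true_subgroup_label=np.asarray(d["true_subgroup_label"]),
        true_latent_scores=np.asarray(d["true_latent_scores"], dtype=float),
        implied_canonical_correlations=np.asarray(
            d["implied_canonical_correlations"], dtype=float
        ),
        severe_marker_signs=np.asarray(d["severe_marker_signs"], dtype=float),
        mild_marker_signs=np.asarray(d["mild_marker_signs"], dtype=float),
    )
    return Cohort(phenotypes=phen, fc=fc, ground_truth=truth,
                  params=SimParams(**params_d))
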