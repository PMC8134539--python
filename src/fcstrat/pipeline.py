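"""End-to-end pipeline: simulate/load -> standardize/residualize -> screen ->
CCA + permutation -> cluster -> agreement -> biomarkers -> prediction.

Every stage logs its seed, parameters and row/column counts; a stage failure
aborts the run with the stage name attached.  Outputs are a JSON summary and
TSV tables under the requested output directory; re-running with the same
config and seed reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agreement_mod
from . import biomarkers as biomarkers_mod
from . import prediction as prediction_mod
from .cca import permutation_suite
from .config import PipelineConfig
from .connectome import FCDataset, read_fc_table, residualize, standardize_dataset
from .phenotypes import apply_inclusion_filters, load_phenotypes
from .simulate import Cohort, SimParams, generate_cohort

log = logging.getLogger("fcstrat")

__all__ = ["run_pipeline", "PipelineError"]

COVARIATE_COLS = ["age", "sex", "full_iq", "mean_fd", "site"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def _covariates(phen: pd.DataFrame) -> pd.DataFrame:
    return phen.set_index("subject_id")[COVARIATE_COLS]


def run_pipeline(
    cfg: PipelineConfig | None = None,
    sim_params: SimParams | None = None,
    phenotype_path=None,
    fc_path=None,
    out_dir=None,
    cohort: Cohort | None = None,
) -> dict:
    """Run every stage and return the report bundle.

    Inputs are either a pre-built :class:`Cohort`, phenotype/FC file paths,
    or (default) a cohort simulated from ``sim_params``.  When ``out_dir`` is
    given, JSON/TSV artifacts are written there.
    """
    cfg = (cfg or PipelineConfig()).validate()
    rng = np.random.default_rng(cfg.rng_seed)
    bundle: dict = {"config": asdict(cfg)}

    @_stage("simulate")
    def _input() -> tuple[pd.DataFrame, FCDataset]:
        if cohort is not None:
            return cohort.phenotypes, cohort.fc
        if phenotype_path is not None and fc_path is not None:
            return load_phenotypes(phenotype_path), read_fc_table(fc_path)
        params = sim_params or SimParams(seed=cfg.rng_seed)
        log.info("simulating cohort: seed=%d", params.seed)
        c = generate_cohort(params)
        bundle["ground_truth_subgroups"] = c.ground_truth.true_subgroup_label
        return c.phenotypes, c.fc

    phen_raw, fc_raw = _input()

    @_stage("filters")
    def _filters():
        phen, report = apply_inclusion_filters(phen_raw, cfg)
        log.info("filters: %d input, removed per rule %s", report.n_input,
                 report.removed)
        bundle["filter_report"] = {
            "n_input": report.n_input,
            "removed": report.removed,
            "group_sizes": report.group_sizes,
        }
        return phen

    phen = _filters()

    @_stage("fc")
    def _prepare_fc() -> FCDataset:
        data = fc_raw
        if data.stage == "fisher_z":
            data = standardize_dataset(data, mode=cfg.standardize_mode)
        keep = phen.loc[phen["group_assignment"] != "excluded", "subject_id"]
        keep = [s for s in keep if s in set(data.subject_ids)]
        data = data.subset(keep)
        if cfg.cca_on_residualized:
            data = residualize(data, _covariates(phen).loc[keep])
        log.info("fc: %d subjects x %d edges, stage=%s", data.n_subjects,
                 data.edge_index.n_edges, data.stage)
        return data

    data = _prepare_fc()
    by_group = {
        g: phen.loc[phen["group_assignment"] == g, "subject_id"].tolist()
        for g in ("discovery", "control", "validation")
    }
    disc_ids = [s for s in by_group["discovery"] if s in set(data.subject_ids)]
    disc = data.subset(disc_ids)
    phen_idx = phen.set_index("subject_id")
    subscales = phen_idx.loc[disc_ids, ["ados_comm", "ados_social", "ados_rrb"]]
    totals = phen_idx.loc[disc_ids, "ados_total"].to_numpy(float)
    cov_design = None
    if len(disc_ids) >= 10:
        from .connectome import build_design

        cov_design, _ = build_design(
            phen_idx.loc[disc_ids, ["full_iq", "sex", "age", "site"]]
        )

    @_stage("screen_cca_cluster")
    def _cca():
        cca_res, part = permutation_suite(
            disc,
            subscales.to_numpy(float),
            totals,
            cfg,
            rng=rng,
            covariates=cov_design,
        )
        log.info(
            "cca: k=%d edges, R=%s, eta2=%.4f (adj %.4f), p_eta=%.4g; "
            "clusters severe=%d mild=%d (t=%.2f, p_perm=%.4g)",
            len(cca_res.selected_edges), np.round(cca_res.correlations, 3),
            cca_res.eta_sq, cca_res.adj_eta_sq, cca_res.p_eta_sq,
            part.n_severe, part.n_mild, part.ados_contrast.t,
            part.p_permutation,
        )
        return cca_res, part

    cca_res, part = _cca()
    bundle["cca"] = {
        "k_screened": int(len(cca_res.selected_edges)),
        "feature_to_sample_ratio_pct":
            100.0 * len(cca_res.selected_edges) / max(1, len(disc_ids)),
        "canonical_correlations": cca_res.correlations.tolist(),
        "wilks_lambda": cca_res.wilks_lambda,
        "eta_sq": cca_res.eta_sq,
        "adj_eta_sq": cca_res.adj_eta_sq,
        "p_eta_sq": cca_res.p_eta_sq,
        "p_correlations": cca_res.p_correlations.tolist(),
    }
    bundle["partition"] = {
        "n_severe": part.n_severe,
        "n_mild": part.n_mild,
        "ados_contrast_t": part.ados_contrast.t,
        "ados_contrast_d": part.ados_contrast.cohens_d,
        "p_permutation": part.p_permutation,
        "silhouette_by_k": part.silhouette_by_k,
        "chosen_k": part.chosen_k,
    }

    @_stage("agree")
    def _agree():
        return agreement_mod.cutoff_sweep(
            part.labels, totals, cfg.cutoff_range, rule=cfg.cutoff_rule
        )

    agree_df = _agree()
    bundle["agreement"] = agree_df.to_dict(orient="list")

    @_stage("biomarkers")
    def _biom():
        severe_ids = [s for s, l in zip(disc_ids, part.labels) if l == "severe"]
        mild_ids = [s for s, l in zip(disc_ids, part.labels) if l == "mild"]
        ctrl_ids = [s for s in by_group["control"] if s in set(data.subject_ids)]
        cov = _covariates(phen)[["full_iq", "sex", "age", "site"]]
        out = {}
        for name, a in (("severe_vs_control", severe_ids),
                        ("mild_vs_control", mild_ids)):
            if len(a) >= 2 and len(ctrl_ids) >= 2:
                out[name] = biomarkers_mod.groupwise_tests(
                    data, a, ctrl_ids, covariates=cov, q=cfg.fdr_q,
                    comparison=name,
                )
        composites = {}
        for name, table in out.items():
            sig = table[table["significant"]]
            if sig.empty:
                continue
            comp = biomarkers_mod.align_and_composite(
                data, sig["edge"].to_numpy(int), sig["sign"].to_numpy(float)
            )
            lab = np.asarray(
                ["severe" if s in set(severe_ids) else
                 "mild" if s in set(mild_ids) else
                 "control" if s in set(ctrl_ids) else "other"
                 for s in data.subject_ids]
            )
            mask = lab != "other"
            composites[name] = biomarkers_mod.graded_change_test(
                comp[mask], lab[mask]
            )
        return out, composites

    biom_tables, graded = _biom()
    bundle["biomarkers"] = {
        name: {"n_significant": int(t["significant"].sum())}
        for name, t in biom_tables.items()
    }
    bundle["graded_change"] = {
        name: {
            "severe_vs_mild_t": g["severe_vs_mild"].t,
            "mild_vs_control_t": g["mild_vs_control"].t,
            "graded_change": bool(g["graded_change"]),
        }
        for name, g in graded.items()
    }

    @_stage("predict")
    def _predict():
        features = prediction_mod.select_top_features(
            disc,
            cca_res.selected_edges,
            part.labels,
            disc_ids,
            q=cfg.fdr_q,
            cap=cfg.prediction_feature_cap,
        )
        cv = prediction_mod.cv_predict(
            disc.matrix[:, features], totals, cfg, rng_seed=cfg.rng_seed
        )
        result = {"features": features, "cv": cv}
        val_ids = [s for s in by_group["validation"] if s in set(data.subject_ids)]
        if len(val_ids) >= 2:
            val = data.subset(val_ids)
            y_val = phen_idx.loc[val_ids, "ados_total"].to_numpy(float)
            result["validation"] = prediction_mod.external_validate(
                disc.matrix[:, features], totals,
                val.matrix[:, features], y_val, cfg,
            )
        return result

    pred = _predict()
    bundle["prediction"] = {
        "n_features": int(len(pred["features"])),
        "cv_r": pred["cv"].r,
        "cv_t": pred["cv"].t,
        "cv_p_one_tailed": pred["cv"].p_one_tailed,
    }
    if "validation" in pred:
        bundle["prediction"].update(
            validation_r=pred["validation"].r,
            validation_t=pred["validation"].t,
            validation_p_one_tailed=pred["validation"].p_one_tailed,
        )

    if out_dir is not None:
        _write_bundle(bundle, agree_df, biom_tables, part, out_dir)
    bundle["_objects"] = {
        "phenotypes": phen,
        "data": data,
        "cca": cca_res,
        "partition": part,
        "agreement": agree_df,
        "biomarker_tables": biom_tables,
        "prediction": pred,
    }
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_bundle(bundle, agree_df, biom_tables, part, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {k: v for k, v in bundle.items() if not k.startswith("_")}
    summary.pop("ground_truth_subgroups", None)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
    agree_df.to_csv(out / "agreement.tsv", sep="\t", index=False)
    for name, table in biom_tables.items():
        table.to_csv(out / f"biomarkers_{name}.tsv", sep="\t", index=False)
    pd.DataFrame({"label": part.labels}).to_csv(
        out / "partition_labels.tsv", sep="\t", index=False
    )
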