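#!/usr/bin/env python
"""SVM prediction of ADOS totals from severity-discriminating edges.

The 20 edges most different between the FC-derived severe and mild
subgroups (BH-FDR over the screened set) feed an RBF-kernel SVM with
default hyperparameters, evaluated by seeded 10-fold cross-validation in
the discovery group and then applied unchanged to the held-out validation
group.

Reads results/subject_scores.tsv; writes results/prediction.tsv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, cohort as make_cohort, prepared_data

from fcstrat.config import PipelineConfig
from fcstrat.prediction import cv_predict, external_validate, select_top_features
from fcstrat.screening import spearman_screen

ROOT = RESULTS


def main():
    cohort = make_cohort()
    data = prepared_data(cohort)
    phen = cohort.phenotypes.set_index("subject_id")
    scores = pd.read_csv(ROOT / "subject_scores.tsv", sep="\t")
    disc_ids = scores["subject_id"].tolist()
    disc = data.subset(disc_ids)
    sub = phen.loc[disc_ids, ["ados_comm", "ados_social",
                              "ados_rrb"]].to_numpy(float)
    totals = phen.loc[disc_ids, "ados_total"].to_numpy(float)

    cfg = PipelineConfig(rng_seed=1)
    screen = spearman_screen(disc.matrix, sub,
                             threshold=cfg.screening_p_threshold, min_edges=3)
    feats = select_top_features(disc, screen.selected,
                                scores["fc_label"].to_numpy(), disc_ids,
                                q=cfg.fdr_q, cap=cfg.prediction_feature_cap)
    labels = disc.edge_index.edge_labels
    print(f"selected {len(feats)} severity-discriminating edges "
          f"(top: {labels[feats[0]]})")

    cv = cv_predict(disc.matrix[:, feats], totals, cfg)
    print(f"10-fold CV (n={cv.n}, folds {np.bincount(cv.fold_assignment)[0]}"
          f" held out): r = {cv.r:.2f}, t = {cv.t:.2f}, "
          f"p_one_tailed = {cv.p_one_tailed:.2g}")

    val_ids = phen.index[phen["group_assignment"] == "validation"].tolist()
    val = data.subset(val_ids)
    y_val = phen.loc[val_ids, "ados_total"].to_numpy(float)
    ext = external_validate(disc.matrix[:, feats], totals,
                            val.matrix[:, feats], y_val, cfg)
    print(f"external validation (n={ext.n}): r = {ext.r:.2f}, "
          f"t = {ext.t:.2f}, p_one_tailed = {ext.p_one_tailed:.3f}")

    out = pd.DataFrame({
        "subject_id": disc_ids + val_ids,
        "group": ["discovery"] * len(disc_ids) + ["validation"] * len(val_ids),
        "observed": np.concatenate([cv.observed, ext.observed]),
        "predicted": np.concatenate([cv.predicted, ext.predicted]),
    })
    out.to_csv(ROOT / "prediction.tsv", sep="\t", index=False)
    print(f"wrote {ROOT / 'prediction.tsv'}")


if __name__ == "__main__":
    main()
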