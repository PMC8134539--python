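#!/usr/bin/env python
"""Agreement between the FC-based partition and ADOS-cutoff partitions.

Sweeps integer ADOS-total cutoffs 9-17, reporting the percentage of
agreement and, under both reference orientations, sensitivity (severe
called severe) and specificity (mild called mild), plus the recovery of the
planted subgroups.

Reads results/subject_scores.tsv (from 03); writes results/agreement.tsv.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from common import RESULTS, cohort as make_cohort

from fcstrat.agreement import cutoff_sweep

ROOT = RESULTS


def main():
    cohort = make_cohort()
    scores = pd.read_csv(ROOT / "subject_scores.tsv", sep="\t")
    phen = cohort.phenotypes.set_index("subject_id")
    totals = phen.loc[scores["subject_id"], "ados_total"].to_numpy(float)
    labels = scores["fc_label"].to_numpy()

    ari = adjusted_rand_score(cohort.ground_truth.true_subgroup_label, labels)
    print(f"FC partition vs planted subgroups: ARI = {ari:.2f}")

    curve = cutoff_sweep(labels, totals, (9, 17))
    curve.to_csv(ROOT / "agreement.tsv", sep="\t", index=False)
    print(curve.round(3).to_string(index=False))
    best = curve.loc[curve["poa"].idxmax()]
    print(f"\nbest agreement: PoA = {100 * best['poa']:.1f}% at cutoff "
          f"{int(best['cutoff'])}")
    high = curve[curve["poa"] > 0.7]["cutoff"].tolist()
    print(f"cutoffs with PoA > 70%: {high}")


if __name__ == "__main__":
    main()
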