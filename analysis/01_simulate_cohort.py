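#!/usr/bin/env python
"""Generate the synthetic multi-site cohort used by the downstream analyses.

Emulates the structure of a resting-state FC study of high-functioning
autism: a 260-subject discovery group with complete ADOS subscales, 574
controls without ADOS, and a 29-subject validation group with totals but an
incomplete subscale record, spread over 10 main sites plus 2
validation-only sites.  A 30-ROI edge space (435 edges) keeps the analysis
fast; the planted structure (latent clinical trait, severity subgroups,
marker edges) is recorded as ground truth.

Writes the file fixture (phenotypes CSV, FC TSV, ground-truth JSON) under
scratch/cohort (bulky, regenerable) and a phenotype summary under results/.
"""

from common import PARAMS, RESULTS, SCRATCH

from fcstrat.simulate import generate_cohort, write_fixture


def main():
    params = PARAMS
    cohort = generate_cohort(params)
    write_fixture(cohort, SCRATCH / "cohort")

    phen = cohort.phenotypes
    print(f"cohort fixture written to {SCRATCH / 'cohort'}")
    print(phen["group_assignment"].value_counts().to_string())
    disc = phen.query("group_assignment == 'discovery'")
    truth = cohort.ground_truth.true_subgroup_label
    print(f"\nplanted subgroups: {int((truth == 'severe').sum())} severe / "
          f"{int((truth == 'mild').sum())} mild")
    print(f"ADOS total: mild mean "
          f"{disc['ados_total'][truth == 'mild'].mean():.2f}, severe mean "
          f"{disc['ados_total'][truth == 'severe'].mean():.2f}")
    print(f"planted edges: {params.n_signal_edges} signal, "
          f"{params.n_severe_marker_edges} severe-marker, "
          f"{params.n_mild_marker_edges} mild-marker "
          f"of {params.n_edges} total")
    RESULTS.mkdir(exist_ok=True)
    summary = phen.groupby("group_assignment")[
        ["age", "full_iq", "mean_fd", "ados_total"]].agg(["mean", "std"])
    summary.round(2).to_csv(RESULTS / "cohort_summary.tsv", sep="\t")
    print(f"summary written to {RESULTS / 'cohort_summary.tsv'}")


if __name__ == "__main__":
    main()
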