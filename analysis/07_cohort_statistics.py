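#!/usr/bin/env python
"""Descriptive associations: PRS vs comorbidity and the PRS x CNV model.

Runs the Student t test of the PRS by ADHD-comorbidity status, Pearson
correlations between the PRS and baseline SRS, and the linear
PRS x clinically-significant-CNV interaction on SRS change scores.
Writes results/cohort_stats/.
"""

from pathlib import Path

import pandas as pd

from prstrial import io as pio
from prstrial.cohort_stats import group_t_test, pearson_corr, prs_cnv_interaction
from prstrial.geneset import delta_srs

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pio.TrialCohort.from_csv(ROOT / "study" / "cohort.csv")
    ind = cohort.individuals.set_index("id")
    out = ROOT / "cohort_stats"
    out.mkdir(parents=True, exist_ok=True)

    t = group_t_test(ind["prs_true"], ind["adhd_comorbid"])
    print(
        f"PRS by ADHD comorbidity: t = {t.t:.3f}, P = {t.p:.4f} "
        f"(means {t.group_means[0]:.3f} vs {t.group_means[1]:.3f}, df = {t.df:.0f})"
    )

    pre = cohort.outcomes.query("timepoint == 'pre'").set_index("id")["srs_total"]
    corr = pearson_corr(ind.loc[pre.index, "prs_true"], pre)
    print(f"PRS vs baseline SRS: r = {corr.r:.3f}, P = {corr.p:.4f}, n = {corr.n}")

    change, _ = delta_srs(cohort, "post")
    table = prs_cnv_interaction(
        change, ind["prs_true"], ind["cnv_clinsig"],
        covariates=ind[["pc1", "pc2", "pc3", "pc4"]],
    )
    table.to_csv(out / "prs_cnv_interaction.tsv", sep="\t")
    row = table.loc["prs_x_cnv"]
    print(
        f"PRS x CNV interaction on post change: beta = {row['beta']:.3f} "
        f"[{row['ci_lo']:.3f}, {row['ci_hi']:.3f}], P = {row['p']:.4f}"
    )

    pd.DataFrame(
        [
            {"test": "prs_by_adhd_comorbidity_t", "stat": t.t, "p": t.p},
            {"test": "prs_vs_baseline_srs_r", "stat": corr.r, "p": corr.p},
            {"test": "prs_x_cnv_beta", "stat": row["beta"], "p": row["p"]},
        ]
    ).to_csv(out / "summary.tsv", sep="\t", index=False)
    print(f"wrote cohort statistics to {out}")


if __name__ == "__main__":
    main()
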