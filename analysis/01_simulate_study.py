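#!/usr/bin/env python
"""Generate the synthetic study: genotypes, reference GWAS, trial cohort.

Design conditions mirror the trial the pipeline targets: 188 genotyped
participants (99 SSGT / 89 standard care) at 13 centers, SRS at pre / post /
3-month follow-up with dropout to ~169 and ~152, LD-blocked genotypes, and a
planted PRS x time x arm effect of +6.7 SRS points per PRS SD at follow-up
so downstream stages have a known truth.  Writes PLINK + TSV genotypes,
summary-stat TSV, cohort CSV and the truth record under results/study/.
"""

from pathlib import Path

from prstrial import io as pio
from prstrial.simulate import SimConfig, simulate_all

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 2024


def main() -> None:
    cfg = SimConfig(seed=SEED, prs_time_arm_beta=(3.0, 6.7))
    out = simulate_all(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    pio.write_plink(out.genotypes, OUT / "genotypes")
    pio.write_genotypes_tsv(out.genotypes, OUT / "genotypes.tsv")
    out.summary_stats.to_tsv(OUT / "sumstats.tsv")
    out.cohort.to_csv(OUT / "cohort.csv")
    pio.write_json(out.truth, OUT / "truth.json")
    counts = out.cohort.arm_counts()
    print(
        f"simulated {out.genotypes.n_individuals} individuals "
        f"({counts['SSGT']} SSGT / {counts['standard_care']} standard care), "
        f"{out.genotypes.n_variants} variants in LD blocks"
    )
    print(
        f"outcome records: pre {out.cohort.n_with_timepoint('pre')}, "
        f"post {out.cohort.n_with_timepoint('post')}, "
        f"follow-up {out.cohort.n_with_timepoint('followup')}"
    )
    print(f"wrote study files to {OUT}")


if __name__ == "__main__":
    main()
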