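#!/usr/bin/env python
"""Quality-control the simulated genotypes.

Injects realistic missingness, then applies the per-individual filters
(genotype failure rate > 0.03, heterozygosity beyond 3 SD) and per-marker
filters (missingness > 0.05, MAF < 0.05, exact Hardy-Weinberg P < 1e-6,
individual missingness > 0.1).  Writes the cleaned fileset and an itemized
report under results/qc/.
"""

from pathlib import Path

import pandas as pd

from prstrial import io as pio
from prstrial.qc import qc_individuals, qc_markers
from prstrial.simulate import inject_missingness

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    g = pio.read_plink(ROOT / "study" / "genotypes")
    g = inject_missingness(g, marker_rate=0.01, individual_rate=0.005, seed=11)
    g1, rep_ind = qc_individuals(g)
    g2, rep_mark = qc_markers(g1)
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    pio.write_plink(g2, out / "genotypes_clean")
    report = pd.concat([rep_ind.to_frame(), rep_mark.to_frame()], ignore_index=True)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    print(
        f"individuals: {g.n_individuals} -> {g2.n_individuals} "
        f"({len(rep_ind.removed_individuals) + len(rep_mark.removed_individuals)} removed)"
    )
    by_reason = report.query("item_type == 'variant'")["reason"].value_counts().to_dict()
    print(f"markers: {g.n_variants} -> {g2.n_variants} (removed by reason: {by_reason})")
    print(f"wrote cleaned genotypes and report to {out}")


if __name__ == "__main__":
    main()
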