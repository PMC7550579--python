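"""Per-individual and per-marker genotype quality control.

Filters follow standard array-QC practice: individuals are screened for
call-rate failure and outlying heterozygosity first, then markers for
missingness, minor allele frequency, and departure from Hardy-Weinberg
equilibrium by the conditional exact test.
"""

from __future__ import annotations

import dataclasses
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "QCReport",
    "hwe_exact_test",
    "qc_individuals",
    "qc_markers",
    "EmptyAfterQCError",
]


class EmptyAfterQCError(ValueError):
    """All individuals or all markers were removed by a filter."""


@dataclasses.dataclass
class QCReport:
    """Itemized record of one QC pass.

    Each removed item carries exactly one primary reason (the first filter,
    in application order, that rejected it).
    """

    removed_individuals: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    removed_variants: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    thresholds_used: dict = dataclasses.field(default_factory=dict)
    filter_order: list[str] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("individual", i, r) for i, r in self.removed_individuals]
        rows += [("variant", v, r) for v, r in self.removed_variants]
        return pd.DataFrame(rows, columns=["item_type", "item_id", "reason"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact test of Hardy-Weinberg equilibrium.

    Given genotype counts, conditions on the observed allele counts and sums
    the probabilities of every heterozygote count (same parity as observed)
    whose conditional probability does not exceed that of the observed
    table.  Monomorphic markers return 1.0.  Uses the standard stable
    recurrence over heterozygote counts rather than factorials.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa  # rarer-or-not, symmetric either way
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # probabilities over all heterozygote counts with the observed parity
    het_min = rare % 2
    hets = list(range(het_min, rare + 1, 2))
    # unnormalized log-probabilities via the hypergeometric-style kernel:
    # P(nAa = h) ∝ 2^h / (nAA! nAa! naa!) with nAA, naa implied by h
    logs = []
    for h in hets:
        n_rare_hom = (rare - h) // 2
        n_common_hom = (2 * n - rare - h) // 2
        logp = h * np.log(2.0) - (
            lgamma(n_rare_hom + 1) + lgamma(h + 1) + lgamma(n_common_hom + 1)
        )
        logs.append(logp)
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(n_Aa)]
    # tolerance guards against ties lost to rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _heterozygosity_outliers(g: GenotypeMatrix, het_sd: float) -> np.ndarray:
    het = g.heterozygosity_rate()
    mean = np.nanmean(het)
    sd = np.nanstd(het, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros(g.n_individuals, dtype=bool)
    return np.abs(het - mean) > het_sd * sd


def qc_individuals(
    g: GenotypeMatrix,
    het_sd: float = 3.0,
    ind_fail_rate: float = 0.03,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove poorly genotyped individuals.

    An individual fails on missingness when its genotype failure (missing
    call) fraction exceeds ``ind_fail_rate``, or on heterozygosity when its
    heterozygous-call rate deviates from the cohort mean by more than
    ``het_sd`` cohort standard deviations.  Missingness is the primary
    reason when both apply; heterozygosity statistics are computed on the
    full input cohort before any removal.
    """
    if g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        thresholds_used={"het_sd": het_sd, "ind_fail_rate": ind_fail_rate},
        filter_order=["individual_missingness", "heterozygosity"],
    )
    miss_fail = g.individual_missingness() > ind_fail_rate
    het_fail = _heterozygosity_outliers(g, het_sd)
    keep = []
    for i, iid in enumerate(g.individual_ids):
        if miss_fail[i]:
            report.removed_individuals.append((iid, "missingness"))
        elif het_fail[i]:
            report.removed_individuals.append((iid, "heterozygosity"))
        else:
            keep.append(i)
    if not keep:
        raise EmptyAfterQCError("individual QC removed every individual")
    return g.subset(individuals=keep), report


def qc_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_min_p: float = 1e-6,
    marker_miss_max: float = 0.05,
    ind_miss_max: float = 0.1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Combined-cohort cleaning of low-quality markers.

    Applied in order: (1) individuals with missing fraction above
    ``ind_miss_max`` are removed; then per marker, (2) missingness above
    ``marker_miss_max``, (3) minor allele frequency below ``maf_min``
    (computed on non-missing calls), (4) exact Hardy-Weinberg P below
    ``hwe_min_p``.  Each removed marker records the first filter that
    rejected it.
    """
    if g.n_individuals == 0 or g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        thresholds_used={
            "maf": maf_min,
            "hwe_p": hwe_min_p,
            "marker_missingness": marker_miss_max,
            "individual_missingness": ind_miss_max,
        },
        filter_order=["individual_missingness", "marker_missingness", "maf", "hwe"],
    )
    ind_miss = g.individual_missingness()
    keep_ind = []
    for i, iid in enumerate(g.individual_ids):
        if ind_miss[i] > ind_miss_max:
            report.removed_individuals.append((iid, "missingness"))
        else:
            keep_ind.append(i)
    if not keep_ind:
        raise EmptyAfterQCError("individual-missingness filter removed everyone")
    g = g.subset(individuals=keep_ind)

    miss = g.marker_missingness()
    maf = g.maf()
    counts = g.allele_counts()
    keep_var = []
    for j, v in enumerate(g.variants):
        if miss[j] > marker_miss_max:
            report.removed_variants.append((v.id, "missingness"))
        elif maf[j] < maf_min or not np.isfinite(maf[j]):
            report.removed_variants.append((v.id, "maf"))
        else:
            n0, n1, n2 = counts[j]
            if hwe_exact_test(int(n2), int(n1), int(n0)) < hwe_min_p:
                report.removed_variants.append((v.id, "hwe"))
            else:
                keep_var.append(j)
    if not keep_var:
        raise EmptyAfterQCError("marker QC removed every marker")
    return g.subset(variants=keep_var), report


def apply_exclusion_list(
    g: GenotypeMatrix, exclude_ids: Sequence[str]
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop externally flagged individuals (e.g. sex-check or relatedness lists)."""
    excl = set(exclude_ids)
    report = QCReport(filter_order=["external_exclusion"])
    keep = []
    for i, iid in enumerate(g.individual_ids):
        if iid in excl:
            report.removed_individuals.append((iid, "external_exclusion"))
        else:
            keep.append(i)
    if not keep:
        raise EmptyAfterQCError("exclusion list removed every individual")
    return g.subset(individuals=keep), report
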