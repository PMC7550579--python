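"""Clump-and-threshold polygenic risk scoring.

Pipeline: harmonize the cohort's counted alleles with the reference GWAS
effect alleles (flipping dosages where the counted allele is the non-effect
allele, resolving strand complements, and handling palindromic A/T-G/C
markers by policy), greedily clump variants to an approximately independent
set (r^2 < 0.1 within 500 kb by default), sum ln(OR)-weighted dosages at
each P-value threshold, and standardize each score column to mean 0, SD 1.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SummaryStats

__all__ = ["PRSConfig", "PRSProfile", "harmonize", "ld_clump", "score", "standardize"]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.5, 1.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2


@dataclasses.dataclass
class PRSConfig:
    """Scoring parameters: inclusion thresholds and clumping geometry."""

    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    clump_r2: float = 0.1
    clump_window_kb: float = 500.0
    palindromic_policy: Literal["keep", "drop"] = "keep"

    def __post_init__(self) -> None:
        ts = list(self.thresholds)
        if any(not (0 < t <= 1) for t in ts):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.palindromic_policy not in ("keep", "drop"):
            raise ValueError("palindromic_policy must be 'keep' or 'drop'")


@dataclasses.dataclass
class PRSProfile:
    """Per-individual scores at each threshold, raw and (optionally) z-scored.

    ``raw`` and ``z`` are DataFrames indexed by individual id with one column
    per threshold (named ``pt_<threshold>``); ``n_snps_used`` maps each
    threshold to the number of variants entering that score.
    """

    raw: pd.DataFrame
    n_snps_used: dict[float, int]
    z: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        out = self.raw.add_prefix("raw_")
        if self.z is not None:
            out = out.join(self.z.add_prefix("z_"))
        out.index.name = "id"
        out.to_csv(path, sep="\t")


def harmonize(
    summary: SummaryStats,
    g: GenotypeMatrix,
    policy: Literal["keep", "drop"] = "keep",
) -> tuple[SummaryStats, dict[str, int]]:
    """Match reference variants to the genotype panel and orient dosages.

    Returns the matched summary subset and an orientation map
    ``variant id -> +1`` (counted allele is the effect allele: use the dosage
    as-is) or ``-1`` (counted allele is the other allele: score ``2 - dosage``).
    Matching tries the allele pair directly, then its strand complement;
    irreconcilable pairs are dropped with a warning, and palindromic (A/T or
    G/C) variants are dropped when ``policy='drop'``.
    """
    geno_alleles = {
        v.id: (v.allele_counted, v.allele_other) for v in g.variants
    }
    orientation: dict[str, int] = {}
    keep_rows = []
    dropped: list[str] = []
    for row in summary.table.itertuples(index=False):
        alleles = geno_alleles.get(row.SNP)
        if alleles is None:
            continue
        counted, other = alleles
        eff, alt = str(row.A1), str(row.A2)
        if _is_palindromic(eff, alt) and policy == "drop":
            dropped.append(row.SNP)
            continue
        if (counted, other) == (eff, alt):
            flip = +1
        elif (counted, other) == (alt, eff):
            flip = -1
        elif (counted, other) == (_complement(eff), _complement(alt)):
            flip = +1
        elif (counted, other) == (_complement(alt), _complement(eff)):
            flip = -1
        else:
            dropped.append(row.SNP)
            continue
        orientation[row.SNP] = flip
        keep_rows.append(row)
    if dropped:
        warnings.warn(
            f"harmonize dropped {len(dropped)} variants "
            f"(unresolvable or palindromic): {dropped[:5]}..."
        )
    if not keep_rows:
        raise ValueError("no variants shared between summary stats and genotypes")
    matched = SummaryStats(pd.DataFrame(keep_rows))
    return matched, orientation


def _pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete dosages."""
    ok = ~(np.isnan(d1) | np.isnan(d2))
    if ok.sum() < 2:
        return 0.0
    x, y = d1[ok], d2[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_clump(
    summary: SummaryStats, g: GenotypeMatrix, cfg: PRSConfig | None = None
) -> list[str]:
    """Greedy LD clumping to an approximately independent variant set.

    Repeatedly promotes the unclaimed variant with the smallest association P
    to index status and claims every unclaimed variant on the same chromosome
    within ``clump_window_kb`` kb (|position difference| <= window x 1000)
    whose genotype r^2 with the index is at least ``clump_r2``.  Ties on P
    break by position then id.  Returns retained (index) variant ids in
    promotion order.
    """
    cfg = cfg or PRSConfig()
    vidx = g.variant_index()
    missing = [s for s in summary.table["SNP"] if s not in vidx]
    if missing:
        raise ValueError(f"summary variants absent from genotypes: {missing[:5]}")
    info = []
    for row in summary.table.itertuples(index=False):
        v = g.variants[vidx[row.SNP]]
        info.append((float(row.P), v.position, v.id, v.chromosome, vidx[row.SNP]))
    info.sort(key=lambda t: (t[0], t[1], t[2]))

    window_bp = cfg.clump_window_kb * 1000.0
    claimed: set[str] = set()
    retained: list[str] = []
    for p, pos, vid, chrom, col in info:
        if vid in claimed:
            continue
        retained.append(vid)
        claimed.add(vid)
        for p2, pos2, vid2, chrom2, col2 in info:
            if vid2 in claimed or chrom2 != chrom:
                continue
            if abs(pos2 - pos) > window_bp:
                continue
            if _pairwise_r2(g.dosage[:, col], g.dosage[:, col2]) >= cfg.clump_r2:
                claimed.add(vid2)
    return retained


def score(
    g: GenotypeMatrix,
    summary: SummaryStats,
    retained: Sequence[str],
    cfg: PRSConfig | None = None,
    orientation: dict[str, int] | None = None,
    missing_policy: Literal["mean", "omit"] = "mean",
) -> PRSProfile:
    """Sum ln(OR)-weighted oriented dosages at each P-value threshold.

    ``score_i(Pt) = sum over retained variants with P < Pt of
    ln(OR) x oriented dosage``, where a ``-1`` orientation reflects the
    dosage to ``2 - dosage``.  Missing dosages contribute the variant's mean
    oriented dosage among non-missing individuals (``missing_policy='mean'``,
    the common scoring-tool default) or nothing (``'omit'``).
    """
    cfg = cfg or PRSConfig()
    orientation = orientation or {}
    vidx = g.variant_index()
    tab = summary.table.set_index("SNP")
    cols, weights = [], []
    pvals = []
    for vid in retained:
        if vid not in tab.index:
            raise ValueError(f"retained variant {vid} absent from summary stats")
        if vid not in vidx:
            raise ValueError(f"retained variant {vid} absent from genotypes")
        d = g.dosage[:, vidx[vid]].copy()
        if orientation.get(vid, +1) < 0:
            d = 2.0 - d
        if missing_policy == "mean":
            mean = np.nanmean(d) if np.isfinite(np.nanmean(d)) else 0.0
            d = np.where(np.isnan(d), mean, d)
        else:
            d = np.nan_to_num(d, nan=0.0)
        cols.append(d)
        weights.append(np.log(float(tab.loc[vid, "OR"])))
        pvals.append(float(tab.loc[vid, "P"]))
    dmat = np.column_stack(cols) if cols else np.zeros((g.n_individuals, 0))
    wvec = np.asarray(weights)
    pvec = np.asarray(pvals)

    raw = {}
    n_used = {}
    for t in cfg.thresholds:
        sel = pvec < t
        n_used[t] = int(sel.sum())
        if n_used[t] == 0:
            warnings.warn(f"threshold {t} selects zero variants; score is 0")
            raw[f"pt_{t:g}"] = np.zeros(g.n_individuals)
        else:
            raw[f"pt_{t:g}"] = dmat[:, sel] @ wvec[sel]
    raw_df = pd.DataFrame(raw, index=pd.Index(g.individual_ids, name="id"))
    return PRSProfile(raw=raw_df, n_snps_used=n_used)


def standardize(profile: PRSProfile) -> PRSProfile:
    """Z-score each threshold column to sample mean 0 and SD 1 (ddof=1)."""
    if len(profile.raw) < 2:
        raise ValueError("standardization needs at least 2 individuals")
    z = {}
    for col in profile.raw.columns:
        x = profile.raw[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in score column {col!r}")
        z[col] = (x - x.mean()) / sd
    return PRSProfile(
        raw=profile.raw,
        n_snps_used=dict(profile.n_snps_used),
        z=pd.DataFrame(z, index=profile.raw.index),
    )


def compute_prs(
    g: GenotypeMatrix,
    summary: SummaryStats,
    cfg: PRSConfig | None = None,
) -> PRSProfile:
    """Full pipeline: harmonize, clump, score at all thresholds, standardize."""
    cfg = cfg or PRSConfig()
    matched, orientation = harmonize(summary, g, cfg.palindromic_policy)
    retained = ld_clump(matched, g, cfg)
    profile = score(g, matched, retained, cfg, orientation)
    return standardize(profile)
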