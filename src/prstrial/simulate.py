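"""Synthetic genotypes, GWAS summary statistics, and a two-arm trial cohort.

The generator emulates the study conditions the pipeline was built for: a
randomized trial of social skills group training (SSGT) versus standard care
in autistic children and adolescents, with 188 genotyped participants
(99 SSGT / 89 standard care) recruited at 13 clinical centers, parent-rated
SRS totals (0-195) at pre-intervention, post-intervention and 3-month
follow-up, and dropout leaving 169 individuals at post and 152 at follow-up.

Genotypes get block-diagonal LD through a Gaussian copula: each haplotype is
a latent multivariate-normal draw with compound-symmetric within-block
correlation, thresholded at the MAF quantile.  Summary statistics come from
a simulated reference GWAS; outcomes follow a linear mixed model with
center and individual random intercepts and configurable PRS x time x arm
interaction effects, so every downstream stage has a known truth to recover.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .io import MISSING, GenotypeMatrix, SummaryStats, TrialCohort, TIMEPOINTS, VariantRecord

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_ld_genotypes",
    "simulate_summary_stats",
    "simulate_trial_cohort",
    "inject_missingness",
    "simulate_all",
]


@dataclasses.dataclass
class SimConfig:
    """Generating parameters for one synthetic study.

    Effect sizes are in SRS points per standard deviation of true polygenic
    score; variance components (``center_sd``, ``individual_sd``,
    ``residual_sd``) are in SRS points.  ``prs_time_beta`` and
    ``prs_time_arm_beta`` give one value per non-baseline timepoint
    (post, followup).
    """

    n_individuals: int = 188
    n_variants: int = 400
    ld_block_sizes: Sequence[int] | None = None  # default: blocks of 8
    within_block_r: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_centers: int = 13
    arm_sizes: tuple[int, int] = (99, 89)  # (SSGT, standard_care)
    timepoints: tuple[str, ...] = TIMEPOINTS
    # observed 169/188 at post and 152/188 at follow-up
    dropout_rates: tuple[float, float, float] = (0.0, 19 / 188, 36 / 188)
    baseline_srs: float = 95.0
    time_effects: tuple[float, float] = (-5.0, -6.0)  # post, followup vs pre
    arm_time_effects: tuple[float, float] = (-3.0, -3.0)  # extra SSGT change
    prs_main_beta: float = 0.0
    prs_time_beta: tuple[float, float] = (0.0, 0.0)
    prs_time_arm_beta: tuple[float, float] = (0.0, 0.0)
    center_sd: float = 3.0
    individual_sd: float = 15.0
    residual_sd: float = 8.0
    cnv_carrier_rate: float = 0.10
    comorbidity_prs_shift: float = 0.5  # logit shift per PRS SD
    male_fraction: float = 0.75
    n_causal: int | None = None  # default: one fifth of the variants
    effect_sd: float = 0.1  # log-OR units
    gwas_n: int = 50_000
    seed: int = 0

    def block_sizes(self) -> list[int]:
        if self.ld_block_sizes is not None:
            return list(self.ld_block_sizes)
        full, rem = divmod(self.n_variants, 8)
        return [8] * full + ([rem] if rem else [])

    def validate(self) -> None:
        if sum(self.arm_sizes) != self.n_individuals:
            raise ValueError(
                f"arm sizes {self.arm_sizes} must sum to n_individuals={self.n_individuals}"
            )
        if sum(self.block_sizes()) != self.n_variants:
            raise ValueError(
                f"ld_block_sizes sum to {sum(self.block_sizes())}, "
                f"expected n_variants={self.n_variants}"
            )
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for sd in (self.center_sd, self.individual_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("variance-component SDs must be >= 0")
        if len(self.dropout_rates) != len(self.timepoints):
            raise ValueError("need one dropout rate per timepoint")
        if self.dropout_rates[0] != 0:
            raise ValueError("dropout never removes the pre timepoint")
        if any(not (0 <= r < 1) for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


@dataclasses.dataclass
class SimOutput:
    """One complete synthetic study plus the truth that generated it."""

    genotypes: GenotypeMatrix
    summary_stats: SummaryStats
    cohort: TrialCohort
    truth: dict


def simulate_ld_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw additive genotypes with block-diagonal LD via a Gaussian copula.

    Each of the two haplotypes per individual is a latent MVN vector with
    correlation ``within_block_r`` inside each block (compound symmetry) and
    0 across blocks; an allele is the minor allele when its latent value
    falls below the normal quantile of the variant's MAF.  Dosages count the
    minor allele.  Blocks are laid along chromosome 1 with 10 kb spacing
    within a block and 2 Mb gaps between blocks, so default clumping windows
    never span blocks.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    blocks = cfg.block_sizes()
    n, m = cfg.n_individuals, cfg.n_variants
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    hap_alleles = np.empty((2, n, m), dtype=float)
    col = 0
    for size in blocks:
        r = cfg.within_block_r
        for h in range(2):
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, size))
            latent = np.sqrt(r) * shared + np.sqrt(1 - r) * own
            hap_alleles[h, :, col : col + size] = (
                latent < thresholds[col : col + size]
            ).astype(float)
        col += size

    dosage = hap_alleles.sum(axis=0)

    variants = []
    pos = 1
    col = 0
    for b, size in enumerate(blocks):
        for k in range(size):
            variants.append(
                VariantRecord(
                    id=f"rs{col + 1}",
                    chromosome="1",
                    position=pos,
                    allele_counted="A",
                    allele_other="G",
                )
            )
            pos += 10_000
            col += 1
        pos += 2_000_000
    ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosage, ids, variants)


def simulate_summary_stats(
    genotypes: GenotypeMatrix,
    n_causal: int,
    effect_sd: float,
    gwas_n: int,
    seed: int,
) -> tuple[SummaryStats, dict]:
    """Simulate a reference-GWAS summary table over the cohort's variants.

    The first ``n_causal`` variants (a random draw) get true log odds ratios
    from N(0, effect_sd^2); the rest are null.  Each variant's estimate is
    the truth plus sampling noise with standard error
    1 / sqrt(2 n p (1 - p)) for allele frequency p, the usual large-sample
    approximation for an additive per-allele effect at sample size n.  The
    two-sided P comes from the Wald z.  Returns the stats and a truth record
    (causal ids and true log-ORs).
    """
    m = genotypes.n_variants
    if n_causal > m:
        raise ValueError(f"n_causal={n_causal} exceeds variant count {m}")
    rng = np.random.default_rng(seed)
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=n_causal, replace=False)] = True
    true_beta = np.where(causal, rng.normal(0.0, effect_sd, size=m), 0.0)

    freq = np.clip(genotypes.counted_allele_freq(), 0.01, 0.99)
    se = 1.0 / np.sqrt(2.0 * gwas_n * freq * (1.0 - freq))
    beta_hat = true_beta + rng.normal(0.0, se)
    z = beta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    import pandas as pd

    table = pd.DataFrame(
        {
            "SNP": genotypes.variant_ids(),
            "CHR": [v.chromosome for v in genotypes.variants],
            "BP": [v.position for v in genotypes.variants],
            "A1": [v.allele_counted for v in genotypes.variants],
            "A2": [v.allele_other for v in genotypes.variants],
            "OR": np.exp(beta_hat),
            "P": pvals,
        }
    )
    truth = {
        "causal_ids": [v.id for v, c in zip(genotypes.variants, causal) if c],
        "true_log_or": dict(zip(genotypes.variant_ids(), true_beta)),
    }
    return SummaryStats(table), truth


def _true_prs(genotypes: GenotypeMatrix, truth: dict) -> np.ndarray:
    """Standardized true polygenic score: dosage . true log-OR, z-scored."""
    beta = np.array([truth["true_log_or"][vid] for vid in genotypes.variant_ids()])
    dos = np.nan_to_num(genotypes.dosage, nan=0.0)
    raw = dos @ beta
    sd = raw.std(ddof=1)
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def simulate_trial_cohort(
    genotypes: GenotypeMatrix,
    summary_stats: SummaryStats,
    cfg: SimConfig,
    truth: dict | None = None,
) -> tuple[TrialCohort, dict]:
    """Simulate arms, centers, covariates, and longitudinal SRS outcomes.

    SRS(i, t) = baseline + time effect + SSGT-by-time effect
              + PRS terms (main, PRS x time, PRS x time x arm)
              + center intercept + individual intercept + residual,
    rounded to an integer and truncated to the instrument range [0, 195].
    Dropout removes post/follow-up records completely at random at the
    configured per-timepoint rates.  The PRS entering the generating model is
    the standardized true-score (dosages weighted by true log-ORs); when no
    ``truth`` is supplied every true weight is treated as zero and a pure
    noise PRS standard normal draw is used instead.
    """
    cfg.validate()
    n = genotypes.n_individuals
    if n != cfg.n_individuals:
        raise ValueError("genotype matrix and SimConfig disagree on n_individuals")
    rng = np.random.default_rng(cfg.seed + 1)

    import pandas as pd

    prs_true = (
        _true_prs(genotypes, truth)
        if truth is not None
        else rng.standard_normal(n)
    )

    arm = np.array(
        ["SSGT"] * cfg.arm_sizes[0] + ["standard_care"] * cfg.arm_sizes[1]
    )
    rng.shuffle(arm)
    center = rng.integers(0, cfg.n_centers, size=n)
    age_group = np.where(rng.random(n) < 0.5, "child", "adolescent")
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    pcs = rng.standard_normal((n, 4))
    cnv_clinsig = (rng.random(n) < cfg.cnv_carrier_rate).astype(int)
    cnv_large = np.maximum(
        cnv_clinsig, (rng.random(n) < cfg.cnv_carrier_rate).astype(int)
    )
    # comorbidity probability rises with true PRS on the logit scale
    logit = -0.5 + cfg.comorbidity_prs_shift * prs_true
    adhd_comorbid = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    individuals = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "arm": arm,
            "center": [f"center{c + 1}" for c in center],
            "age_group": age_group,
            "sex": sex,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
            "cnv_clinsig": cnv_clinsig,
            "cnv_large": cnv_large,
            "adhd_comorbid": adhd_comorbid,
            "prs_true": prs_true,
        }
    )

    center_u = rng.normal(0.0, cfg.center_sd, size=cfg.n_centers)
    indiv_u = rng.normal(0.0, cfg.individual_sd, size=n)
    is_ssgt = (arm == "SSGT").astype(float)

    rows = []
    for t_idx, tp in enumerate(cfg.timepoints):
        mu = np.full(n, cfg.baseline_srs)
        mu += cfg.prs_main_beta * prs_true
        if t_idx > 0:
            k = t_idx - 1
            mu += cfg.time_effects[k]
            mu += cfg.arm_time_effects[k] * is_ssgt
            mu += cfg.prs_time_beta[k] * prs_true
            mu += cfg.prs_time_arm_beta[k] * prs_true * is_ssgt
        y = mu + center_u[center] + indiv_u + rng.normal(0.0, cfg.residual_sd, size=n)
        y = np.clip(np.rint(y), 0, 195)
        keep = rng.random(n) >= cfg.dropout_rates[t_idx]
        if t_idx == 0:
            keep[:] = True
        for i in np.flatnonzero(keep):
            rows.append((genotypes.individual_ids[i], tp, int(y[i])))
    outcomes = pd.DataFrame(rows, columns=["id", "timepoint", "srs_total"])

    cohort_truth = {
        "config": dataclasses.asdict(cfg),
        "prs_true": dict(zip(genotypes.individual_ids, prs_true)),
        "center_sd": cfg.center_sd,
        "individual_sd": cfg.individual_sd,
        "residual_sd": cfg.residual_sd,
        "prs_main_beta": cfg.prs_main_beta,
        "prs_time_beta": list(cfg.prs_time_beta),
        "prs_time_arm_beta": list(cfg.prs_time_arm_beta),
    }
    return TrialCohort(individuals, outcomes), cohort_truth


def inject_missingness(
    genotypes: GenotypeMatrix,
    marker_rate: float,
    individual_rate: float,
    seed: int,
) -> GenotypeMatrix:
    """Blank genotype calls at random for QC testing.

    Two independent entry-level Bernoulli masks are drawn, one at
    ``marker_rate`` and one at ``individual_rate``, and their union is set to
    missing; with either rate at 0 the other marginal missing fraction is
    exactly the requested rate in expectation (with both nonzero the
    combined entry rate is ``1 - (1-m)(1-i)``).  Retained entries are
    unchanged.
    """
    for r in (marker_rate, individual_rate):
        if not (0 <= r < 1):
            raise ValueError("missingness rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = genotypes.dosage.shape
    mask = rng.random(shape) < marker_rate
    mask |= rng.random(shape) < individual_rate
    out = genotypes.copy()
    out.dosage[mask] = MISSING
    return out


def simulate_all(cfg: SimConfig) -> SimOutput:
    """Full study draw: genotypes, reference summary stats, trial cohort."""
    genotypes = simulate_ld_genotypes(cfg)
    n_causal = cfg.n_causal if cfg.n_causal is not None else cfg.n_variants // 5
    summary, gwas_truth = simulate_summary_stats(
        genotypes, n_causal, cfg.effect_sd, cfg.gwas_n, seed=cfg.seed + 2
    )
    cohort, cohort_truth = simulate_trial_cohort(genotypes, summary, cfg, gwas_truth)
    truth = {**gwas_truth, **cohort_truth}
    return SimOutput(genotypes, summary, cohort, truth)
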