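"""PRS engine: harmonization, clumping and scoring against loop oracles."""

import numpy as np
import pandas as pd
import pytest

from prstrial.io import GenotypeMatrix, SummaryStats, VariantRecord
from prstrial.prs import (
    PRSConfig,
    compute_prs,
    harmonize,
    ld_clump,
    score,
    standardize,
)


def _geno(dosage, variants):
    ids = [f"i{k}" for k in range(len(dosage))]
    return GenotypeMatrix(np.asarray(dosage, dtype=float), ids, variants)


def _summary(rows):
    return SummaryStats(
        pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "OR", "P"])
    )


class TestHarmonize:
    def test_counted_equals_effect_allele_as_is(self):
        g = _geno([[0], [1], [2]], [VariantRecord("rs1", "1", 10, "A", "G")])
        ss = _summary([("rs1", "1", 10, "A", "G", 2.0, 0.01)])
        matched, orient = harmonize(ss, g)
        assert orient == {"rs1": +1}
        assert len(matched) == 1

    def test_flip_reflects_dosage_in_score(self):
        """Counted allele = other allele: score must equal ln(OR) * (2 - dosage)."""
        g = _geno([[0], [1], [2]], [VariantRecord("rs1", "1", 10, "G", "A")])
        ss = _summary([("rs1", "1", 10, "A", "G", np.e, 0.01)])
        matched, orient = harmonize(ss, g)
        assert orient == {"rs1": -1}
        prof = score(g, matched, ["rs1"], PRSConfig(thresholds=(1.0,)), orient)
        np.testing.assert_allclose(
            prof.raw["pt_1"].to_numpy(), [2.0, 1.0, 0.0]
        )

    def test_strand_complement_resolved(self):
        g = _geno([[1]], [VariantRecord("rs1", "1", 10, "T", "C")])  # complement of A/G
        ss = _summary([("rs1", "1", 10, "A", "G", 1.5, 0.1)])
        _, orient = harmonize(ss, g)
        assert orient == {"rs1": +1}

    def test_palindromic_dropped_by_policy(self):
        g = _geno(
            [[1, 1]],
            [
                VariantRecord("rs1", "1", 10, "A", "T"),
                VariantRecord("rs2", "1", 20, "C", "G"),
            ],
        )
        ss = _summary(
            [
                ("rs1", "1", 10, "A", "T", 1.5, 0.1),
                ("rs2", "1", 20, "C", "G", 1.2, 0.2),
            ]
        )
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="no variants"):
                harmonize(ss, g, policy="drop")

    def test_irreconcilable_alleles_dropped(self):
        g = _geno(
            [[1, 0]],
            [
                VariantRecord("rs1", "1", 10, "A", "C"),
                VariantRecord("rs2", "1", 20, "A", "G"),
            ],
        )
        ss = _summary(
            [
                ("rs1", "1", 10, "A", "G", 1.5, 0.1),  # C vs G: unresolvable
                ("rs2", "1", 20, "A", "G", 1.2, 0.2),
            ]
        )
        with pytest.warns(UserWarning, match="dropped"):
            matched, orient = harmonize(ss, g)
        assert list(matched.table["SNP"]) == ["rs2"]


def greedy_clump_oracle(summary, g, r2_cut, window_bp):
    """Exhaustive greedy clumping recomputing every pairwise r^2 from scratch."""
    vidx = g.variant_index()
    items = []
    for row in summary.table.itertuples(index=False):
        v = g.variants[vidx[row.SNP]]
        items.append((row.P, v.position, v.id, v.chromosome))
    items.sort()
    removed = set()
    kept = []
    for p, pos, vid, chrom in items:
        if vid in removed:
            continue
        kept.append(vid)
        for p2, pos2, vid2, chrom2 in items:
            if vid2 == vid or vid2 in removed or vid2 in kept:
                continue
            if chrom2 != chrom or abs(pos2 - pos) > window_bp:
                continue
            a = g.dosage[:, vidx[vid]]
            b = g.dosage[:, vidx[vid2]]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 >= r2_cut:
                removed.add(vid2)
    return kept


class TestLDClump:
    def test_perfect_ld_keeps_smallest_p(self):
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        g = _geno(
            np.column_stack([col, col, col]),
            [VariantRecord(f"rs{j}", "1", 100 * j + 1, "A", "G") for j in range(3)],
        )
        ss = _summary(
            [
                ("rs0", "1", 1, "A", "G", 1.2, 0.01),
                ("rs1", "1", 101, "A", "G", 1.2, 0.001),
                ("rs2", "1", 201, "A", "G", 1.2, 0.02),
            ]
        )
        assert ld_clump(ss, g) == ["rs1"]

    def test_uncorrelated_variants_all_retained(self, rng):
        dosage = rng.integers(0, 3, size=(2000, 4)).astype(float)
        g = _geno(
            dosage,
            [VariantRecord(f"rs{j}", "1", 1000 * j + 1, "A", "G") for j in range(4)],
        )
        ss = _summary(
            [(f"rs{j}", "1", 1000 * j + 1, "A", "G", 1.1, 0.05) for j in range(4)]
        )
        assert sorted(ld_clump(ss, g)) == ["rs0", "rs1", "rs2", "rs3"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_var = 50
        dosage = rng.integers(0, 3, size=(5, n_var)).astype(float)
        variants = [
            VariantRecord(
                f"rs{j}", str(rng.integers(1, 3)), int(rng.integers(1, 400_000)),
                "A", "G",
            )
            for j in range(n_var)
        ]
        g = _geno(dosage, variants)
        ss = _summary(
            [
                (v.id, v.chromosome, v.position, "A", "G", 1.1,
                 float(rng.uniform(1e-6, 1)))
                for v in variants
            ]
        )
        cfg = PRSConfig(clump_r2=0.1, clump_window_kb=100)
        assert ld_clump(ss, g, cfg) == greedy_clump_oracle(ss, g, 0.1, 100_000)

    def test_clump_free_guarantee(self, default_study):
        """No two retained variants within the window share r^2 >= cutoff."""
        g = default_study.genotypes
        ss = default_study.summary_stats
        cfg = PRSConfig()
        kept = ld_clump(ss, g, cfg)
        vidx = g.variant_index()
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                va, vb = g.variants[vidx[a]], g.variants[vidx[b]]
                if va.chromosome != vb.chromosome:
                    continue
                if abs(va.position - vb.position) > cfg.clump_window_kb * 1000:
                    continue
                r = np.corrcoef(g.dosage[:, vidx[a]], g.dosage[:, vidx[b]])[0, 1]
                assert r * r < cfg.clump_r2

    def test_missing_variant_rejected(self):
        g = _geno([[1]], [VariantRecord("rs1", "1", 1, "A", "G")])
        ss = _summary([("rs9", "1", 1, "A", "G", 1.1, 0.5)])
        with pytest.raises(ValueError, match="absent"):
            ld_clump(ss, g)


class TestScore:
    def test_unit_weight_returns_dosage(self):
        g = _geno([[0], [1], [2]], [VariantRecord("rs1", "1", 1, "A", "G")])
        ss = _summary([("rs1", "1", 1, "A", "G", np.e, 0.5)])
        prof = score(g, ss, ["rs1"], PRSConfig(thresholds=(1.0,)))
        np.testing.assert_allclose(prof.raw["pt_1"].to_numpy(), [0.0, 1.0, 2.0])

    def test_five_default_thresholds_give_five_columns(self, default_study):
        prof = compute_prs(default_study.genotypes, default_study.summary_stats)
        assert list(prof.raw.columns) == [
            "pt_0.01", "pt_0.05", "pt_0.1", "pt_0.5", "pt_1",
        ]
        assert list(prof.z.columns) == list(prof.raw.columns)

    def test_matches_explicit_loop_oracle(self, rng):
        n, m = 5, 10
        dosage = rng.integers(0, 3, size=(n, m)).astype(float)
        dosage[rng.random((n, m)) < 0.1] = np.nan
        variants = [
            VariantRecord(f"rs{j}", "1", j * 1000 + 1, "A", "G") for j in range(m)
        ]
        g = _geno(dosage, variants)
        ors = rng.uniform(0.7, 1.5, size=m)
        ps = rng.uniform(0, 1, size=m)
        ss = _summary(
            [
                (f"rs{j}", "1", j * 1000 + 1, "A", "G", ors[j], ps[j])
                for j in range(m)
            ]
        )
        cfg = PRSConfig(thresholds=(0.25, 0.75, 1.0))
        prof = score(g, ss, [v.id for v in variants], cfg)

        for t in cfg.thresholds:
            for i in range(n):
                expected = 0.0
                for j in range(m):
                    if ps[j] >= t:
                        continue
                    d = dosage[i, j]
                    if np.isnan(d):
                        d = np.nanmean(dosage[:, j])
                    expected += np.log(ors[j]) * d
                assert prof.raw.iloc[i][f"pt_{t:g}"] == pytest.approx(expected)

    def test_monotone_inclusion_in_threshold(self, default_study):
        prof = compute_prs(default_study.genotypes, default_study.summary_stats)
        used = [prof.n_snps_used[t] for t in (0.01, 0.05, 0.1, 0.5, 1.0)]
        assert used == sorted(used)

    def test_score_linearity_over_disjoint_sets(self, rng):
        dosage = rng.integers(0, 3, size=(6, 8)).astype(float)
        variants = [
            VariantRecord(f"rs{j}", "1", j * 1000 + 1, "A", "G") for j in range(8)
        ]
        g = _geno(dosage, variants)
        ss = _summary(
            [
                (f"rs{j}", "1", j * 1000 + 1, "A", "G", 1.0 + 0.1 * j, 0.5)
                for j in range(8)
            ]
        )
        cfg = PRSConfig(thresholds=(1.0,))
        all_ids = [v.id for v in variants]
        total = score(g, ss, all_ids, cfg).raw["pt_1"]
        part1 = score(g, ss, all_ids[:4], cfg).raw["pt_1"]
        part2 = score(g, ss, all_ids[4:], cfg).raw["pt_1"]
        np.testing.assert_allclose(total, part1 + part2)

    def test_empty_threshold_warns_and_scores_zero(self):
        g = _geno([[1], [2]], [VariantRecord("rs1", "1", 1, "A", "G")])
        ss = _summary([("rs1", "1", 1, "A", "G", 1.5, 0.9)])
        with pytest.warns(UserWarning, match="zero variants"):
            prof = score(g, ss, ["rs1"], PRSConfig(thresholds=(0.01, 1.0)))
        assert prof.n_snps_used[0.01] == 0
        np.testing.assert_allclose(prof.raw["pt_0.01"], 0.0)


class TestStandardize:
    def test_symmetric_triplet(self):
        prof = _profile([1.0, 2.0, 3.0])
        z = standardize(prof).z["pt_1"].to_numpy()
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, default_study):
        prof = compute_prs(default_study.genotypes, default_study.summary_stats)
        for col in prof.z.columns:
            assert prof.z[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert prof.z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, rng):
        raw = rng.normal(size=20)
        z1 = standardize(_profile(raw)).z["pt_1"]
        z2 = standardize(_profile(3.5 * raw + 11.0)).z["pt_1"]
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="pt_1"):
            standardize(_profile([2.0, 2.0, 2.0]))


def _profile(values):
    from prstrial.prs import PRSProfile

    return PRSProfile(
        raw=pd.DataFrame(
            {"pt_1": values}, index=[f"i{k}" for k in range(len(values))]
        ),
        n_snps_used={1.0: 1},
    )
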