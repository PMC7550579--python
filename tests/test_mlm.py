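"""Mixed-model interaction analysis: design construction, estimation, R^2."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from prstrial.mlm import (
    MLMSpec,
    build_design,
    delta_r2,
    fit_mlm,
    interaction_estimates,
    nakagawa_r2,
    significance_threshold,
)
from prstrial.simulate import SimConfig, simulate_all


def _cohort_with_named_prs(study, name="adhd"):
    ind = study.cohort.individuals.copy()
    ind[f"prs_{name}"] = ind["prs_true"]
    from prstrial.io import TrialCohort

    return TrialCohort(ind, study.cohort.outcomes)


class TestSignificanceThreshold:
    def test_three_phenotypes_rounds_to_0_0167(self):
        assert significance_threshold(3, 0.05) == 0.0167

    def test_no_correction(self):
        assert significance_threshold(1, 0.05) == 0.05

    def test_exact_division(self):
        assert significance_threshold(5, 0.05) == 0.01

    def test_zero_phenotypes_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(0)


class TestBuildDesign:
    def test_three_way_has_exactly_two_triple_products(self, small_study):
        d = build_design(small_study.cohort, MLMSpec(prs_phenotype="true"))
        triples = [c for c in d.fixed_columns if c.count("_") >= 3 and "arm" in c]
        assert sorted(triples) == ["prs_t_follow_arm", "prs_t_post_arm"]

    def test_two_way_subset_drops_constant_arm_column(self, small_study):
        d = build_design(
            small_study.cohort,
            MLMSpec(prs_phenotype="true", interaction="two_way", arm_subset="SSGT"),
        )
        assert not any("arm" in c for c in d.fixed_columns)
        assert set(d.data["indiv"]) == set(
            small_study.cohort.individuals.query("arm == 'SSGT'")["id"]
        )

    def test_adhd_phenotype_forces_comorbidity_column(self, small_study):
        cohort = _cohort_with_named_prs(small_study, "adhd")
        d = build_design(cohort, MLMSpec(prs_phenotype="ADHD"))
        assert "adhd" in d.fixed_columns

    def test_cnv_adjustment_variants(self, small_study):
        for cnv in ("clinsig", "large"):
            d = build_design(
                small_study.cohort, MLMSpec(prs_phenotype="true", cnv_adjustment=cnv)
            )
            assert "cnv" in d.fixed_columns
        d = build_design(
            small_study.cohort, MLMSpec(prs_phenotype="true", cnv_adjustment="none")
        )
        assert "cnv" not in d.fixed_columns

    def test_missing_prs_column_rejected(self, small_study):
        with pytest.raises(ValueError, match="prs_asd"):
            build_design(small_study.cohort, MLMSpec(prs_phenotype="ASD"))

    def test_three_way_with_arm_subset_rejected(self):
        with pytest.raises(ValueError, match="arm subset"):
            MLMSpec(prs_phenotype="true", interaction="three_way", arm_subset="SSGT")


class TestFitMLM:
    def test_zero_variance_member_equals_ols(self):
        """GLS at pinned-zero random variance reproduces OLS exactly."""
        cfg = SimConfig(
            seed=13, center_sd=0.0, individual_sd=0.0, residual_sd=8.0,
            dropout_rates=(0, 0, 0), n_variants=64,
        )
        out = simulate_all(cfg)
        d = build_design(out.cohort, MLMSpec(prs_phenotype="true"))
        fit = fit_mlm(d, varcomp_fixed={"center": 0.0, "individual": 0.0})
        X = sm.add_constant(d.data[d.fixed_columns])
        ols = sm.OLS(d.data["srs_total"], X).fit()
        np.testing.assert_allclose(
            fit.beta.to_numpy(), ols.params.to_numpy(), atol=1e-4
        )
        np.testing.assert_allclose(fit.se.to_numpy(), ols.bse.to_numpy(), atol=1e-4)

    def test_reml_recovers_variance_components(self):
        """REML variance components sit near the generating values."""
        ests = []
        for seed in range(5):
            cfg = SimConfig(
                seed=seed, n_variants=32, center_sd=5.0, individual_sd=12.0,
                residual_sd=6.0, n_centers=20, dropout_rates=(0, 0, 0),
            )
            out = simulate_all(cfg)
            fit = fit_mlm(build_design(out.cohort, MLMSpec(prs_phenotype="true")))
            ests.append(
                [fit.varcomp["center"], fit.varcomp["individual"], fit.varcomp["residual"]]
            )
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(25.0, rel=0.8)  # 20 centers: noisy
        assert mean[1] == pytest.approx(144.0, rel=0.25)
        assert mean[2] == pytest.approx(36.0, rel=0.25)

    def test_ci_is_beta_pm_1p96_se(self, small_study):
        fit = fit_mlm(build_design(small_study.cohort, MLMSpec(prs_phenotype="true")))
        np.testing.assert_allclose(
            fit.ci95["lo"].to_numpy(), (fit.beta - 1.96 * fit.se).to_numpy()
        )
        assert all(v >= 0 for v in fit.varcomp.values())

    def test_single_center_rejected(self, small_study):
        d = build_design(small_study.cohort, MLMSpec(prs_phenotype="true"))
        d.data["center"] = "c1"
        with pytest.raises(ValueError, match="centers"):
            fit_mlm(d)


class TestInteractionEstimates:
    def test_planted_effect_detected_and_flagged(self, small_study):
        spec = MLMSpec(prs_phenotype="true")
        fit = fit_mlm(build_design(small_study.cohort, spec))
        table = interaction_estimates(fit, spec)
        assert list(table["term"]) == ["PRS x post x SSGT", "PRS x followup x SSGT"]
        row = table.set_index("term").loc["PRS x followup x SSGT"]
        assert row["ci_lo"] < 6.7 < row["ci_hi"] or row["p"] < 0.05

    def test_threshold_boundary_flags(self):
        """P just under / just over alpha/3 flips the significance flag."""
        assert (0.016 < significance_threshold(3)) is True
        assert (0.019 < significance_threshold(3)) is False

    def test_permuted_prs_gives_null_betas(self, small_study):
        """Permuting PRS across individuals breaks the interaction (|z| < 3)."""
        rng = np.random.default_rng(5)
        hits = 0
        runs = 20
        for _ in range(runs):
            ind = small_study.cohort.individuals.copy()
            ind["prs_true"] = rng.permutation(ind["prs_true"].to_numpy())
            from prstrial.io import TrialCohort

            cohort = TrialCohort(ind, small_study.cohort.outcomes)
            spec = MLMSpec(prs_phenotype="true")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_mlm(build_design(cohort, spec))
            term = "prs_t_follow_arm"
            z = abs(fit.beta[term] / fit.se[term])
            hits += z < 3
        assert hits >= runs - 1

    def test_absent_term_raises(self, small_study):
        spec = MLMSpec(prs_phenotype="true")
        fit = fit_mlm(build_design(small_study.cohort, spec))
        fit.design.interaction_terms["bogus"] = "no_such_term"
        with pytest.raises(KeyError, match="no_such_term"):
            interaction_estimates(fit, spec)


class TestNakagawaR2:
    def test_zero_fixed_coefficients_zero_marginal(self, small_study):
        spec = MLMSpec(prs_phenotype="true")
        fit = fit_mlm(build_design(small_study.cohort, spec))
        fit.fitted_fixed = np.zeros_like(fit.fitted_fixed)
        pair = nakagawa_r2(fit)
        assert pair.marginal == 0.0
        assert pair.conditional > 0.0

    def test_no_random_variance_marginal_equals_conditional(self, small_study):
        spec = MLMSpec(prs_phenotype="true")
        fit = fit_mlm(build_design(small_study.cohort, spec))
        fit.varcomp["center"] = 0.0
        fit.varcomp["individual"] = 0.0
        pair = nakagawa_r2(fit)
        assert pair.marginal == pytest.approx(pair.conditional)

    def test_bounds_and_ordering(self, small_study, default_study):
        for study in (small_study, default_study):
            spec = MLMSpec(prs_phenotype="true")
            fit = fit_mlm(build_design(study.cohort, spec))
            pair = nakagawa_r2(fit)
            assert 0.0 <= pair.marginal <= pair.conditional <= 1.0

    def test_recovers_known_variance_shares(self):
        """Marginal R^2 matches the generating fixed-variance share."""
        # PRS main effect beta=8 on z-scored PRS -> fixed var 64 (plus small
        # time/arm contributions set to zero here)
        marginals = []
        for seed in range(8):
            cfg = SimConfig(
                seed=seed, n_variants=32, prs_main_beta=8.0,
                time_effects=(0.0, 0.0), arm_time_effects=(0.0, 0.0),
                center_sd=4.0, individual_sd=10.0, residual_sd=6.0,
                dropout_rates=(0, 0, 0), n_centers=15,
            )
            out = simulate_all(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_mlm(build_design(out.cohort, MLMSpec(prs_phenotype="true")))
            marginals.append(nakagawa_r2(fit).marginal)
        expected = 64.0 / (64.0 + 16.0 + 100.0 + 36.0)
        assert np.mean(marginals) == pytest.approx(expected, rel=0.2)


class TestDeltaR2:
    def test_noise_prs_contributes_nothing(self):
        """A pure-noise PRS adds ~0 to both R^2 components."""
        rng = np.random.default_rng(3)
        deltas = []
        for seed in range(5):
            # large-n case: chance R^2 inflation from the 6 extra PRS terms
            # scales as terms/n_obs and must sit well under 0.01
            cfg = SimConfig(
                seed=seed, n_variants=32, n_individuals=600,
                arm_sizes=(300, 300), n_centers=20,
            )
            out = simulate_all(cfg)
            ind = out.cohort.individuals.copy()
            ind["prs_noise"] = rng.standard_normal(len(ind))
            from prstrial.io import TrialCohort

            cohort = TrialCohort(ind, out.cohort.outcomes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pair, _, _ = delta_r2(cohort, MLMSpec(prs_phenotype="noise"))
            deltas.append(pair.marginal)
        assert np.mean(deltas) < 0.01

    def test_planted_effect_increases_r2(self, small_study):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pair, full, red = delta_r2(small_study.cohort, MLMSpec(prs_phenotype="true"))
        assert pair.marginal > 0.0
        assert len(red.design.prs_terms) == 0
        assert all("prs" not in c for c in red.design.fixed_columns)

    def test_nesting_loglik_order(self, small_study):
        """ML log-likelihood of the full model dominates the reduced model."""
        from prstrial.mlm import _drop_prs

        full_d = build_design(small_study.cohort, MLMSpec(prs_phenotype="true"))
        red_d = _drop_prs(full_d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = fit_mlm(full_d, reml=False)
            red = fit_mlm(red_d, reml=False)
        assert full.loglik >= red.loglik - 1e-6
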