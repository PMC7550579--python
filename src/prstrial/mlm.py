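"""Mixed linear models for PRS-by-intervention interaction on SRS outcomes.

The primary model regresses the longitudinal SRS total on PRS x time x arm
(treatment contrasts: pre-intervention and standard care as references) plus
age group, sex, four ancestry PCs, an optional CNV-carrier flag and, for the
ADHD score, ADHD comorbidity, with random intercepts for clinical center and
for individual (individuals are nested in centers).  Estimation is REML via
``statsmodels`` MixedLM with Wald z inference; the contribution of the PRS
is summarized by Nakagawa-Schielzeth marginal/conditional R^2 differences
between the model with and without all PRS terms.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import TrialCohort

__all__ = [
    "MLMSpec",
    "MLMDesign",
    "MLMFit",
    "R2Pair",
    "build_design",
    "fit_mlm",
    "interaction_estimates",
    "significance_threshold",
    "nakagawa_r2",
    "delta_r2",
]


@dataclasses.dataclass
class MLMSpec:
    """Which PRS, which interaction structure, and which CNV adjustment.

    ``prs_phenotype`` names the cohort column ``prs_<phenotype.lower()>``;
    ADHD comorbidity is always adjusted for when the phenotype is ADHD.
    ``arm_subset`` restricts a two-way model to one intervention arm.
    """

    prs_phenotype: str = "true"
    interaction: Literal["three_way", "two_way"] = "three_way"
    cnv_adjustment: Literal["clinsig", "large", "none"] = "clinsig"
    adjust_adhd_comorbidity: bool = False
    arm_subset: str | None = None

    def __post_init__(self) -> None:
        if self.prs_phenotype.upper() == "ADHD":
            self.adjust_adhd_comorbidity = True
        if self.interaction == "three_way" and self.arm_subset is not None:
            raise ValueError("three-way models use all individuals (no arm subset)")

    @property
    def prs_column(self) -> str:
        return f"prs_{self.prs_phenotype.lower()}"


@dataclasses.dataclass
class MLMDesign:
    """Assembled long-format model frame with explicit fixed-effect columns."""

    data: pd.DataFrame  # includes srs_total, center, indiv and fixed columns
    fixed_columns: list[str]
    prs_terms: list[str]  # fixed columns involving the PRS
    interaction_terms: dict[str, str]  # readable label -> column name
    spec: MLMSpec


@dataclasses.dataclass
class MLMFit:
    """REML fit summary: coefficient table, variance components, likelihood."""

    beta: pd.Series
    se: pd.Series
    ci95: pd.DataFrame  # columns lo, hi
    p: pd.Series
    varcomp: dict[str, float]  # center, individual, residual
    loglik: float
    converged: bool
    n_obs: int
    n_individuals: int
    design: MLMDesign
    fitted_fixed: np.ndarray  # X @ beta on the estimation sample


@dataclasses.dataclass
class R2Pair:
    """Nakagawa-Schielzeth variance-explained pair."""

    marginal: float
    conditional: float


def significance_threshold(n_phenotypes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_phenotypes, rounded to 4 decimals."""
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    return round(alpha / n_phenotypes, 4)


def build_design(cohort: TrialCohort, spec: MLMSpec) -> MLMDesign:
    """Expand the cohort into an explicit fixed-effect design.

    Treatment coding throughout: time dummies ``t_post``/``t_follow``
    (reference pre), arm dummy ``arm_ssgt`` (reference standard care), so in
    the three-way model the products ``prs_t_post_arm``/``prs_t_follow_arm``
    read directly as the SRS-point difference per PRS SD at that timepoint
    in SSGT relative to standard care (positive = inferior SSGT outcome).
    The two-way model drops the arm factor and all its products.
    """
    col = spec.prs_column
    if col not in cohort.individuals.columns:
        raise ValueError(f"cohort has no PRS column {col!r}")
    long = cohort.long_table()
    if spec.arm_subset is not None:
        long = long[long["arm"] == spec.arm_subset]
        if long.empty:
            raise ValueError(f"no individuals in arm {spec.arm_subset!r}")

    d = pd.DataFrame(index=long.index)
    d["prs"] = long[col].to_numpy(dtype=float)
    d["t_post"] = (long["timepoint"] == "post").astype(float)
    d["t_follow"] = (long["timepoint"] == "followup").astype(float)
    d["prs_t_post"] = d["prs"] * d["t_post"]
    d["prs_t_follow"] = d["prs"] * d["t_follow"]
    interaction_terms: dict[str, str] = {}
    if spec.interaction == "three_way":
        d["arm_ssgt"] = (long["arm"] == "SSGT").astype(float)
        d["prs_arm"] = d["prs"] * d["arm_ssgt"]
        d["arm_t_post"] = d["arm_ssgt"] * d["t_post"]
        d["arm_t_follow"] = d["arm_ssgt"] * d["t_follow"]
        d["prs_t_post_arm"] = d["prs"] * d["t_post"] * d["arm_ssgt"]
        d["prs_t_follow_arm"] = d["prs"] * d["t_follow"] * d["arm_ssgt"]
        interaction_terms = {
            "PRS x post x SSGT": "prs_t_post_arm",
            "PRS x followup x SSGT": "prs_t_follow_arm",
        }
    else:
        interaction_terms = {
            "PRS x post": "prs_t_post",
            "PRS x followup": "prs_t_follow",
        }
    d["age_child"] = (long["age_group"] == "child").astype(float)
    d["sex_male"] = (long["sex"] == "male").astype(float)
    for k in range(1, 5):
        d[f"pc{k}"] = long[f"pc{k}"].to_numpy(dtype=float)
    if spec.cnv_adjustment == "clinsig":
        d["cnv"] = long["cnv_clinsig"].to_numpy(dtype=float)
    elif spec.cnv_adjustment == "large":
        d["cnv"] = long["cnv_large"].to_numpy(dtype=float)
    if spec.adjust_adhd_comorbidity:
        d["adhd"] = long["adhd_comorbid"].to_numpy(dtype=float)

    # drop constant columns (e.g. arm dummy within an arm subset)
    fixed_columns = [c for c in d.columns if d[c].nunique() > 1 or c == "prs"]
    d = d[fixed_columns]
    data = d.copy()
    data["srs_total"] = long["srs_total"].to_numpy(dtype=float)
    data["center"] = long["center"].to_numpy()
    data["indiv"] = long["id"].to_numpy()
    prs_terms = [c for c in fixed_columns if c.startswith("prs")]
    return MLMDesign(
        data=data.reset_index(drop=True),
        fixed_columns=fixed_columns,
        prs_terms=prs_terms,
        interaction_terms=interaction_terms,
        spec=spec,
    )


def _drop_prs(design: MLMDesign) -> MLMDesign:
    keep = [c for c in design.fixed_columns if c not in design.prs_terms]
    data = design.data[keep + ["srs_total", "center", "indiv"]].copy()
    return MLMDesign(
        data=data,
        fixed_columns=keep,
        prs_terms=[],
        interaction_terms={},
        spec=design.spec,
    )


def fit_mlm(
    design: MLMDesign,
    reml: bool = True,
    varcomp_fixed: dict[str, float] | None = None,
) -> MLMFit:
    """REML fit of the two-random-intercept model (center + individual).

    Individuals are treated as a variance component nested within the
    center grouping.  Wald z two-sided P values; a variance component
    estimated at 0 (singular fit) is a warning, not an error; outright
    non-convergence raises with diagnostics.

    ``varcomp_fixed`` pins the center/individual variances at given values
    instead of estimating them; the fixed effects are then the closed-form
    GLS solution at that covariance (with both pinned at 0 this is the
    degenerate mixed model, i.e. ordinary least squares).
    """
    if varcomp_fixed is not None:
        return _fit_gls_at(design, varcomp_fixed)
    data = design.data
    if data["center"].nunique() < 2:
        raise ValueError("need >= 2 centers for a center random intercept")
    formula = "srs_total ~ " + " + ".join(design.fixed_columns)
    model = sm.MixedLM.from_formula(
        formula,
        data=data,
        groups="center",
        re_formula="1",
        vc_formula={"individual": "0 + C(indiv)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method="lbfgs", maxiter=500)
        if not res.converged:
            # boundary fits (variance ~0) often trip gradient methods
            res = model.fit(reml=reml, method="powell", maxiter=2000)
        if not res.converged:
            res = model.fit(reml=reml, method="cg", maxiter=500)
    if not res.converged:
        raise RuntimeError(
            "mixed model did not converge; "
            f"n_obs={len(data)}, params={res.params.to_dict()}"
        )
    v_center = float(np.asarray(res.cov_re)[0, 0])
    v_indiv = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    v_resid = float(res.scale)
    if min(v_center, v_indiv) <= 1e-10:
        warnings.warn("singular fit: a random-effect variance is ~0")
    fe = res.fe_params
    se = res.bse_fe
    X = model.exog  # patsy design, Intercept first
    p = 2.0 * _norm_sf(np.abs(fe / se))
    ci = pd.DataFrame(
        {"lo": fe - 1.96 * se, "hi": fe + 1.96 * se}, index=fe.index
    )
    return MLMFit(
        beta=fe,
        se=se,
        ci95=ci,
        p=pd.Series(p, index=fe.index),
        varcomp={"center": v_center, "individual": v_indiv, "residual": v_resid},
        loglik=float(res.llf),
        converged=bool(res.converged),
        n_obs=len(data),
        n_individuals=data["indiv"].nunique(),
        design=design,
        fitted_fixed=np.asarray(X @ np.asarray(fe)),
    )


def _fit_gls_at(design: MLMDesign, varcomp: dict[str, float]) -> MLMFit:
    """Generalized least squares at pinned random-intercept variances.

    Builds V_g = s2_r I + s2_c 11' + s2_i Z_i Z_i' per center group and
    solves the mixed-model normal equations
    beta = (sum X' V^-1 X)^-1 sum X' V^-1 y directly.  The residual
    variance is profiled (REML-style denominator n - p).  Used for the
    degenerate zero-variance member and for diagnostics.
    """
    data = design.data
    cols = ["Intercept"] + design.fixed_columns
    Xall = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in design.fixed_columns]
    )
    yall = data["srs_total"].to_numpy(dtype=float)
    s2_c = float(varcomp.get("center", 0.0))
    s2_i = float(varcomp.get("individual", 0.0))
    s2_r = float(varcomp.get("residual", 1.0))

    xtvx = np.zeros((Xall.shape[1], Xall.shape[1]))
    xtvy = np.zeros(Xall.shape[1])
    all_indiv = data["indiv"].to_numpy()
    for _, idx in data.groupby("center", sort=True).groups.items():
        rows = data.index.get_indexer(idx)
        Xg = Xall[rows]
        yg = yall[rows]
        ng = len(rows)
        indiv = all_indiv[rows]
        V = s2_r * np.eye(ng) + s2_c * np.ones((ng, ng))
        Z = (indiv[:, None] == pd.unique(indiv)[None, :]).astype(float)
        V += s2_i * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        xtvx += Xg.T @ Vi @ Xg
        xtvy += Xg.T @ Vi @ yg
    beta = np.linalg.solve(xtvx, xtvy)
    if "residual" not in varcomp:
        # xtvx was built with the unit placeholder, so xtvx == X'X / 1;
        # profile the residual scale from the GLS residuals
        resid = yall - Xall @ beta
        s2_r = float(resid @ resid) / (len(yall) - Xall.shape[1])
        cov_beta = np.linalg.inv(xtvx) * s2_r
    else:
        cov_beta = np.linalg.inv(xtvx)
    fe = pd.Series(beta, index=cols)
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=cols)
    p = pd.Series(2.0 * _norm_sf(np.abs(beta) / se.to_numpy()), index=cols)
    ci = pd.DataFrame({"lo": fe - 1.96 * se, "hi": fe + 1.96 * se}, index=cols)
    return MLMFit(
        beta=fe,
        se=se,
        ci95=ci,
        p=p,
        varcomp={"center": s2_c, "individual": s2_i, "residual": s2_r},
        loglik=float("nan"),
        converged=True,
        n_obs=len(data),
        n_individuals=data["indiv"].nunique(),
        design=design,
        fitted_fixed=np.asarray(Xall @ beta),
    )


def _norm_sf(x):
    from scipy.stats import norm

    return norm.sf(x)


def interaction_estimates(fit: MLMFit, spec: MLMSpec, alpha: float = 0.05,
                          n_phenotypes: int = 3) -> pd.DataFrame:
    """Extract the PRS-by-time(-by-arm) rows with significance flags.

    Returns one row per non-baseline timepoint with beta, 95% CI, P, and a
    flag against the Bonferroni-style family threshold ``alpha/n_phenotypes``.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    thr = significance_threshold(n_phenotypes, alpha)
    rows = []
    for label, term in fit.design.interaction_terms.items():
        if term not in fit.beta.index:
            raise KeyError(f"term {term!r} absent from the fitted model")
        rows.append(
            {
                "term": label,
                "beta": float(fit.beta[term]),
                "se": float(fit.se[term]),
                "ci_lo": float(fit.ci95.loc[term, "lo"]),
                "ci_hi": float(fit.ci95.loc[term, "hi"]),
                "p": float(fit.p[term]),
                "significant": bool(fit.p[term] < thr),
                "threshold": thr,
            }
        )
    return pd.DataFrame(rows)


def nakagawa_r2(fit: MLMFit) -> R2Pair:
    """Variance explained by fixed effects (marginal) and fixed+random (conditional).

    marginal = var(Xb) / (var(Xb) + v_center + v_individual + v_residual);
    conditional adds both random-intercept variances to the numerator.
    """
    var_f = float(np.var(fit.fitted_fixed))
    v_c = fit.varcomp["center"]
    v_i = fit.varcomp["individual"]
    v_r = fit.varcomp["residual"]
    total = var_f + v_c + v_i + v_r
    if total <= 0:
        raise ValueError("zero total variance")
    return R2Pair(
        marginal=var_f / total,
        conditional=(var_f + v_c + v_i) / total,
    )


def delta_r2(cohort: TrialCohort, spec: MLMSpec) -> tuple[R2Pair, MLMFit, MLMFit]:
    """R^2 attributable to the PRS: full model minus the model with every
    PRS-containing term (main effect and all interactions) removed.

    Both models are fit by REML with otherwise identical fixed and random
    structure.  Returns the (marginal, conditional) differences plus both fits.
    """
    full_design = build_design(cohort, spec)
    red_design = _drop_prs(full_design)
    full = fit_mlm(full_design)
    red = fit_mlm(red_design)
    r_full = nakagawa_r2(full)
    r_red = nakagawa_r2(red)
    return (
        R2Pair(
            marginal=r_full.marginal - r_red.marginal,
            conditional=r_full.conditional - r_red.conditional,
        ),
        full,
        red,
    )


def r2_grid(
    cohort: TrialCohort,
    phenotypes: list[str],
    thresholds: list[str],
    cnv_adjustment: str = "clinsig",
) -> pd.DataFrame:
    """Delta-R^2 grid over phenotypes x P-value thresholds (report shape).

    ``thresholds`` are suffixes: the PRS columns are ``prs_<pheno>_<suffix>``.
    """
    rows = []
    for pheno in phenotypes:
        for t in thresholds:
            spec = MLMSpec(
                prs_phenotype=f"{pheno}_{t}", cnv_adjustment=cnv_adjustment
            )
            pair, _, _ = delta_r2(cohort, spec)
            rows.append(
                {
                    "phenotype": pheno,
                    "threshold": t,
                    "cnv_model": cnv_adjustment,
                    "delta_marginal_r2": pair.marginal,
                    "delta_conditional_r2": pair.conditional,
                }
            )
    return pd.DataFrame(rows)
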