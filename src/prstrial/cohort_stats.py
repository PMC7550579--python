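"""Descriptive associations among PRSs, comorbidity, IQ, and CNV status."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["CorrResult", "TTestResult", "pearson_corr", "group_t_test", "prs_cnv_interaction"]


@dataclasses.dataclass
class CorrResult:
    r: float
    p: float
    n: int


@dataclasses.dataclass
class TTestResult:
    t: float
    p: float
    df: float
    group_means: tuple[float, float]


def pearson_corr(x, y) -> CorrResult:
    """Sample Pearson correlation with the t-distribution two-sided P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrResult(r=float(r), p=float(p), n=len(x))


def group_t_test(values, groups, equal_var: bool = True) -> TTestResult:
    """Two-sided Student's t test between the two label groups.

    Equal-variance (pooled) by default with df = n1 + n2 - 2; set
    ``equal_var=False`` for Welch.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.sort(np.unique(groups))  # deterministic group order
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 members")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=float(df),
        group_means=(float(a.mean()), float(b.mean())),
    )


def prs_cnv_interaction(
    change: pd.Series,
    prs: pd.Series,
    cnv: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of SRS change on PRS, CNV-carrier flag, their product, and covariates.

    All inputs are aligned on their (individual-id) index; returns the full
    coefficient table with the ``prs_x_cnv`` row carrying the interaction.
    """
    idx = change.index.intersection(prs.index).intersection(cnv.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    y = change.loc[idx].to_numpy(dtype=float)
    c = cnv.loc[idx].to_numpy(dtype=float)
    n_carriers = int(c.sum())
    if n_carriers < 2 or len(c) - n_carriers < 2:
        raise ValueError(
            f"need >= 2 carriers and >= 2 noncarriers (got {n_carriers}/{len(c)})"
        )
    X = pd.DataFrame(index=idx)
    X["prs"] = prs.loc[idx].to_numpy(dtype=float)
    X["cnv"] = c
    X["prs_x_cnv"] = X["prs"] * X["cnv"]
    if covariates is not None:
        for col in covariates.columns:
            X[col] = covariates.loc[idx, col].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    ci = res.conf_int()
    return pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
            "p": res.pvalues,
        }
    )
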