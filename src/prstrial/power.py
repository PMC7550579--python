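"""Cluster-bootstrap power estimation for the PRS interaction effect.

Individuals (with all their longitudinal records) are resampled with
replacement to a target size, duplicates receive fresh ids so the
individual random intercept stays well defined, the mixed model is refit,
and power is the fraction of converged fits whose target term reaches
P < alpha.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import TrialCohort
from .mlm import MLMSpec, build_design, fit_mlm

__all__ = ["PowerPoint", "bootstrap_power"]


@dataclasses.dataclass
class PowerPoint:
    """Power estimate at one target sample size."""

    n: int
    power: float
    mc_se: float
    reps: int
    alpha: float
    n_nonconverged: int
    warning: str | None = None


def resample_cohort(cohort: TrialCohort, n: int, rng: np.random.Generator) -> TrialCohort:
    """Draw ``n`` individuals with replacement, relabelling duplicates.

    Every resampled individual keeps its center, covariates and all observed
    timepoints; copies are distinct individuals for the random-effect
    grouping.
    """
    ids = cohort.individuals["id"].to_numpy()
    picks = rng.choice(len(ids), size=n, replace=True)
    ind = cohort.individuals.iloc[picks].copy().reset_index(drop=True)
    new_ids = [f"bs{k}_{ids[i]}" for k, i in enumerate(picks)]
    ind["id"] = new_ids
    out_by_id = {i: sub for i, sub in cohort.outcomes.groupby("id")}
    frames = []
    for new_id, i in zip(new_ids, picks):
        sub = out_by_id[ids[i]].copy()
        sub["id"] = new_id
        frames.append(sub)
    outcomes = pd.concat(frames, ignore_index=True)
    return TrialCohort(ind, outcomes)


def bootstrap_power(
    cohort: TrialCohort,
    spec: MLMSpec,
    target_term: str,
    sizes: list[int],
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PowerPoint]:
    """Estimate rejection power of ``target_term`` at each target size.

    ``target_term`` is a fixed-effect column name of the design (e.g.
    ``prs_t_follow_arm``).  Non-converged refits are excluded from the power
    denominator and counted; a point with more than 20% non-convergence
    carries a warning.  ``mc_se = sqrt(p(1-p)/reps_used)``.
    """
    if any(n < 20 for n in sizes):
        raise ValueError("target sizes must be >= 20")
    # validate the term on the source data once
    base = build_design(cohort, spec)
    if target_term not in base.fixed_columns:
        raise ValueError(
            f"target term {target_term!r} not among design columns {base.fixed_columns}"
        )
    rng = np.random.default_rng(seed)
    points = []
    for n in sizes:
        hits = 0
        used = 0
        bad = 0
        for _ in range(reps):
            boot = resample_cohort(cohort, n, rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_mlm(build_design(boot, spec))
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                bad += 1
                continue
            used += 1
            if fit.p[target_term] < alpha:
                hits += 1
        power = hits / used if used else float("nan")
        mc_se = float(np.sqrt(power * (1 - power) / used)) if used else float("nan")
        warning = None
        if reps and bad > 0.2 * reps:
            warning = f"{bad}/{reps} resamples failed to converge"
        points.append(
            PowerPoint(
                n=n,
                power=power,
                mc_se=mc_se,
                reps=used,
                alpha=alpha,
                n_nonconverged=bad,
                warning=warning,
            )
        )
    return points


def power_table(points: list[PowerPoint], phenotype: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phenotype": phenotype,
                "n": p.n,
                "power": p.power,
                "mc_se": p.mc_se,
                "reps": p.reps,
                "n_nonconverged": p.n_nonconverged,
            }
            for p in points
        ]
    )
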