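"""Stratified MR orchestration: per-stratum estimates, replicate pooling,
and heterogeneity / trend inference.

Under a linear, homogeneous causal effect every stratum's localized
estimate targets the same quantity, so Cochran's Q over the stratum
estimates is chi-square with J - 1 degrees of freedom and a trend across
stratum mean exposures is null.  Departures — heterogeneity, trends, or
per-stratum first-stage slopes that differ — are either genuine
non-linearity or bias (e.g. selection amplified within strata); the
negative-control machinery in :mod:`stratmr.diagnostics` distinguishes the
two.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    MREstimate,
    iv_exposure_assoc,
    two_stage_binary,
    two_stage_continuous,
)
from .stratify import StratumAssignment, StratumSummary, summarize_strata

__all__ = [
    "StratumEstimateSet",
    "PooledEstimateSet",
    "HeterogeneityResult",
    "stratified_mr",
    "pool_replicates",
    "cochran_q",
    "trend_test",
    "constant_genetic_effect_check",
    "flag_impossibility",
]


@dataclass
class HeterogeneityResult:
    """Cochran's Q over stratum estimates and/or an exposure trend test."""

    Q: Optional[float] = None
    df: Optional[int] = None
    p_Q: Optional[float] = None
    trend_slope: Optional[float] = None
    trend_se: Optional[float] = None
    p_trend: Optional[float] = None


@dataclass
class StratumEstimateSet:
    """Per-stratum MR results from a single stratification replicate.

    ``estimates[j-1]`` is the localized (stratum-specific) causal-effect
    estimate for stratum j, ``first_stage[j-1]`` the instrument-exposure
    slope in that stratum, ``summaries[j-1]`` its descriptive summary.
    A failed stratum holds ``None`` with the reason in ``errors``.
    ``overall`` is the conventional whole-sample estimate for reference.
    """

    method: str
    n_strata: int
    outcome: str
    family: str
    estimates: list[Optional[MREstimate]]
    first_stage: list[Optional[MREstimate]]
    summaries: list[StratumSummary]
    overall: MREstimate
    replicate_id: int = 0
    errors: dict[int, str] = field(default_factory=dict)

    def betas(self) -> np.ndarray:
        return np.array([e.beta if e else np.nan for e in self.estimates])

    def ses(self) -> np.ndarray:
        return np.array([e.se if e else np.nan for e in self.estimates])

    def mean_exposures(self) -> np.ndarray:
        return np.array([s.mean_exposure for s in self.summaries])


@dataclass
class PooledEstimateSet:
    """Rubin's-rules combination of m stratification replicates.

    Per stratum: pooled beta is the mean of replicate betas, W the mean
    within-replicate variance, B the between-replicate sample variance,
    and the total variance T = W + (1 + 1/m) B, so pooling never reports
    less uncertainty than a single replicate's average.
    """

    method: str
    n_strata: int
    outcome: str
    family: str
    m: int
    estimates: list[MREstimate]
    first_stage: list[MREstimate]
    summaries: list[StratumSummary]
    overall: MREstimate
    within_var: np.ndarray = field(default_factory=lambda: np.array([]))
    between_var: np.ndarray = field(default_factory=lambda: np.array([]))

    def betas(self) -> np.ndarray:
        return np.array([e.beta for e in self.estimates])

    def ses(self) -> np.ndarray:
        return np.array([e.se for e in self.estimates])

    def mean_exposures(self) -> np.ndarray:
        return np.array([s.mean_exposure for s in self.summaries])


EstimateSet = Union[StratumEstimateSet, PooledEstimateSet]


def _estimate(cohort, outcome, family, covariates, exposure_col) -> MREstimate:
    if family == "binary":
        return two_stage_binary(cohort, outcome, covariates, exposure_col=exposure_col)
    return two_stage_continuous(cohort, outcome, covariates, exposure_col=exposure_col)


def stratified_mr(
    cohort: pd.DataFrame,
    assignment: StratumAssignment,
    outcome: str,
    family: str = "continuous",
    covariates: Optional[Sequence[str]] = None,
    exposure_col: str = "exposure",
) -> StratumEstimateSet:
    """Run two-stage MR within each stratum of ``assignment``.

    Also computes the per-stratum first-stage (instrument-exposure)
    association and the conventional whole-cohort estimate.  Estimation
    failures in individual strata (e.g. a one-class binary outcome) are
    recorded per-stratum rather than aborting the analysis.
    """
    if family not in ("continuous", "binary"):
        raise ValueError(f"unknown outcome family {family!r}")
    indexed = cohort.set_index("id", drop=False)
    summaries = summarize_strata(cohort, assignment, exposure_col=exposure_col)
    overall = _estimate(cohort, outcome, family, covariates, exposure_col)

    estimates: list[Optional[MREstimate]] = []
    first: list[Optional[MREstimate]] = []
    errors: dict[int, str] = {}
    for j in range(1, assignment.n_strata + 1):
        sub = indexed.loc[assignment.stratum_ids(j)]
        try:
            estimates.append(_estimate(sub, outcome, family, covariates, exposure_col))
        except (ValueError, np.linalg.LinAlgError) as err:
            estimates.append(None)
            errors[j] = str(err)
        try:
            first.append(iv_exposure_assoc(sub, covariates, exposure_col=exposure_col))
        except (ValueError, np.linalg.LinAlgError) as err:
            first.append(None)
            errors.setdefault(j, f"first stage: {err}")

    result = StratumEstimateSet(
        method=assignment.method,
        n_strata=assignment.n_strata,
        outcome=outcome,
        family=family,
        estimates=estimates,
        first_stage=first,
        summaries=summaries,
        overall=overall,
        replicate_id=assignment.replicate_id,
        errors=errors,
    )
    flag_impossibility(result)
    return result


def _pool(estimates_by_replicate: list[list[MREstimate]], family: str):
    """Rubin's rules applied stratum-wise across replicates."""
    m = len(estimates_by_replicate)
    n_strata = len(estimates_by_replicate[0])
    pooled, W_arr, B_arr = [], np.empty(n_strata), np.empty(n_strata)
    for j in range(n_strata):
        reps = [r[j] for r in estimates_by_replicate]
        if any(e is None for e in reps):
            raise ValueError(f"stratum {j + 1} failed in at least one replicate")
        betas = np.array([e.beta for e in reps])
        W = float(np.mean([e.se**2 for e in reps]))
        B = float(np.var(betas, ddof=1)) if m > 1 else 0.0
        T = W + (1.0 + 1.0 / m) * B
        W_arr[j], B_arr[j] = W, B
        pooled.append(
            MREstimate(
                beta=float(betas.mean()),
                se=math.sqrt(T),
                n=reps[0].n,
                family=family,
                estimator="pooled",
            )
        )
    return pooled, W_arr, B_arr


def pool_replicates(sets: Sequence[StratumEstimateSet]) -> PooledEstimateSet:
    """Combine replicate stratifications by Rubin's rules.

    All replicates must share the method, J and outcome.  With m = 1 the
    between-replicate variance is undefined and is treated as 0, so the
    pooled result equals the single replicate.
    """
    if len(sets) == 0:
        raise ValueError("no replicates to pool")
    ref = sets[0]
    for s in sets[1:]:
        if s.n_strata != ref.n_strata:
            raise ValueError("replicates disagree on the number of strata")
        if s.method != ref.method or s.outcome != ref.outcome:
            raise ValueError("replicates disagree on method or outcome")

    pooled, W, B = _pool([list(s.estimates) for s in sets], ref.family)
    pooled_fs, _, _ = _pool([list(s.first_stage) for s in sets], "continuous")

    # average the descriptive summaries across replicates
    summaries = []
    for j in range(ref.n_strata):
        per = [s.summaries[j] for s in sets]
        summaries.append(
            StratumSummary(
                stratum=j + 1,
                n=per[0].n,
                mean_exposure=float(np.mean([p.mean_exposure for p in per])),
                min_exposure=float(np.min([p.min_exposure for p in per])),
                max_exposure=float(np.max([p.max_exposure for p in per])),
                mean_instrument=float(np.mean([p.mean_instrument for p in per])),
            )
        )
    return PooledEstimateSet(
        method=ref.method,
        n_strata=ref.n_strata,
        outcome=ref.outcome,
        family=ref.family,
        m=len(sets),
        estimates=pooled,
        first_stage=pooled_fs,
        summaries=summaries,
        overall=ref.overall,
        within_var=W,
        between_var=B,
    )


def _q_statistic(betas: np.ndarray, ses: np.ndarray) -> HeterogeneityResult:
    if np.any(ses == 0.0):
        raise ValueError("Cochran's Q requires strictly positive standard errors")
    w = 1.0 / ses**2
    theta = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - theta) ** 2))
    df = len(betas) - 1
    return HeterogeneityResult(Q=Q, df=df, p_Q=float(stats.chi2.sf(Q, df)))


def cochran_q(estimate_set: EstimateSet) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test over stratum estimates.

    Inverse-variance weights w_j = 1/se_j^2, fixed-effect mean
    theta = sum(w b) / sum(w), Q = sum w (b - theta)^2, compared to a
    chi-square with J - 1 degrees of freedom.
    """
    betas, ses = estimate_set.betas(), estimate_set.ses()
    if np.isnan(betas).any():
        keep = ~np.isnan(betas)
        betas, ses = betas[keep], ses[keep]
    if len(betas) < 2:
        raise ValueError("heterogeneity requires at least 2 estimable strata")
    return _q_statistic(betas, ses)


def trend_test(estimate_set: EstimateSet) -> HeterogeneityResult:
    """Inverse-variance-weighted trend of stratum estimates on stratum
    mean exposure.

    Weighted least squares of beta_j on mean_exposure_j with weights
    1/se_j^2; reports the slope (effect units per exposure unit of the
    stratum mean), its standard error, and a two-sided Wald p-value.
    """
    betas, ses = estimate_set.betas(), estimate_set.ses()
    x = estimate_set.mean_exposures()
    keep = ~np.isnan(betas)
    betas, ses, x = betas[keep], ses[keep], x[keep]
    if len(betas) < 3:
        raise ValueError("trend test requires at least 3 estimable strata")
    if np.ptp(x) == 0.0:
        raise ValueError("stratum mean exposures are constant")
    if np.any(ses == 0.0):
        raise ValueError("trend test requires strictly positive standard errors")
    w = 1.0 / ses**2
    xbar = np.sum(w * x) / np.sum(w)
    ybar = np.sum(w * betas) / np.sum(w)
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (betas - ybar)) / sxx)
    se = float(np.sqrt(1.0 / sxx))
    p = float(2.0 * stats.norm.sf(abs(slope / se)))
    return HeterogeneityResult(trend_slope=slope, trend_se=se, p_trend=p)


def constant_genetic_effect_check(estimate_set: EstimateSet) -> HeterogeneityResult:
    """Cochran's Q over the per-stratum first-stage slopes.

    A significant Q says the instrument-exposure association differs
    across strata, i.e. the constant-genetic-effect assumption fails —
    the condition under which the residual method is biased.
    """
    fs = estimate_set.first_stage
    betas = np.array([e.beta if e else np.nan for e in fs])
    ses = np.array([e.se if e else np.nan for e in fs])
    keep = ~np.isnan(betas)
    betas, ses = betas[keep], ses[keep]
    if len(betas) < 2:
        raise ValueError("heterogeneity requires at least 2 estimable strata")
    return _q_statistic(betas, ses)


def flag_impossibility(estimate_set: EstimateSet) -> bool:
    """Warn when stratum and overall estimates cannot both be causal.

    Flags the pattern where every stratum point estimate lies on one side
    of zero while the whole-sample confidence interval excludes all of
    them on that side — if every estimate had a causal interpretation the
    overall effect would have to be compatible with some mixture of the
    stratum effects.
    """
    betas = estimate_set.betas()
    betas = betas[~np.isnan(betas)]
    if len(betas) == 0:
        return False
    overall = estimate_set.overall
    flagged = bool(
        (np.all(betas > 0) and overall.ci_high < betas.min())
        or (np.all(betas < 0) and overall.ci_low > betas.max())
    )
    if flagged:
        warnings.warn(
            "overall confidence interval excludes every stratum point "
            "estimate's common direction: stratum estimates cannot all "
            "have a causal interpretation",
            UserWarning,
            stacklevel=2,
        )
    return flagged
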