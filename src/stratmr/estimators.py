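"""One-sample instrumental-variable estimators.

Continuous outcomes use two-stage least squares (with a single instrument
and no covariates this is exactly the Wald ratio).  Binary outcomes use
two-stage residual inclusion (TSRI): logistic regression of the outcome on
the exposure plus the first-stage residual, reporting the log-odds
coefficient on the exposure.  Confidence intervals are normal-approximation
``beta +/- 1.96 se`` throughout, with two-sided Wald p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.sandbox.regression.gmm import IV2SLS

__all__ = [
    "MREstimate",
    "iv_exposure_assoc",
    "two_stage_continuous",
    "two_stage_binary",
    "ratio_estimate",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """An effect estimate with its Wald inference.

    ``beta`` is in outcome units per exposure unit for continuous
    outcomes, and log-odds per exposure unit for binary outcomes (report
    ``exp(beta)`` as the odds ratio).
    """

    beta: float
    se: float
    n: int
    family: str = "continuous"
    estimator: str = "two_stage"

    def __post_init__(self) -> None:
        # se == 0 is allowed for exact-fit degenerate cases (e.g. noiseless
        # first stage); inference methods handle it explicitly
        if self.se < 0 or not math.isfinite(self.se):
            raise ValueError(f"standard error must be finite and >= 0, got {self.se}")

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se

    @property
    def p_value(self) -> float:
        if self.se == 0.0:
            return 0.0 if self.beta != 0.0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))

    @property
    def odds_ratio(self) -> float:
        if self.family != "binary":
            raise ValueError("odds ratio is only defined for binary outcomes")
        return math.exp(self.beta)


def _design(
    cohort: pd.DataFrame, cols: Sequence[str]
) -> np.ndarray:
    mats = [np.ones(len(cohort))]
    for c in cols:
        mats.append(cohort[c].to_numpy(dtype=float))
    A = np.column_stack(mats)
    # name the offending column on rank deficiency
    if np.linalg.matrix_rank(A) < A.shape[1]:
        for i, c in enumerate(cols, start=1):
            sub = A[:, list(range(i)) ]
            if np.linalg.matrix_rank(np.column_stack([sub, A[:, i]])) == np.linalg.matrix_rank(sub):
                raise ValueError(f"design matrix is singular: column {c!r} is collinear")
        raise ValueError("design matrix is singular")
    return A


def _covariate_list(covariates: Optional[Sequence[str]]) -> list[str]:
    return list(covariates) if covariates else []


def iv_exposure_assoc(
    cohort: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    exposure_col: str = "exposure",
) -> MREstimate:
    """First-stage (instrument-exposure) least-squares association.

    The per-stratum version of this slope probes the constant-genetic-
    effect assumption: under it, the slope is the same in every stratum.
    """
    g = cohort["instrument_score"].to_numpy(dtype=float)
    if np.ptp(g) == 0.0:
        raise ValueError("instrument score has zero variance")
    cols = ["instrument_score", *_covariate_list(covariates)]
    A = _design(cohort, cols)
    y = cohort[exposure_col].to_numpy(dtype=float)
    fit = sm.OLS(y, A).fit()
    return MREstimate(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        n=len(cohort),
        family="continuous",
        estimator="first_stage",
    )


def two_stage_continuous(
    cohort: pd.DataFrame,
    outcome: str = "outcome_continuous",
    covariates: Optional[Sequence[str]] = None,
    exposure_col: str = "exposure",
) -> MREstimate:
    """Two-stage least squares for a continuous outcome.

    Stage 1 regresses the exposure on the instrument (plus covariates);
    stage 2 regresses the outcome on the fitted exposure (plus
    covariates).  Standard errors are the usual IV standard errors, which
    account for the generated regressor.  With a single instrument and no
    covariates the point estimate equals the Wald ratio
    ``cov(G, Y) / cov(G, X)`` exactly.
    """
    g = cohort["instrument_score"].to_numpy(dtype=float)
    if np.ptp(g) == 0.0:
        raise ValueError("instrument score has zero variance")
    covs = _covariate_list(covariates)
    y = cohort[outcome].to_numpy(dtype=float)
    exog = _design(cohort, [exposure_col, *covs])
    instr = _design(cohort, ["instrument_score", *covs])
    fit = IV2SLS(y, exog, instrument=instr).fit()
    return MREstimate(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        n=len(cohort),
        family="continuous",
        estimator="two_stage",
    )


def two_stage_binary(
    cohort: pd.DataFrame,
    outcome: str = "outcome_binary",
    covariates: Optional[Sequence[str]] = None,
    exposure_col: str = "exposure",
) -> MREstimate:
    """Two-stage residual inclusion for a binary outcome.

    Stage 1: least squares of exposure on instrument (+ covariates).
    Stage 2: logistic regression of the outcome on the exposure and the
    stage-1 residual (+ covariates); ``beta`` is the log-odds coefficient
    on the exposure, with the second-stage model-based standard error.
    """
    yb = cohort[outcome].to_numpy(dtype=float)
    classes = np.unique(yb)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError(f"binary outcome {outcome!r} must be coded 0/1")
    if classes.size < 2:
        raise ValueError(f"binary outcome {outcome!r} has a single class")
    g = cohort["instrument_score"].to_numpy(dtype=float)
    if np.ptp(g) == 0.0:
        raise ValueError("instrument score has zero variance")

    covs = _covariate_list(covariates)
    x = cohort[exposure_col].to_numpy(dtype=float)
    stage1 = _design(cohort, ["instrument_score", *covs])
    resid = x - stage1 @ np.linalg.lstsq(stage1, x, rcond=None)[0]

    exog = np.column_stack([_design(cohort, [exposure_col, *covs]), resid])
    try:
        fit = sm.Logit(yb, exog).fit(disp=False, maxiter=200)
    except Exception as err:  # statsmodels raises on perfect separation
        raise ValueError(f"second-stage logistic regression failed: {err}") from err
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        raise ValueError(
            "second-stage logistic regression is unstable "
            "(possible separation: standard error diverged)"
        )
    return MREstimate(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        n=len(cohort),
        family="binary",
        estimator="two_stage",
    )


def ratio_estimate(beta_gy: MREstimate, beta_gx: MREstimate) -> MREstimate:
    """Wald ratio: reduced-form over first-stage slope.

    ``beta = beta_gy / beta_gx`` with a first-order delta-method standard
    error ``sqrt(se_gy^2 / beta_gx^2 + beta_gy^2 se_gx^2 / beta_gx^4)``.
    """
    if beta_gx.beta == 0.0:
        raise ValueError("first-stage slope is zero: instrument has no effect")
    b = beta_gy.beta / beta_gx.beta
    var = (
        beta_gy.se**2 / beta_gx.beta**2
        + beta_gy.beta**2 * beta_gx.se**2 / beta_gx.beta**4
    )
    return MREstimate(
        beta=b,
        se=math.sqrt(var),
        n=min(beta_gy.n, beta_gx.n),
        family=beta_gy.family,
        estimator="ratio",
    )
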