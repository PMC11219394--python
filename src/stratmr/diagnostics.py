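"""Bias-detection workflows for stratified MR.

Two complementary checks:

* **Negative-control-outcome (NCO) analysis** — run conventional and
  stratified MR of the exposure on outcomes it cannot plausibly cause
  (an age-like and a sex-like variable).  Non-null stratum estimates, or
  heterogeneity across strata, on such outcomes indicate that the
  stratification procedure manufactures associations — typically via
  selection/collider bias — rather than revealing non-linearity.

* **Strata-stability analysis** — when a repeat exposure measurement
  exists, stratify at each occasion with the same instrument and
  cross-tabulate stratum membership.  If individuals do not stay in their
  stratum, stratum-specific estimates cannot be interpreted as effects
  "in people with low/high exposure": membership is largely measurement
  noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate
from .nlmr import (
    HeterogeneityResult,
    PooledEstimateSet,
    StratumEstimateSet,
    cochran_q,
    flag_impossibility,
    pool_replicates,
    stratified_mr,
    trend_test,
)
from .stratify import doubly_ranked_strata, residual_strata

__all__ = [
    "NCOOutcomeResult",
    "NCOReport",
    "TransitionMatrix",
    "nco_analysis",
    "stability_analysis",
    "render_report",
]


@dataclass
class NCOOutcomeResult:
    """All results for one negative-control outcome under one method."""

    outcome: str
    method: str
    family: str
    overall: MREstimate
    stratified: StratumEstimateSet | PooledEstimateSet
    heterogeneity: HeterogeneityResult
    trend: Optional[HeterogeneityResult]
    nonnull_strata_count: int
    heterogeneity_flag: bool
    impossibility_flag: bool


@dataclass
class NCOReport:
    """Negative-control-outcome report for one exposure.

    ``results[(outcome, method)]`` holds the per-outcome, per-method
    detail; the ``biased`` property is True when any heterogeneity flag
    fired.
    """

    exposure: str
    n_strata: int
    alpha: float
    results: dict[tuple[str, str], NCOOutcomeResult] = field(default_factory=dict)
    annotations: list[str] = field(default_factory=list)

    @property
    def biased(self) -> bool:
        return any(r.heterogeneity_flag for r in self.results.values())


@dataclass
class TransitionMatrix:
    """J x J cross-classification of stratum membership at two occasions.

    ``counts[i, j]`` is the number of individuals in stratum i+1 at the
    first occasion and stratum j+1 at the second; ``proportions`` are
    row-normalised, so the diagonal is the per-stratum retention.
    """

    n_strata: int
    counts: np.ndarray
    method: str = "doubly_ranked"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.n_strata, self.n_strata):
            raise ValueError("counts must be J x J")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def proportions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / np.where(totals == 0, 1, totals)

    @property
    def retention(self) -> np.ndarray:
        """Per-stratum probability of staying in the same stratum."""
        return np.diag(self.proportions)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _infer_family(values: pd.Series) -> str:
    vals = pd.unique(values.dropna())
    return "binary" if np.isin(vals, (0, 1)).all() and len(vals) <= 2 else "continuous"


def nco_analysis(
    cohort: pd.DataFrame,
    exposure: str = "exposure",
    nco_outcomes: Sequence[str] = ("age", "sex"),
    n_strata: int = 10,
    methods: Sequence[str] = ("residual", "doubly_ranked"),
    m_replicates: int = 20,
    covariates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> NCOReport:
    """Run the full negative-control-outcome workup.

    For each NCO and stratification method: conventional (whole-sample)
    MR, stratified MR (the doubly-ranked method pooled over
    ``m_replicates`` tie-breaking replicates by Rubin's rules; the
    residual method as a single deterministic run), Cochran's Q and an
    exposure trend across strata.  ``heterogeneity_flag`` is
    ``p_Q < alpha``; ``nonnull_strata_count`` counts strata with
    ``p < alpha``.  An outcome family (binary vs continuous) is inferred
    from the data.
    """
    report = NCOReport(exposure=exposure, n_strata=n_strata, alpha=alpha)
    for outcome in nco_outcomes:
        if outcome not in cohort.columns:
            raise ValueError(f"negative-control outcome {outcome!r} not in cohort")
        family = _infer_family(cohort[outcome])
        for method in methods:
            if method == "residual":
                assignment = residual_strata(cohort, n_strata, covariates=None,
                                             exposure_col=exposure)
                strat = stratified_mr(
                    cohort, assignment, outcome, family, covariates, exposure_col=exposure
                )
            elif method == "doubly_ranked":
                reps = []
                for r in range(m_replicates):
                    a = doubly_ranked_strata(
                        cohort, n_strata, replicate_seed=base_seed + r,
                        exposure_col=exposure,
                    )
                    reps.append(
                        stratified_mr(cohort, a, outcome, family, covariates,
                                      exposure_col=exposure)
                    )
                    report.annotations.extend(
                        f"{outcome}/{method} replicate {r} stratum {j}: {msg}"
                        for j, msg in reps[-1].errors.items()
                    )
                strat = pool_replicates(reps)
            else:
                raise ValueError(f"unknown stratification method {method!r}")

            if isinstance(strat, StratumEstimateSet):
                report.annotations.extend(
                    f"{outcome}/{method} stratum {j}: {msg}"
                    for j, msg in strat.errors.items()
                )
            het = cochran_q(strat)
            trend = trend_test(strat) if n_strata >= 3 else None
            pvals = [e.p_value for e in strat.estimates if e is not None]
            report.results[(outcome, method)] = NCOOutcomeResult(
                outcome=outcome,
                method=method,
                family=family,
                overall=strat.overall,
                stratified=strat,
                heterogeneity=het,
                trend=trend,
                nonnull_strata_count=int(sum(p < alpha for p in pvals)),
                heterogeneity_flag=bool(het.p_Q < alpha),
                impossibility_flag=flag_impossibility(strat),
            )
    return report


def stability_analysis(
    cohort: pd.DataFrame,
    n_strata: int = 10,
    method: str = "doubly_ranked",
    replicate_seed: int = 0,
) -> TransitionMatrix:
    """Cross-classify stratum membership between two exposure measurements.

    Stratifies the same individuals twice — once on ``exposure``, once on
    ``exposure_repeat`` — with the same instrument and the same
    tie-breaking seed, and counts transitions.  Rows of the resulting
    matrix index the first-occasion stratum.
    """
    if "exposure_repeat" not in cohort.columns or cohort["exposure_repeat"].isna().all():
        raise ValueError("cohort has no repeat exposure measurements")
    rows = cohort.dropna(subset=["exposure", "exposure_repeat"])
    if method == "doubly_ranked":
        a1 = doubly_ranked_strata(rows, n_strata, replicate_seed)
        a2 = doubly_ranked_strata(rows, n_strata, replicate_seed,
                                  exposure_col="exposure_repeat")
    elif method == "residual":
        a1 = residual_strata(rows, n_strata)
        a2 = residual_strata(rows, n_strata, exposure_col="exposure_repeat")
    else:
        raise ValueError(f"unknown stratification method {method!r}")
    s1 = a1.assignment
    s2 = a2.assignment.reindex(s1.index)
    counts = np.zeros((n_strata, n_strata), dtype=int)
    np.add.at(counts, (s1.to_numpy() - 1, s2.to_numpy() - 1), 1)
    return TransitionMatrix(n_strata=n_strata, counts=counts, method=method)


# --------------------------------------------------------------------------
# Rendering

_FLOAT_FMT = "%.6g"


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, (float, np.floating)):
        return _FLOAT_FMT % v
    return str(v)


def _estimate_rows(strat) -> list[dict]:
    rows = []
    for j, (e, fs, s) in enumerate(
        zip(strat.estimates, strat.first_stage, strat.summaries), start=1
    ):
        rows.append(
            {
                "stratum": j,
                "n": s.n,
                "mean_exposure": s.mean_exposure,
                "beta": e.beta if e else None,
                "se": e.se if e else None,
                "ci_low": e.ci_low if e else None,
                "ci_high": e.ci_high if e else None,
                "p": e.p_value if e else None,
                "first_stage_beta": fs.beta if fs else None,
            }
        )
    return rows


def render_report(report, fmt: str = "tsv") -> str:
    """Serialise an :class:`NCOReport` or :class:`TransitionMatrix`.

    ``fmt="tsv"`` emits machine-readable tab-separated tables (one block
    per outcome/method for NCO reports); ``fmt="text"`` emits aligned
    human-readable tables.  Output is deterministic: the same report
    renders byte-identically.
    """
    if fmt not in ("tsv", "text"):
        raise ValueError(f"unknown report format {fmt!r}")

    buf = io.StringIO()
    if isinstance(report, TransitionMatrix):
        header = ["from_stratum"] + [f"to_{j}" for j in range(1, report.n_strata + 1)]
        df = pd.DataFrame(report.proportions,
                          columns=header[1:],
                          index=pd.Index(range(1, report.n_strata + 1),
                                         name="from_stratum"))
        if fmt == "tsv":
            df.round(6).to_csv(buf, sep="\t", float_format=_FLOAT_FMT)
        else:
            buf.write(f"Stratum transition proportions (n={report.n}, "
                      f"method={report.method})\n")
            buf.write(df.round(4).to_string())
            buf.write("\n")
        return buf.getvalue()

    if isinstance(report, NCOReport):
        for (outcome, method), res in sorted(report.results.items()):
            rows = pd.DataFrame(_estimate_rows(res.stratified))
            head = (
                f"# exposure={report.exposure}\toutcome={outcome}\tmethod={method}\t"
                f"family={res.family}\n"
                f"# overall_beta={_fmt(res.overall.beta)}\t"
                f"overall_se={_fmt(res.overall.se)}\t"
                f"Q={_fmt(res.heterogeneity.Q)}\tp_Q={_fmt(res.heterogeneity.p_Q)}\t"
                f"p_trend={_fmt(res.trend.p_trend) if res.trend else 'NA'}\t"
                f"het_flag={int(res.heterogeneity_flag)}\t"
                f"nonnull_strata={res.nonnull_strata_count}\n"
            )
            buf.write(head)
            if fmt == "tsv":
                rows.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT,
                            na_rep="NA")
            else:
                buf.write(rows.to_string(index=False, na_rep="NA",
                                         float_format=lambda v: _FLOAT_FMT % v))
                buf.write("\n")
            buf.write("\n")
        return buf.getvalue()

    raise ValueError(f"cannot render object of type {type(report).__name__}")
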