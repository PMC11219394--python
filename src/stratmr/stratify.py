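"""Exposure stratification for non-linear Mendelian randomization.

Two ways of cutting a cohort into J ordered strata:

* **residual method** — regress the exposure on the instrument, rank the
  residuals (the "IV-free" exposure) and cut them into J equal-size
  quantile groups.  Stratification on the residual rather than the raw
  exposure is meant to avoid conditioning on a collider, but it relies on
  the instrument-exposure effect being constant across the exposure range.

* **doubly-ranked method** — sort individuals by instrument into K
  pre-strata of size J (N = J x K), then within each pre-stratum rank by
  exposure; the j-th ranked member of every pre-stratum forms final
  stratum j.  Each full pre-stratum contributes exactly one member to each
  final stratum, so the instrument distribution is balanced across final
  strata without assuming a constant genetic effect.

Ties in the instrument or the exposure are broken by a seeded random
permutation; running several replicates with different seeds and pooling
is the standard way to average over tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratumAssignment",
    "StratumSummary",
    "residual_strata",
    "doubly_ranked_strata",
    "summarize_strata",
]


@dataclass
class StratumAssignment:
    """A partition of a cohort into J ordered strata (one replicate).

    ``assignment`` maps individual id -> stratum index in 1..J;
    ``pre_strata`` (doubly-ranked only) maps id -> pre-stratum index in
    1..K, with pre-stratum 1 holding the lowest instrument values.
    """

    method: str
    n_strata: int
    replicate_id: int
    assignment: "pd.Series[int]"
    pre_strata: Optional["pd.Series[int]"] = None

    def stratum_ids(self, j: int) -> np.ndarray:
        """Ids of the individuals in final stratum j."""
        return self.assignment.index[self.assignment.to_numpy() == j].to_numpy()

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment.to_numpy(), minlength=self.n_strata + 1)[1:]


@dataclass
class StratumSummary:
    """Descriptive summary of one stratum."""

    stratum: int
    n: int
    mean_exposure: float
    min_exposure: float
    max_exposure: float
    mean_instrument: float


def _check_inputs(cohort: pd.DataFrame, n_strata: int) -> None:
    if n_strata < 1:
        raise ValueError("number of strata must be >= 1")
    if len(cohort) < n_strata:
        raise ValueError(
            f"cannot form {n_strata} strata from {len(cohort)} individuals"
        )
    for col in ("id", "instrument_score", "exposure"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")


def residual_strata(
    cohort: pd.DataFrame,
    n_strata: int,
    covariates: Optional[Sequence[str]] = None,
    exposure_col: str = "exposure",
) -> StratumAssignment:
    """Partition by quantiles of the IV-free exposure residual.

    The exposure is regressed on the instrument score (plus any
    ``covariates``) by least squares; the residuals are ranked (stable
    order, so ties keep input order) and cut into J groups whose sizes
    differ by at most one.  Stratum 1 holds the lowest residuals.
    """
    _check_inputs(cohort, n_strata)
    g = cohort["instrument_score"].to_numpy(dtype=float)
    x = cohort[exposure_col].to_numpy(dtype=float)
    if np.ptp(g) == 0.0:
        raise ValueError("instrument score has zero variance")

    design = [np.ones_like(g), g]
    if covariates:
        for c in covariates:
            design.append(cohort[c].to_numpy(dtype=float))
    A = np.column_stack(design)
    coefs, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coefs

    order = np.argsort(resid, kind="stable")
    strata = np.empty(len(cohort), dtype=int)
    for j, block in enumerate(np.array_split(order, n_strata), start=1):
        strata[block] = j
    assignment = pd.Series(strata, index=cohort["id"].to_numpy(), name="stratum")
    return StratumAssignment(
        method="residual", n_strata=n_strata, replicate_id=0, assignment=assignment
    )


def doubly_ranked_strata(
    cohort: pd.DataFrame,
    n_strata: int,
    replicate_seed: int = 0,
    exposure_col: str = "exposure",
) -> StratumAssignment:
    """Rank by instrument into pre-strata, then by exposure within them.

    With N individuals and J final strata, the K = floor(N/J) leading
    blocks of J consecutive instrument-ranked individuals form full
    pre-strata; a trailing partial pre-stratum of size m < J (when J does
    not divide N) assigns its exposure-ranked members to final strata
    1..m.  Within each pre-stratum the individual with the j-th smallest
    exposure goes to final stratum j.  Ties in either ranking are broken
    by a random permutation seeded with ``replicate_seed``; with no ties
    the result is independent of the seed.
    """
    _check_inputs(cohort, n_strata)
    n = len(cohort)
    g = cohort["instrument_score"].to_numpy(dtype=float)
    x = cohort[exposure_col].to_numpy(dtype=float)

    rng = np.random.default_rng(replicate_seed)
    jitter = rng.permutation(n)  # tie-break key, a permutation of 0..n-1
    g_order = np.lexsort((jitter, g))

    # pre-stratum index 1..K for the full blocks; a trailing remainder block
    # (when J does not divide N) becomes partial pre-stratum K+1
    pre = np.empty(n, dtype=int)
    pre[g_order] = np.arange(n) // n_strata + 1

    strata = np.empty(n, dtype=int)
    jitter2 = rng.permutation(n)
    for k in range(1, int(np.ceil(n / n_strata)) + 1):
        members = np.flatnonzero(pre == k)
        if members.size == 0:
            continue
        x_order = members[np.lexsort((jitter2[members], x[members]))]
        strata[x_order] = np.arange(1, x_order.size + 1)

    ids = cohort["id"].to_numpy()
    return StratumAssignment(
        method="doubly_ranked",
        n_strata=n_strata,
        replicate_id=replicate_seed,
        assignment=pd.Series(strata, index=ids, name="stratum"),
        pre_strata=pd.Series(pre, index=ids, name="pre_stratum"),
    )


def summarize_strata(
    cohort: pd.DataFrame,
    assignment: StratumAssignment,
    exposure_col: str = "exposure",
) -> list[StratumSummary]:
    """Per-stratum n, exposure mean/min/max and mean instrument score."""
    indexed = cohort.set_index("id")
    missing = assignment.assignment.index.difference(indexed.index)
    if len(missing):
        raise ValueError(f"assignment covers ids absent from cohort: {list(missing[:5])}")
    strata = assignment.assignment
    out: list[StratumSummary] = []
    for j in range(1, assignment.n_strata + 1):
        ids = strata.index[strata.to_numpy() == j]
        sub = indexed.loc[ids]
        if len(sub) == 0:
            raise ValueError(f"stratum {j} is empty")
        xs = sub[exposure_col].to_numpy(dtype=float)
        out.append(
            StratumSummary(
                stratum=j,
                n=len(sub),
                mean_exposure=float(xs.mean()),
                min_exposure=float(xs.min()),
                max_exposure=float(xs.max()),
                mean_instrument=float(sub["instrument_score"].mean()),
            )
        )
    return out
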