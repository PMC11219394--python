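"""Polygenic score construction from variant weights and allele dosages.

The instrument is a summed weighted allele score: for individual i,
``score_i = sum_k weight_k * dosage_ik`` where the dosage counts copies of
the effect allele (0..2).  Dosages reported on the other allele are
flipped (d -> 2 - d) at alignment time; missing dosages are mean-imputed
per variant, which leaves the scores of complete rows unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["VariantWeight", "read_weights", "read_dosages", "score_individuals"]

_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantWeight:
    """Per-allele effect of one variant on the exposure."""

    variant_id: str
    effect_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _ALLELES:
            raise ValueError(
                f"{self.variant_id}: effect allele must be one of A/C/G/T, "
                f"got {self.effect_allele!r}"
            )


def read_weights(path) -> list[VariantWeight]:
    """Read a three-column delimited weights file.

    Columns: variant_id, effect_allele, weight (tab- or comma-separated,
    header row required).  Variant ids must be unique.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant_id", "effect_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weights file is missing columns: {sorted(missing)}")
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in weights file: {dups}")
    return [
        VariantWeight(str(r.variant_id), str(r.effect_allele), float(r.weight))
        for r in df.itertuples()
    ]


def read_dosages(path) -> pd.DataFrame:
    """Read a dosage matrix: one row per individual, variant ids as the
    header, values in [0, 2] with "NA" for missing."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return df


def score_individuals(
    dosages: pd.DataFrame,
    weights: Sequence[VariantWeight],
    dosage_alleles: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Summed weighted allele score for every row of ``dosages``.

    ``dosage_alleles`` maps variant id -> the allele the dosage column
    counts; columns counting the non-effect allele are flipped to the
    effect allele (d -> 2 - d) before weighting.  Missing dosages are
    mean-imputed per variant.  Every weighted variant must be present in
    the dosage matrix.
    """
    unmatched = [w.variant_id for w in weights if w.variant_id not in dosages.columns]
    if unmatched:
        raise ValueError(f"variants absent from dosage matrix: {unmatched}")

    n = len(dosages)
    score = np.zeros(n)
    for w in weights:
        d = dosages[w.variant_id].to_numpy(dtype=float)
        if dosage_alleles is not None:
            counted = dosage_alleles.get(w.variant_id, w.effect_allele)
            if counted not in _ALLELES:
                raise ValueError(
                    f"{w.variant_id}: counted allele must be A/C/G/T, got {counted!r}"
                )
            if counted != w.effect_allele:
                d = 2.0 - d
        if np.isnan(d).any():
            if np.isnan(d).all():
                raise ValueError(f"{w.variant_id}: all dosages missing")
            d = np.where(np.isnan(d), np.nanmean(d), d)
        score += w.weight * d
    return score
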