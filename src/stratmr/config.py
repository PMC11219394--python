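"""Simulation configuration for synthetic MR cohorts.

The simulator draws a cohort with a polygenic instrument G (a weighted
allele score), an exposure X with genetic and non-genetic components, two
negative-control outcomes that are causally independent of X (a continuous
age-like outcome and a binary sex-like outcome), a continuous outcome, a
binary disease outcome, and a logistic selection model that decides which
individuals enter the analysed sample.  All parameters live in a single
:class:`SimulationConfig` so that a scenario is one serialisable object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = ["NCOConfig", "SelectionCoeffs", "SimulationConfig", "load_config"]


@dataclass
class NCOConfig:
    """Marginal distribution of the negative-control outcomes.

    The age-like outcome is Gaussian in years; the sex-like outcome is
    Bernoulli.  Both are drawn independently of the instrument, the
    confounder and the exposure: any non-null MR estimate on them in the
    analysed sample is, by construction, bias.
    """

    age_mean: float = 57.0
    age_sd: float = 8.0
    sex_prob: float = 0.46


@dataclass
class SelectionCoeffs:
    """Log-odds coefficients of the logistic selection-into-sample model.

    ``logit P(selected) = intercept + on_exposure * X + on_age * (age - age_mean)
    + on_sex * sex + on_exposure_x_sex * X * sex``.

    ``intercept = +inf`` switches selection off (everyone is selected).
    Age enters centred so the intercept keeps its meaning across age scales.
    """

    intercept: float = math.inf
    on_exposure: float = 0.0
    on_age: float = 0.0
    on_sex: float = 0.0
    on_exposure_x_sex: float = 0.0

    @property
    def active(self) -> bool:
        """False when selection is degenerate (everyone kept or everyone dropped)."""
        return not (math.isinf(self.intercept) and self.intercept > 0)


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic-cohort scenario.

    Parameters
    ----------
    n_individuals
        Cohort size before selection.
    n_variants, allele_freqs, variant_weights
        The instrument is a summed weighted allele score over independent
        biallelic variants with the given effect-allele frequencies; each
        weight is the per-allele effect on the exposure, in exposure units.
    genetic_effect_mode
        ``"constant"``: the instrument-exposure slope is 1 everywhere (the
        constant-genetic-effect assumption holds).  ``"exposure_varying"``:
        the slope rises piecewise-linearly with the individual's latent
        (non-genetic) exposure percentile, from 1 in the lower half to
        ``genetic_effect_top`` at the top — the failure mode in which the
        genotype-exposure association is larger in upper exposure strata.
    confounder_effect
        Effect of the standard-normal confounder U on the exposure.  U also
        enters the continuous outcome with unit weight, so a naive
        regression of outcome on exposure is confounded.
    causal_effect_continuous, causal_effect_binary
        True effect of X on the continuous outcome (outcome units per
        exposure unit) and on the binary outcome (log-odds per exposure
        unit).
    exposure_skew
        0 gives a Gaussian exposure; > 0 exponentiates the Gaussian kernel
        into a log-normal-like right-skewed exposure (triglyceride-like)
        while keeping its mean and variance.
    repeat_correlation
        Target Pearson correlation between the baseline and repeat exposure
        measurements (test-retest correlation).
    """

    n_individuals: int = 10_000
    n_variants: int = 20
    allele_freqs: Optional[Sequence[float]] = None
    variant_weights: Optional[Sequence[float]] = None
    genetic_effect_mode: str = "constant"
    genetic_effect_top: float = 2.0
    exposure_intercept: float = 0.0
    confounder_effect: float = 0.3
    exposure_noise_sd: float = 0.9
    exposure_skew: float = 0.0
    causal_effect_continuous: float = 0.0
    causal_effect_binary: float = 0.0
    outcome_noise_sd: float = 1.0
    binary_outcome_intercept: float = -3.0
    nco: NCOConfig = field(default_factory=NCOConfig)
    selection: SelectionCoeffs = field(default_factory=SelectionCoeffs)
    repeat_correlation: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.allele_freqs is None:
            # default: frequencies spread over (0.1, 0.9)
            self.allele_freqs = tuple(
                0.1 + 0.8 * (k + 0.5) / self.n_variants for k in range(self.n_variants)
            )
        if self.variant_weights is None:
            # equal weights scaled so var(G) ~= 0.1 on an exposure-sd-1 scale
            het = sum(2 * p * (1 - p) for p in self.allele_freqs)
            w = math.sqrt(0.1 / het)
            self.variant_weights = tuple(w for _ in range(self.n_variants))
        self.allele_freqs = tuple(float(p) for p in self.allele_freqs)
        self.variant_weights = tuple(float(w) for w in self.variant_weights)
        self.validate()

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_variants > 0 and len(self.variant_weights) == 0:
            raise ValueError("variant_weights must be non-empty when n_variants > 0")
        if len(self.allele_freqs) != self.n_variants:
            raise ValueError("allele_freqs length must equal n_variants")
        if len(self.variant_weights) != self.n_variants:
            raise ValueError("variant_weights length must equal n_variants")
        if not all(0.0 < p < 1.0 for p in self.allele_freqs):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if self.exposure_noise_sd <= 0:
            raise ValueError("exposure_noise_sd must be > 0")
        if not -1.0 <= self.repeat_correlation <= 1.0:
            raise ValueError("repeat_correlation must lie in [-1, 1]")
        if self.genetic_effect_mode not in ("constant", "exposure_varying"):
            raise ValueError(
                f"unknown genetic_effect_mode {self.genetic_effect_mode!r}"
            )
        finite_params = [
            self.exposure_intercept,
            self.confounder_effect,
            self.exposure_noise_sd,
            self.causal_effect_continuous,
            self.causal_effect_binary,
            self.genetic_effect_top,
            *self.variant_weights,
        ]
        if not all(math.isfinite(v) for v in finite_params):
            raise ValueError("model parameters must be finite")
        sel = self.selection
        for name in ("on_exposure", "on_age", "on_sex", "on_exposure_x_sex"):
            if not math.isfinite(getattr(sel, name)):
                raise ValueError(f"selection coefficient {name} must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allele_freqs"] = list(self.allele_freqs)
        d["variant_weights"] = list(self.variant_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "nco" in d and isinstance(d["nco"], dict):
            d["nco"] = NCOConfig(**d["nco"])
        if "selection" in d and isinstance(d["selection"], dict):
            sel = dict(d["selection"])
            if isinstance(sel.get("intercept"), str):
                sel["intercept"] = float(sel["intercept"])
            d["selection"] = SelectionCoeffs(**sel)
        return cls(**d)


def load_config(path) -> SimulationConfig:
    """Read a YAML scenario file into a :class:`SimulationConfig`.

    The file is a flat mapping of the dataclass fields with nested ``nco``
    and ``selection`` sections; ``selection.intercept: .inf`` turns
    selection off.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return SimulationConfig.from_dict(raw)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
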