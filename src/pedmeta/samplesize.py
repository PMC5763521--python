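"""Sample-size calculators and the extrapolation-impact computation.

Normal-approximation sample sizes for two-proportion and two-mean comparisons,
plus a helper quantifying how a trial's required size changes when the design
nuisance parameter (control event rate or outcome SD) taken from adult trials
is replaced by the value actually observed in pediatric trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from scipy.stats import norm


class InfeasibleDesignError(ValueError):
    """The design admits no finite sample size (e.g. zero effect)."""


@dataclass(frozen=True)
class DesignSpec:
    """Two-sided type-I error probability and power."""

    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")

    @property
    def z_alpha(self) -> float:
        return float(norm.ppf(1 - self.alpha / 2))

    @property
    def z_beta(self) -> float:
        return float(norm.ppf(self.power))


@dataclass(frozen=True)
class BinaryDesign:
    """Control and treatment event probabilities for a two-proportion design."""

    p_control: float
    p_treatment: float

    def __post_init__(self) -> None:
        for name, p in (("p_control", self.p_control), ("p_treatment", self.p_treatment)):
            if not 0 < p < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        if self.p_control == self.p_treatment:
            raise InfeasibleDesignError("p_control and p_treatment must differ")

    @classmethod
    def from_relative_reduction(cls, p_control: float, rrr: float) -> "BinaryDesign":
        """Build a design from a relative risk reduction, p_t = (1 - rrr) p_c."""
        return cls(p_control=p_control, p_treatment=(1.0 - rrr) * p_control)


@dataclass(frozen=True)
class ContinuousDesign:
    """Outcome SD and detectable difference for a two-means design."""

    sd: float
    delta: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.delta <= 0:
            raise InfeasibleDesignError(f"delta must be positive, got {self.delta}")


@dataclass(frozen=True)
class ImpactResult:
    """Required sizes under the adult and pediatric nuisance parameters."""

    n_adult: int
    n_pediatric: int

    @property
    def ratio(self) -> float:
        return self.n_pediatric / self.n_adult


def n_two_proportions(design: BinaryDesign, spec: DesignSpec = DesignSpec()) -> int:
    """Per-arm sample size for comparing two proportions.

    Normal approximation with variance pooled under the null (2 p̄ (1 - p̄),
    p̄ the mean of the two proportions) and unpooled under the alternative,
    rounded up to an integer:

        n = ceil( (z_{1-α/2} sqrt(2 p̄ q̄) + z_{1-β} sqrt(p₁q₁ + p₂q₂))² / (p₁-p₂)² )
    """
    p1, p2 = design.p_control, design.p_treatment
    pbar = (p1 + p2) / 2.0
    num = (
        spec.z_alpha * math.sqrt(2.0 * pbar * (1.0 - pbar))
        + spec.z_beta * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    ) ** 2
    return math.ceil(num / (p1 - p2) ** 2)


def n_two_means(design: ContinuousDesign, spec: DesignSpec = DesignSpec()) -> int:
    """Per-group sample size for comparing two means with common SD.

        n = ceil( 2 sd² (z_{1-α/2} + z_{1-β})² / δ² )
    """
    return math.ceil(
        2.0 * design.sd**2 * (spec.z_alpha + spec.z_beta) ** 2 / design.delta**2
    )


def extrapolation_impact(
    adult_design: Union[BinaryDesign, ContinuousDesign],
    pediatric_design: Union[BinaryDesign, ContinuousDesign],
    spec: DesignSpec = DesignSpec(),
) -> ImpactResult:
    """Sample-size consequence of swapping the adult nuisance parameter for the pediatric one.

    Both designs must be of the same kind and should hold the targeted effect
    fixed (same relative risk reduction, or same detectable difference); only
    the nuisance parameter differs. Returns both per-arm sizes; ``ratio`` is
    n(pediatric) / n(adult). Note the direction is not monotone for binary
    designs at fixed relative reduction: a smaller control rate can raise or
    lower the required size depending on where the rates sit.
    """
    if type(adult_design) is not type(pediatric_design):
        raise TypeError("both designs must be binary or both continuous")
    calc = n_two_proportions if isinstance(adult_design, BinaryDesign) else n_two_means
    return ImpactResult(
        n_adult=calc(adult_design, spec),
        n_pediatric=calc(pediatric_design, spec),
    )


def binary_impact(
    adult_cer: float, pediatric_cer: float, rrr: float, spec: DesignSpec = DesignSpec()
) -> ImpactResult:
    """Impact of a wrong control event rate at a fixed relative risk reduction."""
    return extrapolation_impact(
        BinaryDesign.from_relative_reduction(adult_cer, rrr),
        BinaryDesign.from_relative_reduction(pediatric_cer, rrr),
        spec,
    )


def continuous_impact(
    adult_sd: float, pediatric_sd: float, delta: float, spec: DesignSpec = DesignSpec()
) -> ImpactResult:
    """Impact of a wrong outcome SD at a fixed detectable difference."""
    return extrapolation_impact(
        ContinuousDesign(sd=adult_sd, delta=delta),
        ContinuousDesign(sd=pediatric_sd, delta=delta),
        spec,
    )
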