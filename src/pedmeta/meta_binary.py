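"""Control-event-rate estimation and DerSimonian-Laird pooling for binary outcomes.

Within each meta-analysis the control-group event rates (CERs) of pediatric and
adult trials are pooled separately with a DerSimonian-Laird random-effects
model on the raw proportion scale; the pediatric/adult ratio of the two pooled
CERs (the CER-RR) is then formed on the log scale with a delta-method standard
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from pedmeta.corpus import AgeGroup, BinaryControlArm, EligibilityError, MetaAnalysis

Z_975 = 1.959963984540054  # 97.5% standard-normal quantile


@dataclass(frozen=True)
class Estimate:
    """A point estimate (here a proportion) with its standard error."""

    value: float
    se: float


@dataclass(frozen=True)
class PooledEstimate:
    """DerSimonian-Laird random-effects pool of ``k`` estimates.

    ``i2`` is the percentage of total variability attributable to between-study
    heterogeneity, ``100 * max(0, (Q - df) / Q)``; it is undefined (``None``)
    for single-study pools.
    """

    estimate: float
    se: float
    tau2: float
    q: float
    df: int
    i2: Optional[float]
    k: int


@dataclass(frozen=True)
class RatioEstimate:
    """A ratio carried on the log scale with its standard error and 95% CI."""

    log_value: float
    se_log: float
    value: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_log(cls, log_value: float, se_log: float) -> "RatioEstimate":
        half = Z_975 * se_log
        return cls(
            log_value=log_value,
            se_log=se_log,
            value=math.exp(log_value),
            ci_low=math.exp(log_value - half),
            ci_high=math.exp(log_value + half),
        )


def proportion_se(p: float, n: int) -> float:
    """Normal-approximation standard error of a proportion, sqrt(p(1-p)/n)."""
    if not 0 < p < 1:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return math.sqrt(p * (1.0 - p) / n)


def control_event_rate(arm: BinaryControlArm) -> Estimate:
    """Per-trial control event rate with standard error.

    Zero cells (0 or n events) would make the proportion SE and downstream log
    ratios degenerate, so they receive the correction (events + 0.5) / (n + 1),
    which keeps the rate strictly inside (0, 1); the SE is then computed from
    the corrected rate and size.
    """
    if arm.events in (0, arm.n):
        p = (arm.events + 0.5) / (arm.n + 1)
        n = arm.n + 1
    else:
        p = arm.events / arm.n
        n = arm.n
    return Estimate(value=p, se=proportion_se(p, n))


def needs_zero_cell_correction(arm: BinaryControlArm) -> bool:
    return arm.events in (0, arm.n)


def i_squared(q: float, df: int) -> Optional[float]:
    """Heterogeneity I² in percent; ``None`` when df = 0 (single study)."""
    if q < 0:
        raise ValueError(f"Q must be non-negative, got {q}")
    if df == 0:
        return None
    if q == 0:
        return 0.0
    return 100.0 * max(0.0, (q - df) / q)


def dl_pool(estimates: Sequence[Estimate]) -> PooledEstimate:
    """DerSimonian-Laird random-effects pool.

    Inverse-variance fixed weights give Cochran's Q; the moment estimator
    tau² = max(0, (Q - (k-1)) / (sum(w) - sum(w²)/sum(w))) inflates the weights
    to 1/(se² + tau²) for the random-effects estimate and its SE.
    """
    if not estimates:
        raise ValueError("dl_pool requires at least one estimate")
    if any(e.se <= 0 for e in estimates):
        raise ValueError("all standard errors must be positive")
    k = len(estimates)
    w = [1.0 / (e.se**2) for e in estimates]
    sw = sum(w)
    fixed = sum(wi * e.value for wi, e in zip(w, estimates)) / sw
    q = sum(wi * (e.value - fixed) ** 2 for wi, e in zip(w, estimates))
    df = k - 1
    if df == 0:
        tau2 = 0.0
    else:
        denom = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    wr = [1.0 / (e.se**2 + tau2) for e in estimates]
    swr = sum(wr)
    est = sum(wi * e.value for wi, e in zip(wr, estimates)) / swr
    return PooledEstimate(
        estimate=est,
        se=math.sqrt(1.0 / swr),
        tau2=tau2,
        q=q,
        df=df,
        i2=i_squared(q, df),
        k=k,
    )


def pool_by_age(meta: MetaAnalysis) -> tuple[PooledEstimate, PooledEstimate]:
    """Pool pediatric and adult control event rates separately.

    Unclassified trials contribute to neither pool.
    """
    if meta.outcome_type != "binary":
        raise EligibilityError(f"{meta.ma_id}: not a binary meta-analysis")
    if not meta.eligible:
        raise EligibilityError(
            f"{meta.ma_id}: needs >=1 pediatric and >=1 adult trial "
            f"(pediatric={meta.k_pediatric}, adult={meta.k_adult})"
        )
    ped = dl_pool([control_event_rate(t.arm) for t in meta.trials_in(AgeGroup.PEDIATRIC)])
    adult = dl_pool([control_event_rate(t.arm) for t in meta.trials_in(AgeGroup.ADULT)])
    return ped, adult


def ma_cer_rr(meta: MetaAnalysis) -> RatioEstimate:
    """Pediatric/adult ratio of pooled control event rates for one meta-analysis.

    The log ratio's SE follows by the delta method from the two pooled
    proportions: sqrt(se_p²/p² + se_a²/a²).
    """
    ped, adult = pool_by_age(meta)
    log_value = math.log(ped.estimate / adult.estimate)
    se_log = math.sqrt(
        ped.se**2 / ped.estimate**2 + adult.se**2 / adult.estimate**2
    )
    return RatioEstimate.from_log(log_value, se_log)
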