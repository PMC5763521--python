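"""Pooling of control-group SDs for continuous outcomes.

Pediatric and adult control-group SDs are averaged within each meta-analysis
with square-root-of-sample-size weights; the pediatric/adult ratio of the two
pooled SDs (the CE-SD-ratio) is taken per meta-analysis. No standard error is
attached to the per-meta-analysis ratios: summary statistics alone do not
identify the sampling variance of an SD ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from pedmeta.corpus import AgeGroup, ContinuousControlArm, EligibilityError, MetaAnalysis


@dataclass(frozen=True)
class PooledSD:
    pooled_sd: float
    total_weight: float  # sum of sqrt(n_i)
    k: int


@dataclass(frozen=True)
class SDRatio:
    """Pediatric/adult pooled-SD ratio with its cross-meta-analysis weight."""

    value: float
    log_value: float
    weight: float


def pooled_sd(arms: Sequence[ContinuousControlArm]) -> PooledSD:
    """Weighted average of trial SDs with weights sqrt(n_i)."""
    if not arms:
        raise ValueError("pooled_sd requires at least one trial")
    weights = [math.sqrt(a.n) for a in arms]
    total = sum(weights)
    value = sum(w * a.sd for w, a in zip(weights, arms)) / total
    return PooledSD(pooled_sd=value, total_weight=total, k=len(arms))


def ma_sd_ratio(meta: MetaAnalysis) -> SDRatio:
    """Pediatric/adult ratio of pooled control-group SDs for one meta-analysis.

    The attached weight, used when averaging log ratios across meta-analyses,
    is the square root of the meta-analysis's total control-group sample size
    (both age groups combined).
    """
    if meta.outcome_type != "continuous":
        raise EligibilityError(f"{meta.ma_id}: not a continuous meta-analysis")
    if not meta.eligible:
        raise EligibilityError(
            f"{meta.ma_id}: needs >=1 pediatric and >=1 adult trial "
            f"(pediatric={meta.k_pediatric}, adult={meta.k_adult})"
        )
    ped = pooled_sd([t.arm for t in meta.trials_in(AgeGroup.PEDIATRIC)])
    adult = pooled_sd([t.arm for t in meta.trials_in(AgeGroup.ADULT)])
    value = ped.pooled_sd / adult.pooled_sd
    weight = math.sqrt(sum(t.arm.n for t in meta.trials))
    return SDRatio(value=value, log_value=math.log(value), weight=weight)


def standardize_sds(meta: MetaAnalysis) -> list[tuple[str, AgeGroup, float]]:
    """Divide each trial's SD by the largest SD in its meta-analysis.

    Yields (trial_id, age_group, standardized_sd) tuples with values in (0, 1];
    the trial with the maximum SD scores exactly 1. Scale-free, so pediatric
    and adult spreads are comparable within and across meta-analyses.
    """
    if meta.outcome_type != "continuous":
        raise EligibilityError(f"{meta.ma_id}: not a continuous meta-analysis")
    if not meta.trials:
        raise ValueError(f"{meta.ma_id}: no trials to standardize")
    max_sd = max(t.arm.sd for t in meta.trials)
    return [(t.trial_id, t.age_group, t.arm.sd / max_sd) for t in meta.trials]
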