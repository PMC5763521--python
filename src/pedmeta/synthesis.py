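"""Cross-meta-analysis synthesis of pediatric/adult nuisance-parameter ratios.

One ratio per meta-analysis is carried up to a second-level ("meta-meta")
synthesis: DerSimonian-Laird pooling of log CER-RRs for binary outcomes
(overall and by outcome class), a sqrt-sample-size-weighted mean of log
CE-SD-ratios for continuous outcomes, folded ("absolute ratio") variants of
both quantifying magnitude regardless of direction, and descriptive
distribution reports (I² bins and threshold fractions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from pedmeta.corpus import Corpus
from pedmeta.meta_binary import Estimate, RatioEstimate, dl_pool, ma_cer_rr
from pedmeta.meta_continuous import SDRatio

logger = logging.getLogger(__name__)

# Bin labels for the I² distribution table: "0" is exactly zero; the others
# are half-open intervals (low, high] so the rows are disjoint.
I2_BINS = ["0", "0-20", "20-40", "40-60", "60-80", "80-100"]


@dataclass(frozen=True)
class SummaryResult:
    """A cross-meta-analysis summary ratio.

    Binary summaries carry a 95% CI and the second-level tau²; continuous
    summaries are plain weighted geometric means and leave them ``None``.
    """

    value: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    tau2: Optional[float]
    k: int
    subgroup: str
    folded: bool = False


@dataclass(frozen=True)
class DistributionReport:
    i2_bin_counts: dict[str, int]
    n_i2_undefined: int
    fraction_ped_smaller: float
    fraction_fivefold_ped_smaller: float
    fraction_fivefold_adult_smaller: float
    fraction_twofold_either: float


def absolute_ratio(r: RatioEstimate) -> RatioEstimate:
    """Fold a ratio about 1: replace any value below 1 with its reciprocal.

    Equivalent to taking the absolute value of the log ratio; e.g. 1.25 and
    0.80 both fold to 1.25. The standard error of the log ratio is unchanged.
    """
    return RatioEstimate.from_log(abs(r.log_value), r.se_log)


def summary_cer_rr(
    ratios: Sequence[RatioEstimate], subgroup: str = "overall", folded: bool = False
) -> SummaryResult:
    """Random-effects summary of per-meta-analysis log CER-RRs.

    The log ratios and their SEs are pooled with DerSimonian-Laird; the pooled
    log ratio and its 95% CI are exponentiated back to the ratio scale.
    """
    if not ratios:
        raise ValueError("summary_cer_rr requires at least one ratio")
    pooled = dl_pool([Estimate(value=r.log_value, se=r.se_log) for r in ratios])
    summary = RatioEstimate.from_log(pooled.estimate, pooled.se)
    return SummaryResult(
        value=summary.value,
        ci_low=summary.ci_low,
        ci_high=summary.ci_high,
        tau2=pooled.tau2,
        k=pooled.k,
        subgroup=subgroup,
        folded=folded,
    )


def summary_absolute_cer_rr(
    ratios: Sequence[RatioEstimate], subgroup: str = "overall"
) -> SummaryResult:
    """Summary of folded (magnitude) CER-RRs; always >= 1 in expectation."""
    return summary_cer_rr([absolute_ratio(r) for r in ratios], subgroup=subgroup, folded=True)


def subgroup_summaries(corpus: Corpus) -> list[SummaryResult]:
    """Overall plus per-outcome-class summaries of the binary CER-RRs.

    Classes with no eligible meta-analysis are omitted with a log entry.
    """
    metas = corpus.eligible("binary")
    if not metas:
        raise ValueError("corpus contains no eligible binary meta-analysis")
    ratios = {m.ma_id: ma_cer_rr(m) for m in metas}
    results = [summary_cer_rr(list(ratios.values()), subgroup="overall")]
    for cls in ("mortality", "non_mortality"):
        members = [ratios[m.ma_id] for m in metas if m.outcome_class == cls]
        if not members:
            logger.info("subgroup %s has no eligible meta-analyses; omitted", cls)
            continue
        results.append(summary_cer_rr(members, subgroup=cls))
    return results


def summary_sd_ratio(ratios: Sequence[SDRatio], folded: bool = False) -> SummaryResult:
    """Weighted average of log CE-SD-ratios, exponentiated back.

    Weights are each meta-analysis's sqrt total control-group sample size. The
    folded variant averages |log ratio| instead, measuring magnitude only. No
    CI is produced (see :func:`bootstrap_sd_ratio_ci` for an optional one).
    """
    if not ratios:
        raise ValueError("summary_sd_ratio requires at least one ratio")
    if any(r.weight <= 0 for r in ratios):
        raise ValueError("all weights must be positive")
    logs = [abs(r.log_value) if folded else r.log_value for r in ratios]
    total = sum(r.weight for r in ratios)
    mean_log = sum(w.weight * L for w, L in zip(ratios, logs)) / total
    return SummaryResult(
        value=math.exp(mean_log),
        ci_low=None,
        ci_high=None,
        tau2=None,
        k=len(ratios),
        subgroup="overall",
        folded=folded,
    )


def bootstrap_sd_ratio_ci(
    ratios: Sequence[SDRatio],
    folded: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI for the summary SD ratio.

    Resamples meta-analyses with replacement. Off by default in the pipeline:
    it is an aid for synthetic experiments, not part of the core analysis.
    """
    rng = np.random.default_rng(seed)
    ratios = list(ratios)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(ratios), size=len(ratios))
        stats[b] = summary_sd_ratio([ratios[i] for i in idx], folded=folded).value
    low, high = np.quantile(stats, [0.025, 0.975])
    return float(low), float(high)


def bin_i2(i2: float) -> str:
    """Bin an I² percentage: exactly 0, then half-open (low, high] bins."""
    if not 0 <= i2 <= 100:
        raise ValueError(f"I² must lie in [0, 100], got {i2}")
    if i2 == 0:
        return "0"
    for low, high, label in ((0, 20, "0-20"), (20, 40, "20-40"), (40, 60, "40-60"),
                             (60, 80, "60-80"), (80, 100, "80-100")):
        if low < i2 <= high:
            return label
    raise AssertionError("unreachable")


def distribution_report(
    ratios: Sequence[float],
    i2_values: Sequence[Optional[float]] = (),
) -> DistributionReport:
    """Descriptive distribution of per-meta-analysis ratios and pool I² values.

    ``ratios`` are pediatric/adult ratios (CER-RRs or CE-SD-ratios); the
    threshold fractions use inclusive bounds: five-fold smaller means
    ratio <= 0.2, five-fold larger (adult smaller) means ratio >= 5, two-fold
    in either direction means ratio <= 0.5 or ratio >= 2. ``i2_values`` are the
    within-meta-analysis pool I² values (one per age-group pool); ``None``
    entries, arising from single-study pools where I² is undefined, are counted
    separately rather than binned.
    """
    if not ratios:
        raise ValueError("distribution_report requires at least one ratio")
    counts = {label: 0 for label in I2_BINS}
    undefined = 0
    for i2 in i2_values:
        if i2 is None:
            undefined += 1
        else:
            counts[bin_i2(i2)] += 1
    k = len(ratios)
    return DistributionReport(
        i2_bin_counts=counts,
        n_i2_undefined=undefined,
        fraction_ped_smaller=sum(r < 1 for r in ratios) / k,
        fraction_fivefold_ped_smaller=sum(r <= 0.2 for r in ratios) / k,
        fraction_fivefold_adult_smaller=sum(r >= 5 for r in ratios) / k,
        fraction_twofold_either=sum(r <= 0.5 or r >= 2 for r in ratios) / k,
    )
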