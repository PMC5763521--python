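"""Seeded generator of synthetic trial corpora.

No trial-level data from the source corpus are redistributable, so the
pipeline is exercised on synthetic corpora that reproduce its statistical
structure: meta-analyses of a handful of trials each, adult baseline control
event rates spread across meta-analyses on the logit scale, a systematic
multiplicative pediatric/adult contrast in the nuisance parameter, between-
trial heterogeneity large enough to reach the high-I² regime seen in real
corpora, binomial event counts, and chi-square-distributed sample SDs.

Defaults are calibration anchors echoing the real-data summaries (pediatric
CERs about 10% below adult ones, pediatric SDs about 26% below), not claims of
reproducing the source corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from pedmeta.corpus import (
    AgeGroup,
    BinaryControlArm,
    ContinuousControlArm,
    Corpus,
    MetaAnalysis,
    TrialRecord,
)

_CER_CLAMP = (0.001, 0.999)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    ``true_cer_rr`` and ``true_sd_ratio`` are the generative pediatric/adult
    contrasts the pipeline should recover. ``within_ma_tau_logit`` is the SD of
    trial-level logit control rates around their age group's baseline; 0.6
    places roughly half of multi-trial pools above I² = 80%.
    ``trials_per_ma_range`` applies to each age group separately, so every
    generated meta-analysis is eligible by construction; its lower bound of 1
    lets single-study pools (undefined I²) occur, as they do in real corpora.
    """

    n_meta_binary: int = 200
    n_meta_continuous: int = 100
    trials_per_ma_range: tuple[int, int] = (1, 6)
    n_per_trial_range: tuple[int, int] = (20, 200)
    true_cer_rr: float = 0.90
    true_sd_ratio: float = 0.74
    baseline_cer_logit_mean: float = -1.3862943611198906  # logit(0.2)
    baseline_cer_logit_sd: float = 1.0
    within_ma_tau_logit: float = 0.6
    baseline_sd_log_mean: float = 2.302585092994046  # log(10)
    baseline_sd_log_sd: float = 1.0
    fraction_mortality: float = 21 / 135
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trials_per_ma_range", "n_per_trial_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty range with lower bound >= 1")
        if self.n_per_trial_range[0] < 2:
            raise ValueError("n_per_trial_range lower bound must be >= 2 (SDs need n >= 2)")
        if self.true_cer_rr <= 0 or self.true_sd_ratio <= 0:
            raise ValueError("true ratios must be positive")
        if self.true_cer_rr >= 1 / _CER_CLAMP[0]:
            raise ValueError("true_cer_rr would push pediatric rates outside (0, 1)")
        if self.within_ma_tau_logit < 0:
            raise ValueError("within_ma_tau_logit must be non-negative")
        if not 0 <= self.fraction_mortality <= 1:
            raise ValueError("fraction_mortality must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("trials_per_ma_range", "n_per_trial_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _group_sizes(config: GeneratorConfig, rng: np.random.Generator) -> tuple[int, int]:
    lo, hi = config.trials_per_ma_range
    return int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))


def generate_binary_ma(
    config: GeneratorConfig, rng: np.random.Generator, ma_index: int = 0
) -> MetaAnalysis:
    """One synthetic binary-outcome meta-analysis.

    The adult baseline CER is logit-normal across meta-analyses; the pediatric
    baseline is the adult one scaled by ``true_cer_rr`` on the risk scale (the
    estimand is a ratio of raw pooled rates), clamped into (0.001, 0.999).
    Trial CERs scatter around their group baseline on the logit scale with SD
    ``within_ma_tau_logit``; event counts are binomial.
    """
    ma_id = f"bin{ma_index:04d}"
    adult_cer = _expit(rng.normal(config.baseline_cer_logit_mean, config.baseline_cer_logit_sd))
    adult_cer = min(max(adult_cer, _CER_CLAMP[0]), _CER_CLAMP[1])
    ped_cer = min(max(adult_cer * config.true_cer_rr, _CER_CLAMP[0]), _CER_CLAMP[1])
    outcome_class = (
        "mortality" if rng.random() < config.fraction_mortality else "non_mortality"
    )
    trials: list[TrialRecord] = []
    k_ped, k_adult = _group_sizes(config, rng)
    for group, baseline, k in (
        (AgeGroup.PEDIATRIC, ped_cer, k_ped),
        (AgeGroup.ADULT, adult_cer, k_adult),
    ):
        for j in range(k):
            cer = _expit(rng.normal(_logit(baseline), config.within_ma_tau_logit))
            n = int(rng.integers(config.n_per_trial_range[0], config.n_per_trial_range[1] + 1))
            events = int(rng.binomial(n, cer))
            trials.append(
                TrialRecord(
                    trial_id=f"{ma_id}_{group.value[:3]}{j:02d}",
                    age_group=group,
                    arm=BinaryControlArm(events=events, n=n),
                )
            )
    return MetaAnalysis(
        ma_id=ma_id,
        review_id=f"rev_b{ma_index:04d}",
        outcome_type="binary",
        outcome_class=outcome_class,
        trials=trials,
    )


def generate_continuous_ma(
    config: GeneratorConfig, rng: np.random.Generator, ma_index: int = 0
) -> MetaAnalysis:
    """One synthetic continuous-outcome meta-analysis.

    The adult true SD is lognormal across meta-analyses; the pediatric true SD
    is scaled by ``true_sd_ratio``. Each trial's sample SD is drawn as
    σ sqrt(χ²_{n-1} / (n-1)), the exact sampling law for a normal outcome;
    control-arm means are drawn too but are nuisance to the pipeline.
    """
    ma_id = f"con{ma_index:04d}"
    adult_sigma = math.exp(rng.normal(config.baseline_sd_log_mean, config.baseline_sd_log_sd))
    ped_sigma = adult_sigma * config.true_sd_ratio
    trials: list[TrialRecord] = []
    k_ped, k_adult = _group_sizes(config, rng)
    for group, sigma, k in (
        (AgeGroup.PEDIATRIC, ped_sigma, k_ped),
        (AgeGroup.ADULT, adult_sigma, k_adult),
    ):
        for j in range(k):
            n = int(rng.integers(config.n_per_trial_range[0], config.n_per_trial_range[1] + 1))
            sd = sigma * math.sqrt(rng.chisquare(n - 1) / (n - 1))
            mean = rng.normal(0.0, sigma)
            trials.append(
                TrialRecord(
                    trial_id=f"{ma_id}_{group.value[:3]}{j:02d}",
                    age_group=group,
                    arm=ContinuousControlArm(mean=mean, sd=sd, n=n),
                )
            )
    return MetaAnalysis(
        ma_id=ma_id,
        review_id=f"rev_c{ma_index:04d}",
        outcome_type="continuous",
        outcome_class="not_applicable",
        trials=trials,
    )


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """A full synthetic corpus; identical config (including seed) gives an identical corpus."""
    rng = np.random.default_rng(config.seed)
    metas = [
        generate_binary_ma(config, rng, i) for i in range(config.n_meta_binary)
    ] + [
        generate_continuous_ma(config, rng, i) for i in range(config.n_meta_continuous)
    ]
    return Corpus(meta_analyses=metas)
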