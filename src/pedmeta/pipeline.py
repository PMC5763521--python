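"""End-to-end pipeline: corpus in, tidy result tables out.

Every number in the emitted tables is recomputable by calling the module
functions directly; this layer only orchestrates, formats, and logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from pedmeta import meta_binary, meta_continuous, synthesis
from pedmeta.corpus import AgeGroup, BinaryControlArm, Corpus
from pedmeta.meta_binary import RatioEstimate
from pedmeta.meta_continuous import SDRatio

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    binary_ma: pd.DataFrame
    continuous_ma: pd.DataFrame
    standardized_sd: pd.DataFrame
    summaries: pd.DataFrame
    i2_distribution: pd.DataFrame
    thresholds: pd.DataFrame
    run_log: list[str] = field(default_factory=list)


def _sig(x, digits: int) -> object:
    if digits <= 0 or x is None or isinstance(x, (int, str)):
        return x
    return float(f"{x:.{digits}g}")


def analyze_corpus(
    corpus: Corpus,
    seed: Optional[int] = None,
    bootstrap: int = 0,
    subgroups: bool = True,
    folded: bool = True,
) -> PipelineResult:
    """Run the full two-level analysis on a validated corpus.

    ``bootstrap`` > 0 attaches a percentile-bootstrap CI (that many resamples)
    to the continuous summaries, which otherwise carry none; ``seed`` feeds the
    bootstrap only — the analysis itself is deterministic.
    """
    log: list[str] = [f"seed={seed}"]
    binary = corpus.eligible("binary")
    continuous = corpus.eligible("continuous")
    n_inelig = sum(1 for m in corpus if not m.eligible)
    log.append(f"meta_analyses={len(corpus)} eligible_binary={len(binary)} "
               f"eligible_continuous={len(continuous)} ineligible={n_inelig}")
    for m in corpus:
        if not m.eligible:
            log.append(f"ineligible: {m.ma_id} (pediatric={m.k_pediatric}, adult={m.k_adult})")

    n_zero_cell = sum(
        1
        for m in binary
        for t in m.trials
        if isinstance(t.arm, BinaryControlArm) and meta_binary.needs_zero_cell_correction(t.arm)
    )
    log.append(f"zero_cell_corrections={n_zero_cell}")

    # Per-meta-analysis binary results.
    bin_rows = []
    ratios: dict[str, RatioEstimate] = {}
    i2_values: list[Optional[float]] = []
    for m in binary:
        ped, adult = meta_binary.pool_by_age(m)
        rr = meta_binary.ma_cer_rr(m)
        ratios[m.ma_id] = rr
        i2_values.extend([ped.i2, adult.i2])
        bin_rows.append({
            "ma_id": m.ma_id,
            "outcome_class": m.outcome_class,
            "k_pediatric": ped.k,
            "k_adult": adult.k,
            "pooled_cer_pediatric": ped.estimate,
            "se_pediatric": ped.se,
            "i2_pediatric": ped.i2,
            "pooled_cer_adult": adult.estimate,
            "se_adult": adult.se,
            "i2_adult": adult.i2,
            "cer_rr": rr.value,
            "ci_low": rr.ci_low,
            "ci_high": rr.ci_high,
            "log_cer_rr": rr.log_value,
            "se_log": rr.se_log,
        })
    binary_ma = pd.DataFrame(
        bin_rows,
        columns=[
            "ma_id", "outcome_class", "k_pediatric", "k_adult",
            "pooled_cer_pediatric", "se_pediatric", "i2_pediatric",
            "pooled_cer_adult", "se_adult", "i2_adult",
            "cer_rr", "ci_low", "ci_high", "log_cer_rr", "se_log",
        ],
    )

    # Per-meta-analysis continuous results and the standardized-SD long table.
    con_rows, std_rows = [], []
    sd_ratios: list[SDRatio] = []
    for m in continuous:
        ped = meta_continuous.pooled_sd([t.arm for t in m.trials_in(AgeGroup.PEDIATRIC)])
        adult = meta_continuous.pooled_sd([t.arm for t in m.trials_in(AgeGroup.ADULT)])
        sr = meta_continuous.ma_sd_ratio(m)
        sd_ratios.append(sr)
        con_rows.append({
            "ma_id": m.ma_id,
            "k_pediatric": ped.k,
            "k_adult": adult.k,
            "pooled_sd_pediatric": ped.pooled_sd,
            "pooled_sd_adult": adult.pooled_sd,
            "sd_ratio": sr.value,
            "weight": sr.weight,
        })
        for trial_id, group, value in meta_continuous.standardize_sds(m):
            std_rows.append({
                "ma_id": m.ma_id,
                "trial_id": trial_id,
                "age_group": group.value,
                "standardized_sd": value,
            })
    continuous_ma = pd.DataFrame(
        con_rows,
        columns=[
            "ma_id", "k_pediatric", "k_adult", "pooled_sd_pediatric",
            "pooled_sd_adult", "sd_ratio", "weight",
        ],
    )
    standardized_sd = pd.DataFrame(
        std_rows, columns=["ma_id", "trial_id", "age_group", "standardized_sd"]
    )

    # Cross-meta-analysis summaries.
    summary_results: list[tuple[str, synthesis.SummaryResult]] = []
    if binary:
        if subgroups:
            for s in synthesis.subgroup_summaries(corpus):
                summary_results.append(("binary", s))
        else:
            summary_results.append(("binary", synthesis.summary_cer_rr(list(ratios.values()))))
        if folded:
            summary_results.append(
                ("binary", synthesis.summary_absolute_cer_rr(list(ratios.values())))
            )
    if sd_ratios:
        for fold in ([False, True] if folded else [False]):
            s = synthesis.summary_sd_ratio(sd_ratios, folded=fold)
            if bootstrap > 0:
                lo, hi = synthesis.bootstrap_sd_ratio_ci(
                    sd_ratios, folded=fold, n_boot=bootstrap, seed=0 if seed is None else seed
                )
                s = synthesis.SummaryResult(
                    value=s.value, ci_low=lo, ci_high=hi, tau2=None,
                    k=s.k, subgroup=s.subgroup, folded=s.folded,
                )
            summary_results.append(("continuous", s))
    summaries = pd.DataFrame(
        [
            {
                "outcome_type": kind,
                "subgroup": s.subgroup,
                "folded": s.folded,
                "k": s.k,
                "summary_ratio": s.value,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "tau2": s.tau2,
            }
            for kind, s in summary_results
        ],
        columns=[
            "outcome_type", "subgroup", "folded", "k",
            "summary_ratio", "ci_low", "ci_high", "tau2",
        ],
    )

    # Descriptive distributions.
    i2_rows, thr_rows = [], []
    if binary:
        rep = synthesis.distribution_report([r.value for r in ratios.values()], i2_values)
        i2_rows = [{"i2_bin": b, "count": c} for b, c in rep.i2_bin_counts.items()]
        i2_rows.append({"i2_bin": "undefined", "count": rep.n_i2_undefined})
        thr_rows += [
            {"outcome_type": "binary", "metric": m, "value": v}
            for m, v in (
                ("fraction_ped_smaller", rep.fraction_ped_smaller),
                ("fraction_fivefold_ped_smaller", rep.fraction_fivefold_ped_smaller),
                ("fraction_fivefold_adult_smaller", rep.fraction_fivefold_adult_smaller),
                ("fraction_twofold_either", rep.fraction_twofold_either),
            )
        ]
    if sd_ratios:
        rep = synthesis.distribution_report([r.value for r in sd_ratios])
        thr_rows += [
            {"outcome_type": "continuous", "metric": m, "value": v}
            for m, v in (
                ("fraction_ped_smaller", rep.fraction_ped_smaller),
                ("fraction_twofold_either", rep.fraction_twofold_either),
            )
        ]

    return PipelineResult(
        binary_ma=binary_ma,
        continuous_ma=continuous_ma,
        standardized_sd=standardized_sd,
        summaries=summaries,
        i2_distribution=pd.DataFrame(i2_rows, columns=["i2_bin", "count"]),
        thresholds=pd.DataFrame(thr_rows, columns=["outcome_type", "metric", "value"]),
        run_log=log,
    )


def write_result(
    result: PipelineResult, out_dir: Union[str, Path], digits: int = 6
) -> dict[str, Path]:
    """Write all result tables as CSV plus a run log.

    Floats are rounded to ``digits`` significant digits for reproducible diffs;
    pass ``digits=0`` for full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "binary_ma": result.binary_ma,
        "continuous_ma": result.continuous_ma,
        "standardized_sd": result.standardized_sd,
        "summaries": result.summaries,
        "i2_distribution": result.i2_distribution,
        "thresholds": result.thresholds,
    }
    paths = {}
    for name, table in tables.items():
        path = out / f"{name}.csv"
        formatted = table.map(lambda x: _sig(x, digits)) if len(table) else table
        formatted.to_csv(path, index=False)
        paths[name] = path
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(result.run_log) + "\n")
    paths["run_log"] = log_path
    return paths


def run_pipeline(
    corpus: Corpus,
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
    bootstrap: int = 0,
    subgroups: bool = True,
    folded: bool = True,
    digits: int = 6,
) -> PipelineResult:
    """Analyze a corpus and write the report bundle; fails loudly on an empty one."""
    if not corpus.eligible("binary") and not corpus.eligible("continuous"):
        raise ValueError(
            "corpus has no eligible meta-analysis of either outcome type; nothing to analyze"
        )
    result = analyze_corpus(
        corpus, seed=seed, bootstrap=bootstrap, subgroups=subgroups, folded=folded
    )
    write_result(result, out_dir, digits=digits)
    return result
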