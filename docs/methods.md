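# Methods

## Estimands and procedure

The pipeline targets two pediatric/adult contrasts in trial-design nuisance
parameters, each defined within a meta-analysis and then synthesized across
meta-analyses:

1. **CER-RR** — the ratio of the DerSimonian–Laird-pooled pediatric control
   event rate to the pooled adult one, per binary-outcome meta-analysis.
2. **CE-SD-ratio** — the ratio of √n-weighted mean pediatric control-group SD
   to the adult one, per continuous-outcome meta-analysis.

Level 1 (within meta-analysis): CERs are pooled on the raw proportion scale,
not the logit scale, because the estimand is a ratio of raw pooled rates; the
ratio is then formed from the two pooled values. Level 2 (across
meta-analyses): log CER-RRs with their delta-method SEs are pooled by
DerSimonian–Laird again; log CE-SD-ratios, which carry no SE, are averaged
with weights equal to the square root of each meta-analysis's total
control-group sample size and exponentiated.

Magnitude ("folded") analyses replace each ratio below 1 by its reciprocal —
equivalently pool |log ratio| — *before* the level-2 synthesis, keeping each
ratio's original SE or weight. A folded summary near 1 means pediatric and
adult nuisance parameters genuinely agree; a directional summary near 1 can
also arise from large disagreements that cancel.

## Statistical choices

- **SE of a proportion**: sqrt(p(1−p)/n), the normal approximation. This is
  the only normal-theory SE consistent with pooling raw proportions; results
  on other corpora could differ slightly under other variance estimators.
- **Zero cells**: arms with 0 or n events take (events+0.5)/(n+1), and the SE
  uses the corrected rate and the corrected size n+1. Applied only at the
  boundary, so interior rates are untouched. The pipeline's run log counts
  every correction applied.
- **τ² estimator**: the moment (DerSimonian–Laird) estimator with the usual
  non-negativity clamp; τ² = 0 whenever Q ≤ k−1.
- **I²**: 100·max(0, (Q−df)/Q), reported as undefined (not 0) for
  single-study pools; the distribution table bins it as {exactly 0, (0,20],
  (20,40], (40,60], (60,80], (80,100]} with undefined counted separately. The
  "exactly 0" bin is distinct from (0,20] so the two rows cannot overlap.
- **CIs**: normal quantile 1.959964 throughout, no Knapp–Hartung adjustment,
  matching classic random-effects output. Continuous summaries carry no CI by
  default because summary statistics do not identify the sampling variance of
  an SD ratio; an optional seeded nonparametric bootstrap over meta-analyses
  (`bootstrap_sd_ratio_ci`, percentile, resampling meta-analyses with
  replacement) is available but off by default.
- **Threshold fractions** use inclusive bounds (≤ 0.2, ≥ 5, ≤ 0.5, ≥ 2),
  reading "at least k-fold" as inclusive.
- **Age classification**: adult iff min age > 12 and max age > 20; pediatric
  iff max age < 20 and min age < 12; strict inequalities, so exactly-12 or
  exactly-20 boundaries fail the rule. An explicitly reported age-group label
  takes precedence over the classifier. Unclassified trials stay in the
  corpus but join neither pool.
- **Eligibility**: a meta-analysis enters synthesis only with ≥ 1 pediatric
  and ≥ 1 adult trial; ineligible ones are retained, flagged, and logged
  rather than dropped, for auditability.
- **Sample sizes**: two-proportion designs use variance pooled under H0
  (2·p̄q̄) and unpooled under H1, ceiling-rounded, no continuity correction;
  two-means designs use n = ⌈2σ²(z₁₋α/₂+z₁₋β)²/δ²⌉. A "30% reduction" is
  relative: p_t = 0.7·p_c. The extrapolation-impact helper holds the relative
  risk reduction (binary) or detectable difference (continuous) fixed and
  swaps only the nuisance parameter; it returns both n values because the
  direction of the error is not monotone for binary designs.

## Synthetic corpus

The generator emulates the structure the analysis assumes, with defaults
fixed once:

| parameter | default | rationale |
|---|---|---|
| n_meta_binary / n_meta_continuous | 200 / 100 | corpus of a few hundred meta-analyses; enough for level-2 CIs of a few percent |
| trials_per_ma_range (per age group) | 1–6 | small clusters; lower bound 1 lets single-study pools (undefined I²) occur, as they commonly do |
| n_per_trial_range (control arm) | 20–200 | typical control-arm sizes in systematic reviews |
| true_cer_rr / true_sd_ratio | 0.90 / 0.74 | calibration anchors: pediatric CERs ~10% and SDs ~26% below adult values |
| baseline CER across MAs | logit-normal(logit 0.2, 1.0) | event rates spread over roughly 0.03–0.65 |
| within_ma_tau_logit | 0.6 | places roughly half of multi-trial pools above I² = 80%, the high-heterogeneity regime seen in real corpora |
| baseline SD across MAs | lognormal(log 10, 1.0) | an order of magnitude of spread in outcome units |
| fraction_mortality | 21/135 | minority mortality subgroup |

Binary meta-analyses: the pediatric baseline is the adult baseline times
`true_cer_rr` on the risk scale (clamped into (0.001, 0.999)); trial-level
rates scatter around their group baseline on the logit scale; events are
binomial. Continuous meta-analyses: the pediatric true SD is the adult one
times `true_sd_ratio`; each trial's sample SD is σ·sqrt(χ²₍ₙ₋₁₎/(n−1)), the
exact sampling law under normality; control-arm means are generated but
unused downstream.

What the generator does **not** emulate: treatment arms and effect sizes,
correlation between meta-analyses from a shared review, trials contributing
to several meta-analyses, literature-selection effects, or non-normal
outcomes. Passing recovery tests therefore shows the *pipeline* is correct
and well-calibrated under its assumed data-generating process — not that any
particular real corpus obeys those assumptions.

Two small systematic effects are worth knowing about. Pooling raw proportions
with rate-dependent weights, and averaging logit-normal draws on the risk
scale, each bias the recovered CER ratio slightly toward 1 (below 1% at the
defaults, well inside the level-2 CI at 200 meta-analyses). The folded
summaries are upward-biased for finite SE even when the true contrast is
exactly 1, since |log r̂| > 0 almost surely; that is a property of the
magnitude estimand itself, not an implementation artifact.

## Problem sizes

The recovery benchmarks run at 200 binary and 100 continuous meta-analyses —
the generator defaults — which complete in seconds and give Monte-Carlo bands
(from the run's own SE) of about ±7% on the binary summary and ±3% on the
continuous one. The DerSimonian–Laird implementation is checked against an
independently coded brute-force transcription on 1,000 random pools of 2–10
studies at 1e-10 relative tolerance.

## Known limitations

- The SE of a pooled proportion is approximate near 0 or 1; extremely rare
  events make the delta-method CER-RR SE anti-conservative.
- The level-2 model treats per-meta-analysis log ratios as independent
  normals with known variance; with few meta-analyses the usual DL
  undercoverage applies.
- Continuous summaries are point estimates only unless the bootstrap is
  requested.
- `analysis/01_simulate.py` must be run before `analysis/02_analyze_corpus.py`;
  the generated corpus is not stored in the repository.
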