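import math

import numpy as np
import pytest

from pedmeta.corpus import (
    AgeGroup,
    BinaryControlArm,
    EligibilityError,
    MetaAnalysis,
    TrialRecord,
)
from pedmeta.meta_binary import (
    Estimate,
    control_event_rate,
    dl_pool,
    i_squared,
    ma_cer_rr,
    pool_by_age,
    proportion_se,
)


def dl_pool_brute_force(values, ses):
    """Straight transcription of the DerSimonian-Laird formulas, kept deliberately
    separate from the library implementation as an independent oracle."""
    k = len(values)
    w = [1.0 / s / s for s in ses]
    xbar = sum(wi * xi for wi, xi in zip(w, values)) / sum(w)
    q = 0.0
    for wi, xi in zip(w, values):
        q += wi * (xi - xbar) ** 2
    if k == 1:
        tau2 = 0.0
    else:
        c = sum(w) - sum(wi * wi for wi in w) / sum(w)
        tau2 = (q - (k - 1)) / c
        if tau2 < 0:
            tau2 = 0.0
    wstar = [1.0 / (s * s + tau2) for s in ses]
    est = sum(wi * xi for wi, xi in zip(wstar, values)) / sum(wstar)
    se = (1.0 / sum(wstar)) ** 0.5
    return est, se, tau2, q


class TestControlEventRate:
    def test_plain_division(self):
        est = control_event_rate(BinaryControlArm(events=48, n=100))
        assert est.value == pytest.approx(0.48)
        assert est.se == pytest.approx(math.sqrt(0.48 * 0.52 / 100))

    @pytest.mark.parametrize(
        "events,n,expected",
        [(0, 50, 0.5 / 51), (50, 50, 50.5 / 51)],
    )
    def test_zero_cell_correction_keeps_rate_interior(self, events, n, expected):
        """All-or-none control arms get (events + 0.5)/(n + 1) so log ratios exist."""
        est = control_event_rate(BinaryControlArm(events=events, n=n))
        assert est.value == pytest.approx(expected)
        assert 0 < est.value < 1
        assert est.se == pytest.approx(math.sqrt(expected * (1 - expected) / (n + 1)))


@pytest.mark.parametrize(
    "p,n,expected",
    [(0.5, 100, 0.05), (0.48, 100, 0.049960), (0.2, 50, 0.056569)],
)
def test_proportion_se_normal_approximation(p, n, expected):
    assert proportion_se(p, n) == pytest.approx(expected, abs=5e-7)


@pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
def test_proportion_se_domain(p):
    with pytest.raises(ValueError):
        proportion_se(p, 100)


class TestISquared:
    @pytest.mark.parametrize(
        "q,df,expected", [(8, 1, 87.5), (0.5, 1, 0.0), (3, 3, 0.0), (0, 5, 0.0)]
    )
    def test_values(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)

    def test_undefined_for_single_study(self):
        assert i_squared(0.0, 0) is None


class TestDLPool:
    def test_single_study_identity(self):
        pooled = dl_pool([Estimate(0.3, 0.05)])
        assert (pooled.estimate, pooled.se, pooled.tau2) == (0.3, 0.05, 0.0)
        assert pooled.i2 is None and pooled.k == 1

    def test_identical_studies_halve_variance(self):
        pooled = dl_pool([Estimate(0.3, 0.05), Estimate(0.3, 0.05)])
        assert pooled.estimate == pytest.approx(0.3)
        assert pooled.se == pytest.approx(0.05 / math.sqrt(2))
        assert pooled.q == pytest.approx(0.0)
        assert pooled.tau2 == 0.0 and pooled.i2 == pytest.approx(0.0)

    def test_hand_computed_heterogeneous_pair(self):
        """w=400 each, Q=8, tau²=(8-1)/400, equal random weights → plain mean."""
        pooled = dl_pool([Estimate(0.2, 0.05), Estimate(0.4, 0.05)])
        assert pooled.estimate == pytest.approx(0.3)
        assert pooled.q == pytest.approx(8.0)
        assert pooled.tau2 == pytest.approx(0.0175)
        assert pooled.se == pytest.approx(0.1)
        assert pooled.i2 == pytest.approx(87.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dl_pool([])

    def test_matches_brute_force_oracle_on_random_instances(self):
        """1,000 random small pools agree with the independent transcription to 1e-10."""
        rng = np.random.default_rng(20260927)
        for _ in range(1000):
            k = int(rng.integers(2, 11))
            values = rng.uniform(0.01, 0.99, size=k)
            ses = rng.uniform(0.005, 0.3, size=k)
            pooled = dl_pool([Estimate(v, s) for v, s in zip(values, ses)])
            est, se, tau2, q = dl_pool_brute_force(list(values), list(ses))
            assert pooled.estimate == pytest.approx(est, rel=1e-10)
            assert pooled.se == pytest.approx(se, rel=1e-10)
            assert pooled.tau2 == pytest.approx(tau2, rel=1e-10, abs=1e-12)
            assert pooled.q == pytest.approx(q, rel=1e-10)

    def test_matches_statsmodels_combine_effects(self):
        """Third-party cross-check: statsmodels' DL agrees where tau² is positive
        (statsmodels does not clamp a negative moment estimate; Q always agrees)."""
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(8)
        checked = 0
        while checked < 50:
            k = int(rng.integers(2, 11))
            values = rng.uniform(0.01, 0.99, size=k)
            ses = rng.uniform(0.005, 0.3, size=k)
            with np.errstate(invalid="ignore"):  # statsmodels sqrt of unclamped tau2
                res = combine_effects(values, ses**2, method_re="dl")
            pooled = dl_pool([Estimate(v, s) for v, s in zip(values, ses)])
            assert pooled.q == pytest.approx(res.q, rel=1e-9)
            if res.tau2 > 0:
                assert pooled.tau2 == pytest.approx(res.tau2, rel=1e-9)
                assert pooled.estimate == pytest.approx(res.mean_effect_re, rel=1e-9)
                assert pooled.se == pytest.approx(res.sd_eff_w_re, rel=1e-9)
                checked += 1

    def test_estimate_within_input_range_and_tau2_clamped(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = int(rng.integers(1, 8))
            ests = [Estimate(v, s) for v, s in zip(
                rng.uniform(0.05, 0.95, k), rng.uniform(0.01, 0.2, k))]
            pooled = dl_pool(ests)
            values = [e.value for e in ests]
            assert min(values) - 1e-12 <= pooled.estimate <= max(values) + 1e-12
            assert pooled.tau2 >= 0.0
            if pooled.q <= pooled.df:
                assert pooled.tau2 == 0.0

    def test_equal_se_zero_tau2_reduces_to_mean(self):
        ests = [Estimate(v, 0.1) for v in (0.2, 0.25, 0.3)]
        pooled = dl_pool(ests)
        if pooled.tau2 == 0.0:
            assert pooled.estimate == pytest.approx(0.25)
        # equal ses always give the arithmetic mean whatever tau2 is
        assert pooled.estimate == pytest.approx(0.25)


def _swap_labels(meta):
    flip = {AgeGroup.PEDIATRIC: AgeGroup.ADULT, AgeGroup.ADULT: AgeGroup.PEDIATRIC}
    return MetaAnalysis(
        ma_id=meta.ma_id,
        review_id=meta.review_id,
        outcome_type=meta.outcome_type,
        outcome_class=meta.outcome_class,
        trials=[
            TrialRecord(t.trial_id, flip.get(t.age_group, t.age_group), t.arm)
            for t in meta.trials
        ],
    )


class TestMaCerRR:
    def test_delta_method_se(self, binary_ma):
        ped, adult = pool_by_age(binary_ma)
        rr = ma_cer_rr(binary_ma)
        assert rr.value == pytest.approx(ped.estimate / adult.estimate)
        expected_se = math.sqrt(
            ped.se**2 / ped.estimate**2 + adult.se**2 / adult.estimate**2
        )
        assert rr.se_log == pytest.approx(expected_se)
        assert rr.ci_low == pytest.approx(rr.value * math.exp(-1.959964 * rr.se_log), rel=1e-6)

    def test_tenfold_smaller_pediatric_rate(self):
        """Pooled pediatric CER 0.048 against adult 0.48 gives a ratio of 0.1."""
        meta = MetaAnalysis(
            ma_id="m", review_id="r", outcome_type="binary",
            outcome_class="non_mortality",
            trials=[
                TrialRecord("p", AgeGroup.PEDIATRIC, BinaryControlArm(events=48, n=1000)),
                TrialRecord("a", AgeGroup.ADULT, BinaryControlArm(events=480, n=1000)),
            ],
        )
        assert ma_cer_rr(meta).value == pytest.approx(0.1)

    def test_identical_groups_give_unit_ratio(self, binary_ma):
        mirrored = MetaAnalysis(
            ma_id="m", review_id="r", outcome_type="binary",
            outcome_class="non_mortality",
            trials=[
                TrialRecord("p", AgeGroup.PEDIATRIC, BinaryControlArm(events=30, n=100)),
                TrialRecord("a", AgeGroup.ADULT, BinaryControlArm(events=30, n=100)),
            ],
        )
        rr = ma_cer_rr(mirrored)
        assert rr.value == pytest.approx(1.0)
        assert rr.log_value == pytest.approx(0.0)

    def test_label_swap_inverts_ratio_keeps_se(self, binary_ma):
        rr = ma_cer_rr(binary_ma)
        swapped = ma_cer_rr(_swap_labels(binary_ma))
        assert swapped.value == pytest.approx(1.0 / rr.value)
        assert swapped.se_log == pytest.approx(rr.se_log)

    def test_ineligible_meta_rejected(self, binary_ma):
        adults_only = MetaAnalysis(
            ma_id="m", review_id="r", outcome_type="binary",
            outcome_class="mortality",
            trials=[t for t in binary_ma.trials if t.age_group is AgeGroup.ADULT],
        )
        with pytest.raises(EligibilityError):
            ma_cer_rr(adults_only)
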