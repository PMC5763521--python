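import pytest

from pedmeta.corpus import (
    AgeGroup,
    BinaryControlArm,
    ContinuousControlArm,
    Corpus,
    MetaAnalysis,
    TrialRecord,
)


def _trial(trial_id, group, arm):
    return TrialRecord(trial_id=trial_id, age_group=group, arm=arm)


@pytest.fixture
def binary_ma():
    """Two pediatric + two adult trials, binary outcome."""
    return MetaAnalysis(
        ma_id="ma_b1",
        review_id="rev1",
        outcome_type="binary",
        outcome_class="non_mortality",
        trials=[
            _trial("p1", AgeGroup.PEDIATRIC, BinaryControlArm(events=10, n=100)),
            _trial("p2", AgeGroup.PEDIATRIC, BinaryControlArm(events=20, n=80)),
            _trial("a1", AgeGroup.ADULT, BinaryControlArm(events=48, n=100)),
            _trial("a2", AgeGroup.ADULT, BinaryControlArm(events=30, n=60)),
        ],
    )


@pytest.fixture
def continuous_ma():
    """One pediatric + two adult trials, continuous outcome."""
    return MetaAnalysis(
        ma_id="ma_c1",
        review_id="rev2",
        outcome_type="continuous",
        outcome_class="not_applicable",
        trials=[
            _trial("p1", AgeGroup.PEDIATRIC, ContinuousControlArm(mean=1.0, sd=4.3, n=30)),
            _trial("a1", AgeGroup.ADULT, ContinuousControlArm(mean=2.0, sd=32.0, n=100)),
            _trial("a2", AgeGroup.ADULT, ContinuousControlArm(mean=1.5, sd=16.0, n=400)),
        ],
    )


@pytest.fixture
def small_corpus(binary_ma, continuous_ma):
    return Corpus(meta_analyses=[binary_ma, continuous_ma])
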