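"""Trial-corpus data model, CSV reader/writer, eligibility checks and age classification.

The atomic unit is one randomized trial's control arm together with an age-group
label. Trials sharing a topic/comparison/outcome form a meta-analysis; a
meta-analysis is eligible for the pediatric-vs-adult comparison only when it
contains at least one pediatric and at least one adult trial.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

CORPUS_COLUMNS = [
    "review_id",
    "ma_id",
    "outcome_type",
    "outcome_class",
    "trial_id",
    "age_group",
    "min_age",
    "max_age",
    "events",
    "n",
    "mean",
    "sd",
]


class CorpusValidationError(ValueError):
    """Raised when a corpus file violates the schema or a row-level invariant."""


class EligibilityError(ValueError):
    """Raised when an analysis is requested on an ineligible meta-analysis."""


class AgeGroup(str, enum.Enum):
    PEDIATRIC = "pediatric"
    ADULT = "adult"
    UNCLASSIFIED = "unclassified"


def classify_age_group(min_age: float, max_age: float) -> AgeGroup:
    """Classify a trial's population from its age range.

    A trial is *adult* when every participant is older than 12 years and
    participants older than 20 years were also enrolled; *pediatric* when every
    participant is younger than 20 years and participants younger than 12 years
    were also enrolled. The comparisons are strict, so boundary ages of exactly
    12 or 20 fail the corresponding rule. Ranges meeting neither rule (e.g.
    adolescent-only trials, or trials spanning both childhood and adulthood)
    are *unclassified*.
    """
    if min_age < 0 or max_age < 0:
        raise CorpusValidationError(f"ages must be non-negative, got ({min_age}, {max_age})")
    if min_age > max_age:
        raise CorpusValidationError(f"min_age {min_age} exceeds max_age {max_age}")
    if min_age > 12 and max_age > 20:
        return AgeGroup.ADULT
    if max_age < 20 and min_age < 12:
        return AgeGroup.PEDIATRIC
    return AgeGroup.UNCLASSIFIED


@dataclass(frozen=True)
class BinaryControlArm:
    """Control-arm event count for a binary outcome."""

    events: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CorpusValidationError(f"control-arm n must be >= 1, got {self.n}")
        if not 0 <= self.events <= self.n:
            raise CorpusValidationError(
                f"events must lie in [0, n]: events={self.events}, n={self.n}"
            )


@dataclass(frozen=True)
class ContinuousControlArm:
    """Control-arm summary statistics for a continuous outcome."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise CorpusValidationError(f"control-arm sd must be > 0, got {self.sd}")
        if self.n < 2:
            raise CorpusValidationError(f"control-arm n must be >= 2, got {self.n}")


Arm = Union[BinaryControlArm, ContinuousControlArm]


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    age_group: AgeGroup
    arm: Arm
    min_age: Optional[float] = None
    max_age: Optional[float] = None


@dataclass
class MetaAnalysis:
    """A cluster of trials pooled together in the source review.

    ``outcome_class`` distinguishes mortality from non-mortality endpoints for
    binary outcomes and is ``not_applicable`` for continuous outcomes.
    """

    ma_id: str
    review_id: str
    outcome_type: str  # "binary" | "continuous"
    outcome_class: str  # "mortality" | "non_mortality" | "not_applicable"
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome_type not in ("binary", "continuous"):
            raise CorpusValidationError(
                f"{self.ma_id}: outcome_type must be binary or continuous, got {self.outcome_type!r}"
            )
        if self.outcome_type == "continuous":
            if self.outcome_class != "not_applicable":
                raise CorpusValidationError(
                    f"{self.ma_id}: continuous meta-analyses carry outcome_class=not_applicable"
                )
        elif self.outcome_class not in ("mortality", "non_mortality"):
            raise CorpusValidationError(
                f"{self.ma_id}: binary outcome_class must be mortality or non_mortality"
            )
        expected = BinaryControlArm if self.outcome_type == "binary" else ContinuousControlArm
        for t in self.trials:
            if not isinstance(t.arm, expected):
                raise CorpusValidationError(
                    f"{self.ma_id}/{t.trial_id}: arm type does not match outcome_type "
                    f"{self.outcome_type!r}"
                )

    def trials_in(self, group: AgeGroup) -> list[TrialRecord]:
        return [t for t in self.trials if t.age_group is group]

    @property
    def k_pediatric(self) -> int:
        return len(self.trials_in(AgeGroup.PEDIATRIC))

    @property
    def k_adult(self) -> int:
        return len(self.trials_in(AgeGroup.ADULT))

    @property
    def eligible(self) -> bool:
        """At least one pediatric and one adult trial."""
        return self.k_pediatric >= 1 and self.k_adult >= 1


@dataclass
class Corpus:
    meta_analyses: list[MetaAnalysis] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.ma_id for m in self.meta_analyses]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate ma_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.meta_analyses)

    def __iter__(self):
        return iter(self.meta_analyses)

    def eligible(self, outcome_type: Optional[str] = None) -> list[MetaAnalysis]:
        """Eligible meta-analyses, optionally restricted to one outcome type.

        Ineligible meta-analyses are retained in the corpus for audit but
        excluded from synthesis; each exclusion is logged.
        """
        out = []
        for m in self.meta_analyses:
            if outcome_type is not None and m.outcome_type != outcome_type:
                continue
            if not m.eligible:
                logger.info(
                    "excluding ineligible meta-analysis %s (pediatric=%d, adult=%d)",
                    m.ma_id, m.k_pediatric, m.k_adult,
                )
                continue
            out.append(m)
        return out


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _row_age_group(row, rownum: int) -> tuple[AgeGroup, Optional[float], Optional[float]]:
    # An explicit label wins over the min/max-age classifier, mirroring the
    # precedence given to classifications reported in the source review.
    min_age = None if _is_blank(row["min_age"]) else float(row["min_age"])
    max_age = None if _is_blank(row["max_age"]) else float(row["max_age"])
    raw = row["age_group"]
    if not _is_blank(raw):
        label = str(raw).strip().lower()
        try:
            return AgeGroup(label), min_age, max_age
        except ValueError:
            raise CorpusValidationError(f"row {rownum}: unknown age_group {raw!r}") from None
    if min_age is None or max_age is None:
        raise CorpusValidationError(
            f"row {rownum}: neither age_group nor both min_age/max_age provided"
        )
    return classify_age_group(min_age, max_age), min_age, max_age


def _row_trial(row, outcome_type: str, rownum: int) -> TrialRecord:
    group, min_age, max_age = _row_age_group(row, rownum)
    if outcome_type == "binary":
        for col in ("events", "n"):
            if _is_blank(row[col]):
                raise CorpusValidationError(f"row {rownum}: binary row missing {col!r}")
        try:
            arm: Arm = BinaryControlArm(events=int(row["events"]), n=int(row["n"]))
        except CorpusValidationError as exc:
            raise CorpusValidationError(f"row {rownum}: {exc}") from None
    else:
        for col in ("mean", "sd", "n"):
            if _is_blank(row[col]):
                raise CorpusValidationError(f"row {rownum}: continuous row missing {col!r}")
        try:
            arm = ContinuousControlArm(
                mean=float(row["mean"]), sd=float(row["sd"]), n=int(row["n"])
            )
        except CorpusValidationError as exc:
            raise CorpusValidationError(f"row {rownum}: {exc}") from None
    return TrialRecord(
        trial_id=str(row["trial_id"]),
        age_group=group,
        arm=arm,
        min_age=min_age,
        max_age=max_age,
    )


def read_corpus(path: Union[str, Path]) -> Corpus:
    """Read a corpus from a comma-separated file (see ``CORPUS_COLUMNS``).

    Rows violating arm invariants raise :class:`CorpusValidationError` naming
    the offending row. Meta-analyses lacking a pediatric or an adult trial are
    kept but flagged ineligible (``MetaAnalysis.eligible``), never silently
    dropped.
    """
    table = pd.read_csv(
        path,
        dtype={"review_id": str, "ma_id": str, "trial_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in CORPUS_COLUMNS if c not in table.columns]
    if missing:
        raise CorpusValidationError(f"corpus file missing required columns: {missing}")

    metas: dict[str, MetaAnalysis] = {}
    for rownum, row in enumerate(table.to_dict("records"), start=2):  # header is line 1
        ma_id = str(row["ma_id"])
        outcome_type = str(row["outcome_type"]).strip().lower()
        if outcome_type not in ("binary", "continuous"):
            raise CorpusValidationError(f"row {rownum}: bad outcome_type {row['outcome_type']!r}")
        outcome_class = (
            "not_applicable"
            if outcome_type == "continuous"
            else str(row["outcome_class"]).strip().lower()
        )
        trial = _row_trial(row, outcome_type, rownum)
        if ma_id not in metas:
            metas[ma_id] = MetaAnalysis(
                ma_id=ma_id,
                review_id=str(row["review_id"]),
                outcome_type=outcome_type,
                outcome_class=outcome_class,
                trials=[],
            )
        meta = metas[ma_id]
        if meta.outcome_type != outcome_type or meta.outcome_class != outcome_class:
            raise CorpusValidationError(
                f"row {rownum}: meta-analysis {ma_id} mixes outcome types/classes"
            )
        meta.trials.append(trial)

    # Re-validate each assembled meta-analysis (arm-type coherence).
    corpus = Corpus(meta_analyses=[MetaAnalysis(**vars(m)) for m in metas.values()])
    for m in corpus:
        if not m.eligible:
            logger.warning(
                "meta-analysis %s is ineligible (pediatric=%d, adult=%d)",
                m.ma_id, m.k_pediatric, m.k_adult,
            )
    return corpus


def write_corpus(corpus: Corpus, path: Union[str, Path]) -> Path:
    """Write a corpus as CSV; inverse of :func:`read_corpus` to full precision."""
    rows = []
    for m in corpus:
        for t in m.trials:
            binary = isinstance(t.arm, BinaryControlArm)
            rows.append(
                {
                    "review_id": m.review_id,
                    "ma_id": m.ma_id,
                    "outcome_type": m.outcome_type,
                    "outcome_class": "" if m.outcome_class == "not_applicable" else m.outcome_class,
                    "trial_id": t.trial_id,
                    "age_group": t.age_group.value,
                    "min_age": "" if t.min_age is None else repr(float(t.min_age)),
                    "max_age": "" if t.max_age is None else repr(float(t.max_age)),
                    "events": t.arm.events if binary else "",
                    "n": t.arm.n,
                    "mean": "" if binary else repr(float(t.arm.mean)),
                    "sd": "" if binary else repr(float(t.arm.sd)),
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=CORPUS_COLUMNS).to_csv(path, index=False)
    if not rows:  # header-only file for an empty corpus
        path.write_text(",".join(CORPUS_COLUMNS) + "\n")
    return path
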