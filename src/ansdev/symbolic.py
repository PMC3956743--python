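"""Symbolic number knowledge: give-a-number scoring, knower levels, counting list.

The give-a-number task asks a child for x objects, x in {1..5} (3-year-olds)
plus 7 (4-year-olds), three trials per requested numerosity (15 or 18 trials).
A child is an N-knower for the largest N such that every requested numerosity
m <= N was produced correctly on at least 2 of its 3 trials; failing already
at m = 1 makes a pre-knower, and passing the highest tested numerosity makes
a cardinal-principle knower (a seven-knower when 7 was tested, a five-knower
otherwise).  The counting-list score is the length of the longest correct
count sequence 1, 2, 3, ... (capped at 60); the symbolic battery enters the
analyses only as a bounded 0-63 aggregate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import MalformedDesignError

__all__ = [
    "KnowerLevel",
    "GiveANumberResponse",
    "SymbolicScores",
    "score_give_a_number",
    "classify_knower_level",
    "score_counting_list",
    "knower_level_table",
    "COUNTING_LIST_CAP",
    "BATTERY_MAX",
]

COUNTING_LIST_CAP = 60
BATTERY_MAX = 63
TRIALS_PER_NUMEROSITY = 3
#: Requested numerosities by design: 5 targets for younger children, 6 for
#: older ones (the extra 7-target probes the cardinal principle).
DESIGNS: tuple[tuple[int, ...], ...] = ((1, 2, 3, 4, 5), (1, 2, 3, 4, 5, 7))


class KnowerLevel(enum.IntEnum):
    """Ordinal knower level; the value is the highest exactly-known numeral."""

    PRE = 0
    ONE = 1
    TWO = 2
    THREE = 3
    FOUR = 4
    FIVE = 5
    SEVEN = 7

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class GiveANumberResponse:
    """One give-a-number trial: the request, the set produced, the animal set."""

    requested: int
    produced: int
    set_index: int

    def __post_init__(self) -> None:
        if self.requested not in (1, 2, 3, 4, 5, 7):
            raise ValueError("requested numerosity must be in {1,2,3,4,5,7}")
        if self.produced < 0:
            raise ValueError("produced numerosity must be non-negative")

    @property
    def correct(self) -> bool:
        return self.produced == self.requested


@dataclass(frozen=True)
class SymbolicScores:
    """The three symbolic measures carried by one child at one time point."""

    give_a_number_score: int
    counting_list_max: int
    battery_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.battery_score <= BATTERY_MAX:
            raise ValueError(f"battery score must lie in [0, {BATTERY_MAX}]")
        if not 0 <= self.counting_list_max <= COUNTING_LIST_CAP:
            raise ValueError(f"counting list max must lie in [0, {COUNTING_LIST_CAP}]")


def _grouped(responses: Iterable[GiveANumberResponse]) -> dict[int, list[GiveANumberResponse]]:
    groups: dict[int, list[GiveANumberResponse]] = {}
    for r in responses:
        groups.setdefault(r.requested, []).append(r)
    tested = tuple(sorted(groups))
    if tested not in DESIGNS:
        raise MalformedDesignError(f"requested numerosities {tested} match no design")
    for m, rs in groups.items():
        if len(rs) != TRIALS_PER_NUMEROSITY:
            raise MalformedDesignError(
                f"numerosity {m} has {len(rs)} trials, expected {TRIALS_PER_NUMEROSITY}"
            )
    return groups


def score_give_a_number(responses: Sequence[GiveANumberResponse]) -> int:
    """Number of trials on which the produced set matched the request (of 15/18)."""
    groups = _grouped(responses)
    return sum(r.correct for rs in groups.values() for r in rs)


def classify_knower_level(responses: Sequence[GiveANumberResponse]) -> KnowerLevel:
    """Apply the 2-of-3 criterion per requested numerosity, cumulatively.

    The level is the largest tested N whose every tested predecessor
    (including N itself) was passed; passing the full tested range yields the
    cardinal-principle level for that design.
    """
    groups = _grouped(responses)
    tested = sorted(groups)
    passed_up_to = 0
    for m in tested:
        n_correct = sum(r.correct for r in groups[m])
        if n_correct >= 2:
            passed_up_to = m
        else:
            break
    return KnowerLevel(passed_up_to)


def score_counting_list(sequence: Sequence[int]) -> int:
    """Highest number reached by the correct prefix 1, 2, 3, ... of ``sequence``."""
    count = 0
    for expected, produced in enumerate(sequence, start=1):
        if produced != expected or expected > COUNTING_LIST_CAP:
            break
        count = expected
    return count


def knower_level_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of knower levels by age group and time point.

    ``cohort`` is long-form with columns ``age_group``, ``time_point`` and
    ``knower_level`` (KnowerLevel values or their integer codes).  Rows are
    levels in ordinal order; columns are (age_group, time_point) pairs.
    """
    levels = [KnowerLevel(v) for v in sorted(KnowerLevel)]
    index = pd.Index([str(l) for l in levels], name="knower_level")
    if cohort.empty:
        return pd.DataFrame(index=index)
    df = cohort.copy()
    df["knower_level"] = [str(KnowerLevel(int(v))) for v in df["knower_level"]]
    table = (
        df.groupby(["age_group", "time_point", "knower_level"])
        .size()
        .unstack(["age_group", "time_point"])
        .reindex(index)
        .fillna(0)
        .astype(int)
    )
    return table.sort_index(axis=1)
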