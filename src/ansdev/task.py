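"""Adaptive staircase numerosity-comparison task, simulated from a latent w.

A responder with Weber fraction ``w`` compares two numerosities n1 < n2 under
the linear-Weber model of the approximate number system: the internal
difference signal is Gaussian with mean n2 - n1 and standard deviation
w * sqrt(n1**2 + n2**2), so

    P(correct) = (1 - lapse) * Phi((n2 - n1) / (w * sqrt(n1**2 + n2**2))) + lapse / 2.

The task schedule is an increasing staircase: a 4-trial practice block at the
easiest ratio (unscored), three unconditional 8-trial test blocks at ratios
1:2, 2:3, 3:4, then one 8-trial block per finer ratio (4:5 ... 7:8) for as
long as no block has yet fallen below 6/8 correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd, sqrt

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import InsufficientDataError
from .stimuli import RATIO_ORDER, StimulusPair, build_pair_table

__all__ = [
    "PsychometricModel",
    "BlockResult",
    "StaircaseOutcome",
    "p_correct",
    "run_block",
    "run_staircase",
    "classify_above_chance",
    "flag_below_chance",
    "trials_frame",
]

#: Blocks always administered, regardless of performance.
UNCONDITIONAL_RATIOS: tuple[str, ...] = RATIO_ORDER[:3]
#: chi-square(1) critical value at alpha = .05; for 8-trial blocks this makes
#: "above chance" exactly >= 7 of 8 correct (statistic 4.5).
CHI2_CRIT_05 = 3.841
#: Stop criterion: a block below this count of correct responses (i.e. < 75%)
#: ends the staircase.
STOP_CRITERION = 6
TRIALS_PER_BLOCK = 8
PRACTICE_TRIALS = 4


@dataclass(frozen=True)
class PsychometricModel:
    """Latent responder: Weber fraction ``w`` plus an optional lapse rate."""

    w: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("Weber fraction w must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")


@dataclass(frozen=True)
class BlockResult:
    """Trial counts for one ratio block."""

    ratio_label: str
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")

    @property
    def proportion_correct(self) -> float:
        return self.n_correct / self.n_trials


@dataclass
class StaircaseOutcome:
    """Child-level record of one staircase run (practice excluded from scoring)."""

    blocks: list[BlockResult]
    practice: BlockResult
    overall_accuracy: float
    highest_above_chance_ratio: str | None
    below_chance_flag: bool
    trials: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    # (ratio_label, trial_index, n_small, n_large, correct) when recorded


def p_correct(n_small: int, n_large: int, model: PsychometricModel) -> float:
    """Probability of choosing the larger of two numerosities.

    Depends on the numerosities only through their ratio (the scaled
    difference (n2 - n1)/sqrt(n1**2 + n2**2) is invariant under common
    scaling), which licenses pooling the two same-ratio pairs of a block.
    """
    if n_small > n_large:
        raise ValueError("n_small must not exceed n_large")
    # Reduce by the gcd so same-ratio pairs are bit-identical, not merely
    # equal up to rounding of the common factor.
    g = gcd(int(n_small), int(n_large)) or 1
    a, b = n_small / g, n_large / g
    z = (b - a) / (model.w * sqrt(a**2 + b**2))
    return (1.0 - model.lapse) * float(ndtr(z)) + model.lapse / 2.0


def run_block(
    pairs: list[StimulusPair],
    model: PsychometricModel,
    rng: np.random.Generator,
    record_trials: bool = False,
) -> BlockResult | tuple[BlockResult, list[tuple[str, int, int, int, int]]]:
    """Simulate one 8-trial block: 4 trials per set-size variant of one ratio.

    Side/order counterbalancing is non-informative for a stationary responder
    and is absorbed into the Bernoulli draw.
    """
    if len(pairs) != 2 or pairs[0].ratio_label != pairs[1].ratio_label:
        raise ValueError("a block needs the two set-size variants of one ratio")
    ratio = pairs[0].ratio_label
    trials: list[tuple[str, int, int, int, int]] = []
    n_correct = 0
    for variant_idx, pair in enumerate(pairs):
        p = p_correct(pair.n_small, pair.n_large, model)
        correct = rng.random(TRIALS_PER_BLOCK // 2) < p
        n_correct += int(correct.sum())
        if record_trials:
            for i, c in enumerate(correct):
                trials.append(
                    (ratio, variant_idx * 4 + i, pair.n_small, pair.n_large, int(c))
                )
    block = BlockResult(ratio_label=ratio, n_trials=TRIALS_PER_BLOCK, n_correct=n_correct)
    if record_trials:
        return block, trials
    return block


def classify_above_chance(block: BlockResult) -> bool:
    """Above-chance discrimination by a chi-square test against 50% (alpha=.05).

    For 8-trial blocks the criterion is exactly 7 or 8 correct (statistic 4.5
    at 7/8, versus the 3.841 critical value).
    """
    from .stats import chi_square_vs_chance

    stat = chi_square_vs_chance(block.n_correct, block.n_trials)
    return stat >= CHI2_CRIT_05 and block.proportion_correct > 0.5


def run_staircase(
    model: PsychometricModel,
    rng: np.random.Generator,
    pair_table: list[StimulusPair] | None = None,
    record_trials: bool = False,
) -> StaircaseOutcome:
    """Simulate a full staircase session for one responder.

    The three easiest ratio blocks are always run.  Finer-ratio blocks are
    then added in canonical order while no block so far (including the
    unconditional ones) has fallen below 6/8 correct; the first failed block
    in the conditional phase is included and ends the run.
    """
    table = build_pair_table() if pair_table is None else pair_table
    by_ratio = {
        ratio: [p for p in table if p.ratio_label == ratio] for ratio in RATIO_ORDER
    }

    # Practice: 4 trials at 1:2, alternating the two set-size variants.
    practice_pairs = by_ratio["1:2"]
    practice_correct = 0
    for i in range(PRACTICE_TRIALS):
        pair = practice_pairs[i % 2]
        practice_correct += int(rng.random() < p_correct(pair.n_small, pair.n_large, model))
    practice = BlockResult("1:2", PRACTICE_TRIALS, practice_correct)

    blocks: list[BlockResult] = []
    all_trials: list[tuple[str, int, int, int, int]] = []
    failed = False
    for ratio in RATIO_ORDER:
        unconditional = ratio in UNCONDITIONAL_RATIOS
        if not unconditional and failed:
            break
        result = run_block(by_ratio[ratio], model, rng, record_trials=record_trials)
        if record_trials:
            block, trials = result  # type: ignore[misc]
            all_trials.extend(trials)
        else:
            block = result  # type: ignore[assignment]
        blocks.append(block)
        if block.n_correct < STOP_CRITERION:
            failed = True

    total_trials = sum(b.n_trials for b in blocks)
    total_correct = sum(b.n_correct for b in blocks)
    above = [b.ratio_label for b in blocks if classify_above_chance(b)]
    highest = max(above, key=RATIO_ORDER.index) if above else None
    outcome = StaircaseOutcome(
        blocks=blocks,
        practice=practice,
        overall_accuracy=total_correct / total_trials,
        highest_above_chance_ratio=highest,
        below_chance_flag=False,
        trials=all_trials,
    )
    outcome.below_chance_flag = flag_below_chance(outcome)
    return outcome


def flag_below_chance(outcome: StaircaseOutcome) -> bool:
    """Strictly-below-50% accuracy on the 24 unconditional trials."""
    if len(outcome.blocks) < len(UNCONDITIONAL_RATIOS):
        raise InsufficientDataError("outcome lacks the three unconditional blocks")
    first = outcome.blocks[: len(UNCONDITIONAL_RATIOS)]
    n = sum(b.n_trials for b in first)
    k = sum(b.n_correct for b in first)
    return k / n < 0.5


def trials_frame(child_id, session: int, outcome: StaircaseOutcome) -> pd.DataFrame:
    """Tidy trial-level table (requires ``record_trials=True`` at simulation)."""
    rows = [
        {
            "child_id": child_id,
            "session": session,
            "block_ratio": ratio,
            "trial_index": idx,
            "n_small": ns,
            "n_large": nl,
            "correct": c,
        }
        for ratio, idx, ns, nl, c in outcome.trials
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "session",
            "block_ratio",
            "trial_index",
            "n_small",
            "n_large",
            "correct",
        ],
    )
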