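"""Task structure for the dyadic facial-expression avoidance-learning experiment.

Two target interactants present smile/frown video clips.  One interactant
carries a *copy* rule (respond with the same expression to avoid shock), the
other an *oppose* rule; the rules swap between the two blocks (reversal).
This module defines the expression alphabet, the contingency map, trial
schedules with the randomization constraint (no clip more than
``max_consecutive`` times in a row), and the reinforcement function.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Expression",
    "ActionRule",
    "ContingencyMap",
    "Trial",
    "TrialSchedule",
    "ScheduleError",
    "correct_response",
    "generate_schedule",
    "reinforcement",
    "schedule_to_frame",
]

N_TRIALS = 96
N_BLOCKS = 2
INTERACTANTS = (1, 2)


class Expression(str, enum.Enum):
    """Facial expression alphabet (stimuli and responses share it)."""

    SMILE = "smile"
    FROWN = "frown"

    @property
    def opposite(self) -> "Expression":
        return Expression.FROWN if self is Expression.SMILE else Expression.SMILE


class ActionRule(str, enum.Enum):
    COPY = "copy"
    OPPOSE = "oppose"


@dataclass(frozen=True)
class ContingencyMap:
    """Mapping (interactant, block) -> action rule.

    ``copy_interactant_block1`` names the interactant whose block-1 rule is
    *copy*; the other interactant gets *oppose*, and block 2 swaps both.
    """

    copy_interactant_block1: int = 1

    def __post_init__(self) -> None:
        if self.copy_interactant_block1 not in INTERACTANTS:
            raise ValueError(f"unknown interactant: {self.copy_interactant_block1}")

    def rule(self, interactant: int, block: int) -> ActionRule:
        if interactant not in INTERACTANTS:
            raise ValueError(f"unknown interactant: {interactant}")
        if block not in (1, 2):
            raise ValueError(f"unknown block: {block}")
        copy_in_block1 = interactant == self.copy_interactant_block1
        # reversal: block-2 rules are block-1 rules swapped
        if block == 2:
            copy_in_block1 = not copy_in_block1
        return ActionRule.COPY if copy_in_block1 else ActionRule.OPPOSE


def correct_response(
    interactant: int,
    target_expression: Expression,
    block: int,
    contingencies: ContingencyMap,
) -> Expression:
    """Expression the participant must form to avoid shock on this trial."""
    rule = contingencies.rule(interactant, block)
    if rule is ActionRule.COPY:
        return target_expression
    return target_expression.opposite


@dataclass(frozen=True)
class Trial:
    participant_id: str
    index: int  # 1-based, 1..96
    block: int
    interactant: int
    target_expression: Expression
    condition: str  # "congruent" | "incongruent"
    correct_response: Expression

    def __post_init__(self) -> None:
        if self.block not in (1, 2):
            raise ValueError(f"unknown block: {self.block}")
        if self.index < 1:
            raise ValueError("trial index is 1-based")


@dataclass
class TrialSchedule:
    trials: list[Trial]
    seed: int
    contingencies: ContingencyMap = field(default_factory=ContingencyMap)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


class ScheduleError(RuntimeError):
    """Raised when the randomization constraint cannot be satisfied."""


def _sample_clip_order(
    rng: np.random.Generator,
    counts: np.ndarray,
    max_consecutive: int,
    prefix_tail: list[int],
    max_restarts: int = 1000,
) -> list[int]:
    """Sequential draw from remaining clip counts with run-length constraint.

    Backtracks by restarting the block when a dead end is reached (with 4
    clips and max_consecutive >= 2 dead ends are rare).  ``prefix_tail`` is
    the tail of the previous block so the constraint also holds across the
    block boundary.
    """
    n_clips = len(counts)
    for _ in range(max_restarts):
        remaining = counts.copy()
        order: list[int] = []
        ok = True
        while remaining.sum() > 0:
            tail = (prefix_tail + order)[-max_consecutive:]
            run_clip = tail[-1] if tail else -1
            run_len = 0
            for c in reversed(tail):
                if c == run_clip:
                    run_len += 1
                else:
                    break
            allowed = [
                k
                for k in range(n_clips)
                if remaining[k] > 0 and not (k == run_clip and run_len >= max_consecutive)
            ]
            if not allowed:
                ok = False
                break
            weights = remaining[allowed] / remaining[allowed].sum()
            order.append(int(rng.choice(allowed, p=weights)))
            remaining[order[-1]] -= 1
        if ok:
            return order
    raise ScheduleError(
        f"could not satisfy run-length constraint after {max_restarts} restarts"
    )


def generate_schedule(
    seed: int,
    reps_per_clip: int = 12,
    max_consecutive: int = 2,
    participant_id: str = "p01",
    contingencies: ContingencyMap | None = None,
) -> TrialSchedule:
    """Generate a randomized two-block schedule.

    Each of the 4 clips (interactant x expression) occurs exactly
    ``reps_per_clip`` times per block and no clip appears more than
    ``max_consecutive`` times consecutively (also across the block boundary).
    Deterministic given ``seed``.
    """
    if reps_per_clip < 1:
        raise ValueError("reps_per_clip must be >= 1")
    if max_consecutive < 1:
        raise ValueError("max_consecutive must be >= 1")
    if contingencies is None:
        contingencies = ContingencyMap()
    rng = np.random.default_rng(seed)
    # clip id k in 0..3 -> (interactant, expression)
    clips = [(i, e) for i in INTERACTANTS for e in (Expression.SMILE, Expression.FROWN)]

    trials: list[Trial] = []
    tail: list[int] = []
    index = 1
    for block in (1, 2):
        counts = np.full(len(clips), reps_per_clip)
        order = _sample_clip_order(rng, counts, max_consecutive, tail)
        tail = order[-max_consecutive:]
        for k in order:
            interactant, expr = clips[k]
            rule = contingencies.rule(interactant, block)
            cr = correct_response(interactant, expr, block, contingencies)
            trials.append(
                Trial(
                    participant_id=participant_id,
                    index=index,
                    block=block,
                    interactant=interactant,
                    target_expression=expr,
                    condition="congruent" if rule is ActionRule.COPY else "incongruent",
                    correct_response=cr,
                )
            )
            index += 1
    return TrialSchedule(trials=trials, seed=seed, contingencies=contingencies)


def reinforcement(response: Expression | None, trial: Trial) -> int:
    """+1 (no shock) iff the response equals the correct response, else -1.

    A missing response (no detectable expression) is punished.
    """
    if response is not None and response == trial.correct_response:
        return 1
    return -1


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """Tidy one-row-per-trial frame (the package's CSV schema)."""
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in schedule],
            "trial_index": [t.index for t in schedule],
            "block": [t.block for t in schedule],
            "interactant": [t.interactant for t in schedule],
            "target_expression": [t.target_expression.value for t in schedule],
            "condition": [t.condition for t in schedule],
            "correct_response": [t.correct_response.value for t in schedule],
        }
    )
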