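"""Modified rapid ascending 3-AFC staircase engine.

Each trial presents a triad (one target, two controls); the assessor picks
the odd sample.  The run starts at the second-lowest ladder level.  Before
the first reversal an incorrect answer raises the level by two steps (rapid
ascent); after it, incorrect answers raise by one step and correct answers
lower by one step, producing the familiar 1-up/1-down oscillation.  The run
stops once at least ``min_reversals`` direction changes have occurred and the
same level has been answered correctly on its last ``stop_correct_at_level``
visits ("repeatedly selected the correct sample at one concentration").
Runs pinned against the top or bottom of the ladder, and runs exceeding
``max_trials``, terminate with an explicit censoring-relevant reason.

The engine is purely deterministic given the response sequence; randomness
lives in the observer callable (see :mod:`fattaste.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .concentrations import DilutionSeries

__all__ = [
    "StaircaseConfig",
    "TrialRecord",
    "TrialLog",
    "StaircaseError",
    "next_level",
    "count_reversals",
    "run_staircase",
]


class StaircaseError(RuntimeError):
    """Raised when a staircase run cannot proceed (e.g. observer failure).

    Carries the partial trial log, flagged invalid, in ``partial_log``.
    """

    def __init__(self, message: str, partial_log: "TrialLog | None" = None):
        super().__init__(message)
        self.partial_log = partial_log


@dataclass(frozen=True)
class StaircaseConfig:
    """Tunable parameters of the staircase.

    Defaults encode the study procedure: start at the second-lowest level,
    ascend two levels per miss, descend one level per correct answer, and
    stop after at least four reversals once one level has been answered
    correctly on three successive visits.

    The two-level up-step is kept after the first reversal as well: an
    up-2/down-1 rule equilibrates where P(correct) = 2/3 — exactly the
    midpoint of a 3-AFC psychometric function — and makes a guessing
    assessor (P = 1/3) drift upward one level per trial on average instead
    of lingering near the ladder bottom.  A 1-up/1-down variant
    (``post_reversal_up=1``), which equilibrates at P(correct) = 1/2, is
    available but hovers only marginally above the 1/3 guessing rate and is
    far more prone to chance-driven stops at low concentrations.

    ``stop_correct_at_level=3`` quantifies "repeatedly selected the correct
    sample at one concentration": with a 1-in-3 guessing rate, two correct
    answers at one level occur by chance with probability 1/9 — too weak to
    ever register as a significant true positive — whereas three (1/27)
    clear the default exact-binomial criterion at alpha = 0.05, so a run
    cannot stop before its terminal level is able to anchor the threshold.
    """

    start_index: int = 1
    pre_reversal_up: int = 2
    post_reversal_up: int = 2
    down_step: int = 1
    min_reversals: int = 4
    stop_correct_at_level: int = 3
    max_trials: int = 60
    boundary_patience: int = 3  # consecutive clamped trials before censoring

    def __post_init__(self) -> None:
        if min(self.pre_reversal_up, self.post_reversal_up, self.down_step) < 1:
            raise ValueError("all step sizes must be >= 1")
        if self.min_reversals < 1:
            raise ValueError("min_reversals must be >= 1")
        if self.max_trials < self.min_reversals:
            raise ValueError("max_trials must be >= min_reversals")
        if self.stop_correct_at_level < 1:
            raise ValueError("stop_correct_at_level must be >= 1")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    level_index: int
    correct: bool


@dataclass
class TrialLog:
    """One participant's staircase run.

    ``terminated_by`` is one of ``criterion``, ``ceiling``, ``floor``,
    ``max_trials`` (or ``None`` for logs read back from disk without
    termination metadata).
    """

    participant_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    reversals: int = 0
    terminated_by: str | None = None

    @property
    def levels(self) -> list[int]:
        return [t.level_index for t in self.trials]

    @property
    def responses(self) -> list[bool]:
        return [t.correct for t in self.trials]


def next_level(
    current: int,
    last_correct: bool,
    reversals_so_far: int,
    config: StaircaseConfig,
    n_levels: int,
) -> int:
    """Level for the next trial, clamped to the ladder.

    Incorrect answers ascend (by ``pre_reversal_up`` before the first
    reversal, ``post_reversal_up`` after); correct answers descend by
    ``down_step``.  Overflow past either end is absorbed by clamping; callers
    that need to detect clamping compare against the unclamped move.
    """
    if not 0 <= current < n_levels:
        raise ValueError(f"current level {current} outside ladder [0, {n_levels - 1}]")
    if last_correct:
        raw = current - config.down_step
    elif reversals_so_far == 0:
        raw = current + config.pre_reversal_up
    else:
        raw = current + config.post_reversal_up
    return min(max(raw, 0), n_levels - 1)


def count_reversals(responses: Sequence[bool]) -> int:
    """Number of direction changes implied by a correct/incorrect sequence.

    A correct answer moves the staircase down, an incorrect one up, so every
    transition between correct and incorrect is a reversal.  Counting on the
    response sequence (the intended direction) keeps the tally well defined
    even when the realised trajectory is flattened by boundary clamping.
    """
    return sum(1 for a, b in zip(responses, responses[1:]) if a != b)


def run_staircase(
    observer: Callable[[int], bool],
    config: StaircaseConfig,
    series: DilutionSeries,
    participant_id: str = "obs",
) -> TrialLog:
    """Run the staircase against a response oracle.

    ``observer`` maps a 0-based level index to a correct/incorrect answer.
    Returns the complete :class:`TrialLog` with ``terminated_by`` set.
    """
    n = series.n_levels
    if not 0 <= config.start_index < n:
        raise ValueError("start_index outside the ladder")
    log = TrialLog(participant_id=participant_id)
    level = config.start_index
    # per-level history of responses, for the repeated-correct stop rule
    visits: dict[int, list[bool]] = {}
    clamp_top = 0
    clamp_bottom = 0
    while True:
        trial_index = len(log.trials)
        try:
            correct = bool(observer(level))
        except Exception as exc:  # pragma: no cover - observer contract breach
            log.terminated_by = "invalid"
            raise StaircaseError(
                f"observer failed at level {level}: {exc}", partial_log=log
            ) from exc
        log.trials.append(TrialRecord(trial_index, level, correct))
        visits.setdefault(level, []).append(correct)
        log.reversals = count_reversals(log.responses)

        # stop rule: enough reversals and the current level repeatedly correct
        hist = visits[level]
        if (
            log.reversals >= config.min_reversals
            and len(hist) >= config.stop_correct_at_level
            and all(hist[-config.stop_correct_at_level :])
        ):
            log.terminated_by = "criterion"
            return log
        if len(log.trials) >= config.max_trials:
            log.terminated_by = "max_trials"
            return log

        # compute the move, tracking boundary clamps for censoring
        if correct:
            raw = level - config.down_step
        elif log.reversals == 0:
            raw = level + config.pre_reversal_up
        else:
            raw = level + config.post_reversal_up
        nxt = min(max(raw, 0), n - 1)
        if raw > n - 1:
            clamp_top += 1
            clamp_bottom = 0
        elif raw < 0:
            clamp_bottom += 1
            clamp_top = 0
        else:
            clamp_top = clamp_bottom = 0
        if clamp_top >= config.boundary_patience:
            log.terminated_by = "ceiling"
            return log
        if clamp_bottom >= config.boundary_patience:
            log.terminated_by = "floor"
            return log
        level = nxt
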