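"""2AFC tone-discrimination protocols and the 3-down-1-up adaptive staircase.

Each trial presents two tones and the observer reports which was higher in
frequency.  In the reference-containing protocols one tone is a constant
1000 Hz reference and the other (the comparison) is offset from it by a
percentage controlled by a transformed up-down staircase: the difference
shrinks after three consecutive correct responses and grows after every
error, so the track converges where p_correct**3 = 0.5, i.e. at
100 * 0.5**(1/3) ~= 79.4 % correct.

Frequencies are stored internally as natural logs; Hz appears only at the
generation and I/O boundaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Protocol",
    "RefPosition",
    "Direction",
    "ProtocolSpec",
    "StaircaseState",
    "Trial",
    "Block",
    "DEFAULT_STEP_SCHEDULE",
    "DEFAULT_INITIAL_DIFF_PERCENT",
    "MIN_DIFF_PERCENT",
    "REVERSALS_PER_STEP",
    "STAIRCASE_TARGET_PC",
    "init_staircase",
    "update_staircase",
    "make_trial",
    "jnd_from_block",
]


class Protocol(enum.Enum):
    """Stimulus-arrangement rules for one experiment."""

    REFERENCE_LOWER = "reference-lower"
    REFERENCE = "reference"
    NO_REFERENCE = "no-reference"
    REFERENCE_FIRST = "reference-first"
    REFERENCE_HIGHER = "reference-higher"


class RefPosition(enum.Enum):
    FIRST = "first"
    SECOND = "second"
    NONE = "none"


class Direction(enum.Enum):
    DOWN = "down"
    UP = "up"
    NONE = "none"


#: Step sizes in % frequency difference; the track advances to the next
#: entry after every four reversals and stays on the last one.
DEFAULT_STEP_SCHEDULE: tuple[float, ...] = (4.5, 2.0, 1.0, 0.5, 0.1)
DEFAULT_INITIAL_DIFF_PERCENT = 20.0
#: Floor on the tracked difference; the smallest schedule step.
MIN_DIFF_PERCENT = 0.1
#: Ceiling on the tracked difference.  Keeps every protocol's stimuli
#: positive (a comparison below the reference needs diff < 100 %) while
#: sitting far above the 20 % start, so it never binds for an observer
#: performing above chance.
MAX_DIFF_PERCENT = 80.0
REVERSALS_PER_STEP = 4
#: Convergence point of a 3-down-1-up track, 100 * 0.5**(1/3).
STAIRCASE_TARGET_PC = 100.0 * 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """Protocol identity plus the physical constants of the experiment."""

    name: Protocol
    reference_hz: float = 1000.0
    block_length: int = 80
    no_reference_range_hz: tuple[float, float] = (800.0, 1200.0)

    def __post_init__(self) -> None:
        if self.reference_hz <= 0:
            raise ValueError("reference_hz must be positive")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        low, high = self.no_reference_range_hz
        if not low < high:
            raise ValueError("no_reference_range_hz must satisfy low < high")


@dataclass(frozen=True)
class StaircaseState:
    """Current position of a 3-down-1-up track.

    ``step_index`` points into ``step_schedule``; it advances after every
    ``REVERSALS_PER_STEP``-th reversal, taking effect on the following
    movement, and stays on the last entry thereafter.
    """

    diff_percent: float
    step_schedule: tuple[float, ...]
    step_index: int = 0
    n_reversals: int = 0
    consecutive_correct: int = 0
    last_direction: Direction = Direction.NONE
    min_diff_percent: float = MIN_DIFF_PERCENT
    max_diff_percent: float = MAX_DIFF_PERCENT

    @property
    def step_percent(self) -> float:
        return self.step_schedule[self.step_index]


@dataclass(frozen=True)
class Trial:
    """One two-tone presentation.

    ``x1`` and ``x2`` are natural logs of the tone frequencies.
    ``diff_percent`` records the staircase difference that generated the
    trial (needed to express no-reference trials in % of their own base
    tone); it is ``None`` for trials reconstructed from external tables
    where it can be recomputed from the stimuli.
    """

    index: int
    x1: float
    x2: float
    ref_position: RefPosition
    response_first_higher: Optional[bool] = None
    correct: Optional[bool] = None
    diff_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x1) and math.isfinite(self.x2)):
            raise ValueError("log-frequencies must be finite")
        if self.response_first_higher is not None and self.correct is not None:
            expected = self.response_first_higher == (self.x1 > self.x2)
            if self.correct != expected:
                raise ValueError(
                    "correct flag inconsistent with response and stimuli"
                )

    @property
    def f1_hz(self) -> float:
        return math.exp(self.x1)

    @property
    def f2_hz(self) -> float:
        return math.exp(self.x2)

    @property
    def first_higher(self) -> bool:
        return self.x1 > self.x2

    def with_response(self, response_first_higher: bool) -> "Trial":
        return replace(
            self,
            response_first_higher=bool(response_first_higher),
            correct=bool(response_first_higher) == (self.x1 > self.x2),
        )


@dataclass
class Block:
    """An ordered 80-trial (by default) run under a single protocol."""

    protocol: ProtocolSpec
    trials: list[Trial] = field(default_factory=list)
    participant_id: object = None
    block_id: object = None
    seed: object = None

    def __len__(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        if len(self.trials) != self.protocol.block_length:
            raise ValueError(
                f"block has {len(self.trials)} trials, protocol expects "
                f"{self.protocol.block_length}"
            )
        for i, t in enumerate(self.trials, start=1):
            if t.index != i:
                raise ValueError(f"trial indices must run 1..N; got {t.index} at {i}")


def init_staircase(
    initial_diff_percent: float = DEFAULT_INITIAL_DIFF_PERCENT,
    step_schedule: Sequence[float] = DEFAULT_STEP_SCHEDULE,
    min_diff_percent: float = MIN_DIFF_PERCENT,
    max_diff_percent: float = MAX_DIFF_PERCENT,
) -> StaircaseState:
    """Start a 3-down-1-up track at ``initial_diff_percent``.

    The schedule must be non-empty and strictly decreasing.
    """
    schedule = tuple(float(s) for s in step_schedule)
    if initial_diff_percent <= 0:
        raise ValueError("initial_diff_percent must be positive")
    if not schedule:
        raise ValueError("step_schedule must be non-empty")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("step_schedule must be strictly decreasing")
    if min_diff_percent <= 0:
        raise ValueError("min_diff_percent must be positive")
    if max_diff_percent < initial_diff_percent:
        raise ValueError("max_diff_percent must not be below the start value")
    return StaircaseState(
        diff_percent=float(initial_diff_percent),
        step_schedule=schedule,
        min_diff_percent=float(min_diff_percent),
        max_diff_percent=float(max_diff_percent),
    )


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the track after one response.

    Three consecutive correct responses move the difference DOWN by one
    step; every error moves it UP by one step and resets the run counter.
    A reversal is a change in movement direction (the first movement sets
    the direction without counting); after every fourth reversal the step
    size advances to the next schedule entry, effective from the next
    movement.  The difference is clipped to
    [state.min_diff_percent, state.max_diff_percent].
    """
    if correct:
        run = state.consecutive_correct + 1
        if run < 3:
            return replace(state, consecutive_correct=run)
        move = Direction.DOWN
        new_diff = max(state.diff_percent - state.step_percent, state.min_diff_percent)
    else:
        move = Direction.UP
        new_diff = min(
            state.diff_percent + state.step_percent, state.max_diff_percent
        )

    n_rev = state.n_reversals
    if state.last_direction is not Direction.NONE and move is not state.last_direction:
        n_rev += 1
    step_index = min(n_rev // REVERSALS_PER_STEP, len(state.step_schedule) - 1)
    return replace(
        state,
        diff_percent=new_diff,
        consecutive_correct=0,
        last_direction=move,
        n_reversals=n_rev,
        step_index=step_index,
    )


def make_trial(
    protocol: ProtocolSpec,
    diff_percent: float,
    rng: np.random.Generator,
    index: int = 1,
) -> Trial:
    """Draw one trial's stimuli at the given % frequency difference.

    Coin order is fixed (reference/base position first, then the
    higher-or-lower coin, then the uniform base draw where applicable) so
    a seeded generator reproduces stimuli exactly.
    """
    if diff_percent <= 0:
        raise ValueError("diff_percent must be positive")
    ref = protocol.reference_hz
    d = diff_percent / 100.0
    name = protocol.name

    if name is Protocol.REFERENCE_LOWER:
        ref_first = rng.random() < 0.5
        non_ref = ref * (1.0 + d)
        f1, f2 = (ref, non_ref) if ref_first else (non_ref, ref)
        pos = RefPosition.FIRST if ref_first else RefPosition.SECOND
    elif name is Protocol.REFERENCE:
        ref_first = rng.random() < 0.5
        non_ref_higher = rng.random() < 0.5
        non_ref = ref * (1.0 + d) if non_ref_higher else ref * (1.0 - d)
        f1, f2 = (ref, non_ref) if ref_first else (non_ref, ref)
        pos = RefPosition.FIRST if ref_first else RefPosition.SECOND
    elif name is Protocol.REFERENCE_FIRST:
        non_ref_higher = rng.random() < 0.5
        non_ref = ref * (1.0 + d) if non_ref_higher else ref * (1.0 - d)
        f1, f2 = ref, non_ref
        pos = RefPosition.FIRST
    elif name is Protocol.REFERENCE_HIGHER:
        ref_first = rng.random() < 0.5
        non_ref = ref * (1.0 - d)
        f1, f2 = (ref, non_ref) if ref_first else (non_ref, ref)
        pos = RefPosition.FIRST if ref_first else RefPosition.SECOND
    elif name is Protocol.NO_REFERENCE:
        base_first = rng.random() < 0.5
        other_higher = rng.random() < 0.5
        low, high = protocol.no_reference_range_hz
        base = rng.uniform(low, high)
        other = base * (1.0 + d) if other_higher else base * (1.0 - d)
        f1, f2 = (base, other) if base_first else (other, base)
        pos = RefPosition.NONE
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown protocol {name!r}")

    if f1 <= 0 or f2 <= 0:
        raise ValueError("diff_percent too large: produced a non-positive frequency")
    return Trial(
        index=index,
        x1=math.log(f1),
        x2=math.log(f2),
        ref_position=pos,
        diff_percent=float(diff_percent),
    )


def trial_diff_percent(trial: Trial, protocol: ProtocolSpec) -> float:
    """The trial's frequency difference as % of its reference/base tone."""
    if trial.diff_percent is not None:
        return trial.diff_percent
    if protocol.name is Protocol.NO_REFERENCE:
        raise ValueError(
            "no-reference trials need a recorded diff_percent; the base tone "
            "is not recoverable from the stimuli alone"
        )
    return 100.0 * abs(trial.f2_hz - trial.f1_hz) / protocol.reference_hz


def jnd_from_block(block: Block, n_last: int = 20) -> float:
    """Threshold estimate: mean % difference over the block's last trials.

    For reference protocols the denominator is the 1000 Hz reference; for
    no-reference blocks each trial's own base tone plays that role (the
    recorded staircase difference).
    """
    if len(block.trials) < n_last:
        raise ValueError(f"need at least {n_last} trials, got {len(block.trials)}")
    last = block.trials[-n_last:]
    return float(np.mean([trial_diff_percent(t, block.protocol) for t in last]))
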