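"""Transitive-inference task definition.

A transitive schema over ``n_items`` ranked items (A=1 highest) defines a set
of ordered-pair trial types. In the delay variant of the task, the two items
of a pair are presented as instantaneous (single-timestep) input pulses
separated by a stimulus-free delay; the network must report, during a
subsequent choice period, whether item 1 or item 2 ranks higher. In the
traditional variant both items are presented simultaneously as one
concatenated input vector.

Times are expressed in units of the network time constant tau, integrated on
a grid of step ``dt`` (default tau/10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

#: Output-unit order: (choice 1, choice 2, rest).
N_OUT = 3
#: Target value for an activated output unit; resting target is 0.
ACTIVATED_TARGET = 5.0

EndOrder = Literal["first", "second", "both", "none"]


class InvalidSchemaError(ValueError):
    """Raised for schemas that cannot define a task (fewer than 2 items)."""


class UndefinedChoiceError(ValueError):
    """Raised when a correct choice is requested for a same-rank pair."""


class TimingError(ValueError):
    """Raised for inconsistent trial timing parameters."""


@dataclass(frozen=True)
class TransitiveSchema:
    """Ranked item set A > B > C > ... with 1-based ranks (A=1 highest)."""

    n_items: int = 7

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise InvalidSchemaError(
                f"a transitive schema needs at least 2 items, got {self.n_items}"
            )

    @property
    def items(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_items)]

    def rank(self, item: str) -> int:
        r = ord(item.upper()) - ord("A") + 1
        if not 1 <= r <= self.n_items:
            raise KeyError(item)
        return r

    def item(self, rank: int) -> str:
        if not 1 <= rank <= self.n_items:
            raise KeyError(rank)
        return chr(ord("A") + rank - 1)


@dataclass(frozen=True)
class TrialType:
    """An ordered item pair (item 1 presented first, item 2 second)."""

    rank1: int
    rank2: int
    n_items: int = 7

    def __post_init__(self) -> None:
        for r in (self.rank1, self.rank2):
            if not 1 <= r <= self.n_items:
                raise InvalidSchemaError(f"rank {r} outside 1..{self.n_items}")

    @property
    def correct_choice(self) -> int:
        """1 if item 1 ranks higher (smaller rank number), else 2."""
        if self.rank1 == self.rank2:
            raise UndefinedChoiceError(f"same-rank pair {self.rank1},{self.rank2}")
        return 1 if self.rank1 < self.rank2 else 2

    @property
    def symbolic_distance(self) -> int:
        return abs(self.rank1 - self.rank2)

    @property
    def is_training(self) -> bool:
        """Training (premise) trials are adjacent-rank pairs."""
        return self.symbolic_distance == 1

    @property
    def has_end_item(self) -> bool:
        ends = {1, self.n_items}
        return self.rank1 in ends or self.rank2 in ends

    @property
    def end_item_order(self) -> EndOrder:
        ends = {1, self.n_items}
        first = self.rank1 in ends
        second = self.rank2 in ends
        if first and second:
            return "both"
        if first:
            return "first"
        if second:
            return "second"
        return "none"

    @property
    def items(self) -> tuple[str, str]:
        schema = TransitiveSchema(self.n_items)
        return schema.item(self.rank1), schema.item(self.rank2)


def correct_choice(t: TrialType) -> int:
    """Correct response (1 or 2) for a trial type: choose the higher item."""
    return t.correct_choice


def enumerate_trial_types(n_items: int = 7) -> list[TrialType]:
    """All ordered pairs with distinct ranks, row-major by (rank1, rank2).

    For 7 items this yields 42 types: 12 training (adjacent) and 30 test.
    """
    if n_items < 2:
        raise InvalidSchemaError(f"n_items must be >= 2, got {n_items}")
    return [
        TrialType(r1, r2, n_items)
        for r1 in range(1, n_items + 1)
        for r2 in range(1, n_items + 1)
        if r1 != r2
    ]


def trial_type_table(n_items: int = 7) -> pd.DataFrame:
    """Trial-type metadata as a tidy table (exportable as CSV)."""
    rows = []
    for t in enumerate_trial_types(n_items):
        i1, i2 = t.items
        rows.append(
            dict(
                rank1=t.rank1,
                rank2=t.rank2,
                item1=i1,
                item2=i2,
                correct_choice=t.correct_choice,
                symbolic_distance=t.symbolic_distance,
                is_training=t.is_training,
                end_item_order=t.end_item_order,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialTiming:
    """Trial period durations (units of tau) on a dt grid.

    The realized layout is rest -> item-1 pulse (1 step) -> delay -> item-2
    pulse (1 step) -> choice. Pulse steps are not counted inside the period
    durations. For the ``variable`` variant the delay is drawn per trial,
    uniform over integer steps in [2 tau, 6 tau], with the total trial length
    fixed at the ``extended`` value (the choice period absorbs the slack).
    """

    dt: float = 0.1
    rest: float = 0.5
    delay: float = 2.0
    choice: float = 2.0
    variant: Literal["basic", "extended", "variable"] = "basic"
    #: Realized delay steps for variable-delay trials (None = use `delay`).
    realized_delay_steps: int | None = None

    @classmethod
    def basic(cls, dt: float = 0.1) -> "TrialTiming":
        return cls(dt=dt, rest=0.5, delay=2.0, choice=2.0, variant="basic")

    @classmethod
    def extended(cls, dt: float = 0.1) -> "TrialTiming":
        return cls(dt=dt, rest=0.5, delay=6.0, choice=6.0, variant="extended")

    @classmethod
    def variable(cls, rng: np.random.Generator, dt: float = 0.1) -> "TrialTiming":
        """Draw a variable-delay trial; total duration matches ``extended``."""
        lo, hi = round(2.0 / dt), round(6.0 / dt)
        steps = int(rng.integers(lo, hi + 1))
        return cls(
            dt=dt, rest=0.5, delay=6.0, choice=6.0, variant="variable",
            realized_delay_steps=steps,
        )

    def _steps(self, duration: float) -> int:
        n = duration / self.dt
        n_int = round(n)
        if abs(n - n_int) > 1e-9:
            raise TimingError(f"duration {duration} not a multiple of dt={self.dt}")
        return int(n_int)

    @property
    def rest_steps(self) -> int:
        return self._steps(self.rest)

    @property
    def delay_steps(self) -> int:
        if self.variant == "variable":
            steps = self.realized_delay_steps
            if steps is None:
                # analyses of variable-trained nets use the maximum delay
                return self._steps(self.delay)
            lo, hi = round(2.0 / self.dt), round(6.0 / self.dt)
            if not lo <= steps <= hi:
                raise TimingError(
                    f"variable delay {steps} steps outside [{lo}, {hi}]"
                )
            return steps
        return self._steps(self.delay)

    @property
    def choice_steps(self) -> int:
        if self.variant == "variable":
            # total trial duration fixed; choice absorbs delay slack
            total = self.rest_steps + 2 + self._steps(self.delay) + self._steps(self.choice)
            return total - self.rest_steps - 2 - self.delay_steps
        return self._steps(self.choice)

    @property
    def n_steps(self) -> int:
        return self.rest_steps + 1 + self.delay_steps + 1 + self.choice_steps

    @property
    def pulse1_index(self) -> int:
        """Timestep of the item-1 pulse (between rest and delay)."""
        return self.rest_steps

    @property
    def pulse2_index(self) -> int:
        """Timestep of the item-2 pulse (t2; between delay and choice)."""
        return self.rest_steps + 1 + self.delay_steps

    @property
    def delay_slice(self) -> slice:
        """The delay window: steps strictly between the two pulses."""
        return slice(self.pulse1_index + 1, self.pulse2_index)

    @property
    def choice_slice(self) -> slice:
        """The choice window: steps strictly after the item-2 pulse."""
        return slice(self.pulse2_index + 1, self.n_steps)


@dataclass
class TrialInput:
    """Time-resolved input tensor for one delay-TI trial."""

    u: np.ndarray  # (n_steps, N_in)
    pulse1_index: int
    pulse2_index: int
    timing: TrialTiming

    @property
    def n_steps(self) -> int:
        return self.u.shape[0]


@dataclass
class TargetOutput:
    """Piecewise-constant target for the three output units.

    The rest unit's target is activated up to and including the item-2 pulse;
    the correct choice unit's target is activated during the choice period.
    """

    target: np.ndarray  # (n_steps, N_OUT)
    timing: TrialTiming


def build_trial_input(
    panel: np.ndarray, t: TrialType, timing: TrialTiming
) -> tuple[TrialInput, TargetOutput]:
    """Lay out input pulses and targets for one trial.

    ``panel`` is the (n_items, N_in) item-embedding matrix; row ``rank-1``
    holds the input vector of the item with that rank.
    """
    n_steps = timing.n_steps
    n_in = panel.shape[1]
    u = np.zeros((n_steps, n_in), dtype=panel.dtype)
    p1, p2 = timing.pulse1_index, timing.pulse2_index
    u[p1] = panel[t.rank1 - 1]
    u[p2] = panel[t.rank2 - 1]

    target = np.zeros((n_steps, N_OUT), dtype=np.float64)
    target[: p2 + 1, 2] = ACTIVATED_TARGET
    target[timing.choice_slice, t.correct_choice - 1] = ACTIVATED_TARGET
    return TrialInput(u, p1, p2, timing), TargetOutput(target, timing)


def build_traditional_input(panel: np.ndarray, t: TrialType) -> np.ndarray:
    """Simultaneous two-item input: concatenation [u_item1; u_item2]."""
    return np.concatenate([panel[t.rank1 - 1], panel[t.rank2 - 1]])


def batch_targets(
    timing: TrialTiming, correct_choices: Sequence[int]
) -> np.ndarray:
    """Stacked (M, n_steps, N_OUT) targets for trials sharing one timing."""
    n_steps = timing.n_steps
    p2 = timing.pulse2_index
    m = len(correct_choices)
    target = np.zeros((m, n_steps, N_OUT), dtype=np.float64)
    target[:, : p2 + 1, 2] = ACTIVATED_TARGET
    cs = timing.choice_slice
    for i, c in enumerate(correct_choices):
        target[i, cs, c - 1] = ACTIVATED_TARGET
    return target
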