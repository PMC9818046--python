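"""Transformed up-down staircase engine for 2AFC discrimination testing.

Implements the 1-up/2-down adaptive rule with a 2:1 step-size ratio: the
test stimulus moves closer to the reference (harder) after two consecutive
correct responses and further from the reference (easier) after a single
error, with the up-step twice the size of the down-step.  This rule
concentrates trials near the stimulus difference at which the probability
of a correct response is sqrt(0.5) ~ 0.707.

Two staircases run interleaved per session: one presents test stimuli
below the reference, the other above.  Each staircase stops after a fixed
number of reversals (trials at which the step direction changes).  The
discrimination threshold is the mean absolute test-reference difference
over the retained reversals, after dropping the first reversal of each
staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

Side = Literal["below", "above"]
StepDirection = Literal["down", "up", "none"]

#: Probability of a correct response tracked by the 1-up/2-down rule.
TRACKED_P_CORRECT = np.sqrt(0.5)


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-rule parameters for one staircase.

    Parameters
    ----------
    reference_value:
        Magnitude of the reference stimulus (mm or g).
    test_min, test_max:
        Bounds of the available test-stimulus set.
    step_down:
        Decrement of ``|test - reference|`` applied after
        ``n_correct_to_step`` consecutive correct responses.
    step_up:
        Increment applied after ``n_incorrect_to_step`` errors; must be
        twice ``step_down`` (the 2:1 rule).
    side:
        Whether this staircase presents test stimuli below or above the
        reference.
    start_value:
        First test stimulus.  Defaults to the range bound on the
        staircase's side (the easiest available comparison).
    grid_increment:
        Smallest spacing of the physical stimulus set; every test value
        must lie on this grid.
    """

    reference_value: float
    test_min: float
    test_max: float
    step_down: float
    step_up: float
    side: Side
    start_value: float | None = None
    grid_increment: float = 1.0
    n_correct_to_step: int = 2
    n_incorrect_to_step: int = 1
    reversals_to_stop: int = 6

    def __post_init__(self) -> None:
        if not (self.test_min < self.reference_value < self.test_max):
            raise ValueError(
                "reference_value must lie strictly inside (test_min, test_max)"
            )
        if not np.isclose(self.step_up, 2.0 * self.step_down):
            raise ValueError("step_up must be exactly twice step_down (2:1 rule)")
        if self.side not in ("below", "above"):
            raise ValueError(f"side must be 'below' or 'above', got {self.side!r}")
        start = self.start_value
        if start is not None:
            if not (self.test_min <= start <= self.test_max):
                raise ValueError("start_value outside [test_min, test_max]")
            if np.isclose(start, self.reference_value):
                raise ValueError("start_value may not equal the reference")

    def _on_grid(self, value: float) -> bool:
        k = (value - self.test_min) / self.grid_increment
        return bool(np.isclose(k, np.round(k), atol=1e-9))

    @property
    def initial_value(self) -> float:
        if self.start_value is not None:
            return float(self.start_value)
        return float(self.test_min if self.side == "below" else self.test_max)

    @property
    def max_delta(self) -> float:
        """Largest |test - reference| available on this side."""
        if self.side == "below":
            return self.reference_value - self.test_min
        return self.test_max - self.reference_value


def width_config(side: Side) -> StaircaseConfig:
    """Standard width-discrimination staircase: 40 mm reference, 25-55 mm
    test set in 1 mm increments, 1 mm down-step, 2 mm up-step."""
    return StaircaseConfig(
        reference_value=40.0, test_min=25.0, test_max=55.0,
        step_down=1.0, step_up=2.0, side=side, grid_increment=1.0,
    )


def weight_config(side: Side) -> StaircaseConfig:
    """Standard weight-discrimination staircase: 200 g reference, 100-300 g
    test set in 5 g increments, 5 g down-step, 10 g up-step."""
    return StaircaseConfig(
        reference_value=200.0, test_min=100.0, test_max=300.0,
        step_down=5.0, step_up=10.0, side=side, grid_increment=5.0,
    )


@dataclass
class TrialRecord:
    """One 2AFC trial: which staircase, what was shown, what happened."""

    trial_index: int
    staircase_side: Side
    staircase_trial_index: int
    test_value: float
    presentation_order: Literal["reference-first", "test-first"]
    response_correct: bool | None = None
    step_direction_after: StepDirection = "none"
    is_reversal: bool = False


@dataclass
class StaircaseState:
    """Evolving state of one staircase."""

    config: StaircaseConfig
    test_value: float = field(init=False)
    consecutive_correct: int = 0
    history: list[TrialRecord] = field(default_factory=list)
    reversal_values: list[float] = field(default_factory=list)
    _last_step: StepDirection = "none"

    def __post_init__(self) -> None:
        self.test_value = self.config.initial_value

    @property
    def finished(self) -> bool:
        return len(self.reversal_values) >= self.config.reversals_to_stop

    @property
    def delta(self) -> float:
        return abs(self.test_value - self.config.reference_value)

    def _value_from_delta(self, delta: float) -> float:
        if self.config.side == "below":
            return self.config.reference_value - delta
        return self.config.reference_value + delta


def update_staircase(state: StaircaseState, response_correct: bool,
                     record: TrialRecord | None = None) -> StaircaseState:
    """Apply one response to a staircase, mutating and returning ``state``.

    On the second consecutive correct response the test stimulus steps
    toward the reference by ``step_down``; on any error it steps away by
    ``step_up``.  Steps that would reach or cross the reference clamp to
    one grid increment; steps beyond the stimulus-set bounds clamp to the
    bound.  A clamp that leaves the value unchanged counts as no step and
    cannot produce a reversal.  The reversal magnitude recorded is the
    |test - reference| of the stimulus presented on the reversal trial.
    """
    if state.finished:
        raise RuntimeError(
            f"update on finished staircase (side={state.config.side})"
        )
    cfg = state.config
    presented_delta = state.delta
    direction: StepDirection = "none"
    new_delta = presented_delta

    if response_correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= cfg.n_correct_to_step:
            target = presented_delta - cfg.step_down
            # never land on or cross the reference: smallest legal spacing
            new_delta = max(target, cfg.grid_increment)
            if not np.isclose(new_delta, presented_delta):
                direction = "down"
            state.consecutive_correct = 0
    else:
        target = presented_delta + cfg.step_up
        new_delta = min(target, cfg.max_delta)
        if not np.isclose(new_delta, presented_delta):
            direction = "up"
        state.consecutive_correct = 0

    is_reversal = (
        direction != "none"
        and state._last_step != "none"
        and direction != state._last_step
    )
    if is_reversal:
        state.reversal_values.append(presented_delta)
    if direction != "none":
        state._last_step = direction

    if record is not None:
        record.response_correct = response_correct
        record.step_direction_after = direction
        record.is_reversal = is_reversal
        state.history.append(record)
    else:
        state.history.append(TrialRecord(
            trial_index=len(state.history),
            staircase_side=cfg.side,
            staircase_trial_index=len(state.history),
            test_value=state.test_value,
            presentation_order="reference-first",
            response_correct=response_correct,
            step_direction_after=direction,
            is_reversal=is_reversal,
        ))
    if not state.finished:
        state.test_value = state._value_from_delta(new_delta)
    return state


def detect_reversal(history: Sequence[TrialRecord]) -> bool:
    """True iff the latest actual step reversed the preceding step's direction.

    Trials whose step direction is ``none`` (no-step trials, clamped
    non-moves) are transparent: they neither produce nor break a reversal.
    """
    steps = [t.step_direction_after for t in history
             if t.step_direction_after != "none"]
    if len(steps) < 2:
        return False
    return steps[-1] != steps[-2]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Reversal-mean discrimination threshold with provenance."""

    threshold: float
    retained_reversals: tuple[float, ...]
    dropped_reversals: tuple[float, ...]
    modality: str = ""

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


def compute_threshold(below_state: StaircaseState, above_state: StaircaseState,
                      modality: str = "") -> ThresholdEstimate:
    """Mean |test - reference| over retained reversals of both staircases.

    The first reversal of each staircase is discarded (it reflects the
    descent from the easy starting stimulus); the threshold is the
    arithmetic mean of the remaining ``2 * (reversals_to_stop - 1)``
    magnitudes — 10 for the standard six-reversal stop rule.
    """
    for state, name in ((below_state, "below"), (above_state, "above")):
        if not state.finished:
            raise RuntimeError(
                f"cannot compute threshold: {name} staircase unfinished "
                f"({len(state.reversal_values)}/"
                f"{state.config.reversals_to_stop} reversals)"
            )
    dropped = (below_state.reversal_values[0], above_state.reversal_values[0])
    retained = tuple(below_state.reversal_values[1:]) + tuple(
        above_state.reversal_values[1:])
    return ThresholdEstimate(
        threshold=float(np.mean(retained)),
        retained_reversals=retained,
        dropped_reversals=dropped,
        modality=modality,
    )


class DualStaircaseSession:
    """Two interleaved staircases (below/above the reference) with uniform
    random trial selection among the unfinished ones.

    A single seedable generator drives both the staircase choice and the
    reference/test presentation order, so a session is fully reproducible
    from its seed.  A ``max_trials`` guard bounds pathological sessions.
    """

    def __init__(self, below: StaircaseConfig, above: StaircaseConfig,
                 seed: int | np.random.Generator | None = None,
                 max_trials: int = 1000):
        if below.side != "below" or above.side != "above":
            raise ValueError("configs must be a (below, above) pair")
        self.below = StaircaseState(below)
        self.above = StaircaseState(above)
        self.rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        self.max_trials = max_trials
        self.log: list[TrialRecord] = []

    @property
    def finished(self) -> bool:
        return self.below.finished and self.above.finished

    def _state(self, side: Side) -> StaircaseState:
        return self.below if side == "below" else self.above

    def next_trial(self) -> TrialRecord:
        """Draw the next trial stub: side, test value, presentation order."""
        open_sides = [s for s in ("below", "above")
                      if not self._state(s).finished]
        if not open_sides:
            raise SessionComplete("both staircases finished")
        side: Side = open_sides[int(self.rng.integers(len(open_sides)))]
        order = ("reference-first", "test-first")[int(self.rng.integers(2))]
        state = self._state(side)
        return TrialRecord(
            trial_index=len(self.log),
            staircase_side=side,
            staircase_trial_index=len(state.history),
            test_value=state.test_value,
            presentation_order=order,
        )

    def submit_response(self, trial: TrialRecord, response_correct: bool) -> None:
        update_staircase(self._state(trial.staircase_side), response_correct,
                         record=trial)
        self.log.append(trial)

    def run(self, respond) -> ThresholdEstimate:
        """Run to completion against ``respond(trial) -> bool``."""
        while not self.finished:
            if len(self.log) >= self.max_trials:
                raise RuntimeError(
                    f"session exceeded max_trials={self.max_trials}")
            trial = self.next_trial()
            self.submit_response(trial, bool(respond(trial)))
        return compute_threshold(self.below, self.above)


class SessionComplete(Exception):
    """Raised when a trial is requested after both staircases finished."""


def replay_threshold(log: Iterable[TrialRecord],
                     below: StaircaseConfig, above: StaircaseConfig,
                     ) -> ThresholdEstimate:
    """Recompute a threshold from a raw trial log alone.

    Independent of the live session bookkeeping: walks the recorded
    (side, test value, response) sequence, re-derives every step and
    reversal from the adaptive rule, and recomputes the reversal-mean
    threshold.  Used to audit session logs.
    """
    states = {"below": StaircaseState(below), "above": StaircaseState(above)}
    for rec in log:
        st = states[rec.staircase_side]
        if not np.isclose(st.test_value, rec.test_value):
            raise ValueError(
                f"log inconsistent at trial {rec.trial_index}: expected test "
                f"value {st.test_value}, log says {rec.test_value}"
            )
        update_staircase(st, bool(rec.response_correct))
    return compute_threshold(states["below"], states["above"])


def run_session(modality: Literal["width", "weight"], respond,
                seed: int | None = None,
                max_trials: int = 1000) -> tuple[ThresholdEstimate,
                                                 DualStaircaseSession]:
    """Convenience wrapper: build the standard width or weight session,
    run it against a responder and return (estimate, session)."""
    if modality == "width":
        below, above = width_config("below"), width_config("above")
    elif modality == "weight":
        below, above = weight_config("below"), weight_config("above")
    else:
        raise ValueError(f"unknown modality {modality!r}")
    session = DualStaircaseSession(below, above, seed=seed,
                                   max_trials=max_trials)
    est = session.run(respond)
    return ThresholdEstimate(est.threshold, est.retained_reversals,
                             est.dropped_reversals, modality), session
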