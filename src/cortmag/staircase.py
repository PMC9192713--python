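"""Adaptive 3-down-1-up PEST staircases for 2AFC contrast thresholds.

Contrast is stepped in log10 units: down after three consecutive correct
responses, up after any incorrect response, which converges at the accuracy
p solving p^3 = 1/2 (79.4%).  Step size follows PEST rules: it halves at a
reversal and doubles after successive same-direction steps, with the classic
delay of the doubling in the run immediately following a reversal that was
preceded by a doubled step.

A measurement session mirrors the psychophysics design: four staircases,
one per polar-angle location, randomly interleaved within a block of 50
trials per location; five blocks per observer; the per-location threshold is
the across-block mean, and sensitivity is its reciprocal.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .cohort import PsychometricObserver, respond

__all__ = [
    "StaircaseState",
    "BlockResult",
    "ObserverMeasures",
    "staircase_update",
    "run_block",
    "run_observer",
    "aggregate_observer",
    "staircase_convergence_accuracy",
]

CONTRAST_FLOOR = 0.001


@dataclass
class StaircaseState:
    """State of one 3-down-1-up PEST staircase (levels in Michelson contrast)."""

    level: float = 0.5
    step: float = 0.3              # log10 units
    min_step: float = 0.01
    max_step: float = 0.6
    n_down: int = 3
    correct_streak: int = 0
    last_direction: int = 0        # +1 up, -1 down, 0 none yet
    steps_in_run: int = 0          # consecutive steps in the current direction
    last_step_doubled: bool = False
    doubling_delayed: bool = False  # pending delay after a doubled-step reversal
    reversal_levels: list[float] = field(default_factory=list)
    levels: list[float] = field(default_factory=list)
    responses: list[bool] = field(default_factory=list)

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)


def _take_step(state: StaircaseState, direction: int) -> None:
    """Move the level and adapt the step size per PEST rules."""
    if state.last_direction != 0 and direction != state.last_direction:
        # reversal: record, halve the step; if the step just before the
        # reversal was a doubled one, delay the next doubling by one step
        state.reversal_levels.append(state.level)
        state.doubling_delayed = state.last_step_doubled
        state.step = max(state.step / 2.0, state.min_step)
        state.steps_in_run = 1
        state.last_step_doubled = False
    else:
        state.steps_in_run += 1
        threshold = 4 if state.doubling_delayed else 3
        if state.steps_in_run >= threshold:
            state.step = min(state.step * 2.0, state.max_step)
            state.last_step_doubled = True
            state.doubling_delayed = False
        else:
            state.last_step_doubled = False

    log_level = np.log10(state.level) + direction * state.step
    state.level = float(np.clip(10.0**log_level, CONTRAST_FLOOR, 1.0))
    state.last_direction = direction


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase one trial; returns a new state object."""
    state = copy.deepcopy(state)
    state.levels.append(state.level)
    state.responses.append(bool(correct))
    if correct:
        state.correct_streak += 1
        if state.correct_streak >= state.n_down:
            state.correct_streak = 0
            _take_step(state, -1)
    else:
        state.correct_streak = 0
        _take_step(state, +1)
    return state


def threshold_estimate(state: StaircaseState, n_reversals: int = 6) -> float:
    """Mean log-contrast over the last ``n_reversals`` reversal levels.

    Falls back to the final level when fewer reversals occurred.
    """
    if state.n_reversals >= n_reversals:
        tail = np.log10(state.reversal_levels[-n_reversals:])
        return float(10.0 ** tail.mean())
    return float(state.level)


@dataclass
class BlockResult:
    """One block: 50 interleaved trials per location, one threshold each."""

    thresholds: dict[str, float]
    trial_log: list[dict]
    block_index: int = 0

    def accuracy(self, location: str | None = None,
                 last_fraction: float = 1.0) -> float:
        trials = [t for t in self.trial_log
                  if location is None or t["location"] == location]
        trials = trials[int(len(trials) * (1.0 - last_fraction)):]
        return float(np.mean([t["correct"] for t in trials]))


@dataclass
class ObserverMeasures:
    """Across-block mean thresholds and reciprocal sensitivities per location."""

    thresholds: dict[str, float]
    sensitivity: dict[str, float]


def run_block(
    observers: dict[str, PsychometricObserver],
    n_trials_per_location: int = 50,
    seed: int = 0,
    block_index: int = 0,
    staircase_kwargs: dict | None = None,
) -> BlockResult:
    """Run one block of randomly interleaved staircases, one per location."""
    rng = np.random.default_rng(seed)
    locations = list(observers)
    states = {loc: StaircaseState(**(staircase_kwargs or {})) for loc in locations}

    order = np.repeat(np.arange(len(locations)), n_trials_per_location)
    rng.shuffle(order)

    log = []
    for trial, loc_idx in enumerate(order):
        loc = locations[loc_idx]
        level = states[loc].level
        correct = respond(observers[loc], level, rng)
        states[loc] = staircase_update(states[loc], correct)
        log.append({"block": block_index, "trial": trial, "location": loc,
                    "contrast": level, "correct": correct})

    thresholds = {loc: threshold_estimate(states[loc]) for loc in locations}
    return BlockResult(thresholds=thresholds, trial_log=log,
                       block_index=block_index)


def run_observer(
    observers: dict[str, PsychometricObserver],
    n_blocks: int = 5,
    n_trials_per_location: int = 50,
    seed: int = 0,
) -> list[BlockResult]:
    """Run the full five-block session for one observer."""
    seeds = np.random.SeedSequence(seed).generate_state(n_blocks)
    return [run_block(observers, n_trials_per_location, seed=int(s),
                      block_index=b)
            for b, s in enumerate(seeds)]


def aggregate_observer(blocks: list[BlockResult], n_required: int = 5,
                       relax: bool = False) -> ObserverMeasures:
    """Average thresholds across blocks; sensitivity is the reciprocal mean."""
    if len(blocks) != n_required and not relax:
        raise ValueError(
            f"expected {n_required} blocks, got {len(blocks)} (set relax=True "
            "to aggregate over the available blocks)")
    locations = list(blocks[0].thresholds)
    thresholds = {loc: float(np.mean([b.thresholds[loc] for b in blocks]))
                  for loc in locations}
    sensitivity = {loc: 1.0 / thresholds[loc] for loc in locations}
    return ObserverMeasures(thresholds=thresholds, sensitivity=sensitivity)


def staircase_convergence_accuracy(n_down: int = 3, n_up: int = 1) -> float:
    """Accuracy p at which an n-down/1-up staircase converges: p^n_down = 0.5.

    For the 3-down-1-up rule this is 0.5^(1/3) = 0.7937..., i.e. 79.4%.
    ``n_up`` other than 1 is not supported.
    """
    if n_up != 1:
        raise NotImplementedError("only 1-up rules have this closed form")
    return 0.5 ** (1.0 / n_down)
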