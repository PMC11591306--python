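"""Closed-loop reward logic of the circle-drawing task.

The task rewards circle *size*: after five trials scored against a fixed
4.3 cm target, the target radius is set to double the mean drawn radius of
those five trials, so every participant has to roughly double their
spontaneous circle size.  Reward on each trial is determined by an
adaptive percentile staircase: a trial is rewarded when its relative
radius error is strictly smaller than the fifth-largest of the past ten
errors (close to the running median), which holds the success frequency
near 50 % regardless of skill.

The relative radius error treats too-small and too-large circles
symmetrically::

    e = max(r / T, T / r) - 1

with drawn radius ``r`` and target ``T``; it is zero exactly at the
target and invariant under a common rescaling of ``r`` and ``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

from .geometry import RawTrajectory, TrialGeometry, trial_geometry

__all__ = [
    "TargetRule",
    "CriterionState",
    "TrialRecord",
    "ColdStartError",
    "relative_radius_error",
    "set_target",
    "criterion_threshold",
    "assign_reward",
    "run_session",
]

#: Main-phase trial count of the experiment.
N_MAIN_TRIALS = 80

#: Reward granted on the very first trial iff error < this (drawn radius
#: within a factor two of the target); see the module documentation.
COLD_START_THRESHOLD = 1.0


class ColdStartError(ValueError):
    """The criterion window is empty; the cold-start rule applies."""


@dataclass(frozen=True)
class TargetRule:
    """How the target radius is set.

    initial_target : cm, used for the first ``n_baseline_trials`` trials.
    multiplier : target = multiplier x mean baseline radius thereafter.
    n_baseline_trials : number of trials that define the baseline.
    """

    initial_target: float = 4.3
    multiplier: float = 2.0
    n_baseline_trials: int = 5

    def __post_init__(self) -> None:
        if self.initial_target <= 0:
            raise ValueError("initial_target must be positive")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.n_baseline_trials < 1:
            raise ValueError("n_baseline_trials must be >= 1")


@dataclass
class CriterionState:
    """Sliding window of past relative radius errors.

    Holds at most ``window_size`` (10) recent errors; the reward
    threshold is the ``order_index``-th largest (5th) once the window is
    full and the ceil(n/2)-th largest while it is still filling, which
    keeps the implied reward probability near one half from the second
    trial on.
    """

    window: list[float] = field(default_factory=list)
    window_size: int = 10
    order_index: int = 5

    def push(self, error: float) -> None:
        """Append an error, evicting the oldest beyond the window size."""
        if error < 0:
            raise ValueError("relative errors are nonnegative")
        self.window.append(float(error))
        if len(self.window) > self.window_size:
            del self.window[: len(self.window) - self.window_size]

    def replace(self, errors: Sequence[float]) -> None:
        """Replace the window contents (most recent last)."""
        self.window = [float(e) for e in errors][-self.window_size:]


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial: drawn radius, target, error, reward."""

    index: int  # 1-based
    radius: float
    target_radius: float
    relative_error: float
    rewarded: bool
    geometry: Optional[TrialGeometry] = None


def relative_radius_error(radius: float, target: float) -> float:
    """max(r/T, T/r) - 1: symmetric relative size error, zero at target."""
    if radius <= 0 or target <= 0:
        raise ValueError("radius and target must be positive")
    return max(radius / target, target / radius) - 1.0


def set_target(baseline_radii: Sequence[float], rule: TargetRule) -> float:
    """Target radius: ``multiplier`` times the mean baseline radius."""
    if len(baseline_radii) != rule.n_baseline_trials:
        raise ValueError(
            f"expected {rule.n_baseline_trials} baseline radii, got {len(baseline_radii)}"
        )
    if any(r <= 0 for r in baseline_radii):
        raise ValueError("baseline radii must be positive")
    return rule.multiplier * (sum(baseline_radii) / len(baseline_radii))


def criterion_threshold(state: CriterionState) -> float:
    """Current reward threshold: an order statistic of the window.

    With a full window of ``window_size`` errors the threshold is the
    ``order_index``-th largest; with ``n`` < ``window_size`` entries it is
    the ceil(n/2)-th largest.  The returned value is always an element of
    the window.
    """
    n = len(state.window)
    if n == 0:
        raise ColdStartError("criterion window is empty")
    k = state.order_index if n >= state.window_size else math.ceil(n / 2)
    return sorted(state.window, reverse=True)[k - 1]


def assign_reward(
    error: float,
    state: CriterionState,
    cold_start_threshold: float = COLD_START_THRESHOLD,
) -> bool:
    """Reward iff the error is strictly below the current threshold.

    On a cold start (empty window, the first trial) the error is compared
    against ``cold_start_threshold`` instead.  Ties with the threshold
    are not rewarded ("smaller than" is strict).  The caller pushes the
    error into the window afterwards.
    """
    if error < 0:
        raise ValueError("error must be nonnegative")
    try:
        return error < criterion_threshold(state)
    except ColdStartError:
        return error < cold_start_threshold


RadiusSource = Union[
    Iterable[float],
    Callable[[Optional[TrialRecord]], Union[float, RawTrajectory]],
]


def run_session(
    source: RadiusSource,
    rule: TargetRule | None = None,
    n_trials: int = N_MAIN_TRIALS,
    *,
    window_size: int = 10,
    order_index: int = 5,
    cold_start_threshold: float = COLD_START_THRESHOLD,
    recompute_errors_on_target_switch: bool = True,
) -> list[TrialRecord]:
    """Run one main phase of the task against a radius source.

    ``source`` is either an iterable of drawn radii (open loop) or a
    callable receiving the previous :class:`TrialRecord` (``None`` before
    the first trial) and returning the next drawn radius or a raw
    trajectory — the closed-loop protocol a simulated learner uses.  A
    trajectory is reduced through :func:`~circledraw.geometry.trial_geometry`
    and its radius used for scoring.

    The first ``rule.n_baseline_trials`` trials are scored against the
    initial target; the target then switches to ``multiplier`` times
    their mean radius.  With ``recompute_errors_on_target_switch`` (the
    default) the criterion-window entries for the baseline trials are
    recomputed against the new target so the staircase compares like with
    like; the records themselves keep the target and error the
    participant actually experienced.
    """
    if rule is None:
        rule = TargetRule()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    if callable(source):
        pull = source
    else:
        it: Iterator[float] = iter(source)

        def pull(_prev: Optional[TrialRecord]) -> float:
            return next(it)

    state = CriterionState(window_size=window_size, order_index=order_index)
    target = rule.initial_target
    records: list[TrialRecord] = []
    prev: Optional[TrialRecord] = None

    for i in range(1, n_trials + 1):
        drawn = pull(prev)
        if isinstance(drawn, RawTrajectory):
            geom = trial_geometry(drawn)
            radius = geom.radius
        else:
            geom = None
            radius = float(drawn)
        if radius <= 0:
            raise ValueError(f"trial {i}: drawn radius must be positive")

        if i == rule.n_baseline_trials + 1:
            target = set_target([r.radius for r in records], rule)
            if recompute_errors_on_target_switch:
                state.replace(
                    [relative_radius_error(r.radius, target) for r in records]
                )

        error = relative_radius_error(radius, target)
        rewarded = assign_reward(error, state, cold_start_threshold)
        state.push(error)
        prev = TrialRecord(
            index=i,
            radius=radius,
            target_radius=target,
            relative_error=error,
            rewarded=rewarded,
            geometry=geom,
        )
        records.append(prev)

    return records
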