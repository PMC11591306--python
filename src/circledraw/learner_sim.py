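"""Simulated participants for the circle-drawing task.

The generator produces sessions that are format-identical to analysed
real data, driven by a minimal reward-based learner: the intended circle
size performs a random walk in *log-radius* space (size errors in this
task are naturally multiplicative — halving and doubling are symmetric),
with two reward-dependent mechanisms:

* **retention** — the intended radius is pulled toward the radius of the
  last rewarded trial (repeat what worked);
* **reward-gated exploration** — the Gaussian innovation is larger after
  a failure than after a success (explore when it did not work).

Each intended radius is executed with multiplicative motor noise and
rendered as a pen path: a slightly elliptical, slightly offset loop
swept at a varying angular speed with a small closure gap, sampled at
60 Hz — the features of real drawings that the geometry stage must be
robust to.  The analysis never sees the intended radius, only the
trajectory (or, with ``render=False``, the executed radius).

The learner is a deliberately simple stand-in that reproduces the
qualitative structure of the behavior (learning toward the doubled
target, larger changes after failure); it is not a claim about the
mechanism participants use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .geometry import RawTrajectory
from .metrics import Session
from .task_engine import N_MAIN_TRIALS, TargetRule, TrialRecord, run_session

__all__ = [
    "AgentParams",
    "TrajectoryStyle",
    "REFERENCE_AGENT",
    "DEFAULT_CHILD",
    "DEFAULT_ADULT",
    "named_params",
    "step_intended_radius",
    "execute_trial",
    "simulate_agent",
    "simulate_cohort",
    "null_params",
]

#: Tablet sampling rate, Hz.
SAMPLE_RATE = 60.0


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant.

    baseline_radius : cm — spontaneous circle size (initial intended radius).
    motor_noise_sd : SD of the log-radius execution noise (multiplicative).
    explore_sd_fail : SD of the log-radius innovation after a failure.
    explore_sd_success : SD after a success (<= explore_sd_fail for a
        reward-sensitive learner; equal SDs switch the gate off).
    retention : in [0, 1] — pull of the intended radius toward the
        intended radius of the last rewarded trial.
    """

    baseline_radius: float = 2.5
    motor_noise_sd: float = 0.05
    explore_sd_fail: float = 0.15
    explore_sd_success: float = 0.05
    retention: float = 0.9

    def __post_init__(self) -> None:
        if self.baseline_radius <= 0:
            raise ValueError("baseline_radius must be positive")
        for name in ("motor_noise_sd", "explore_sd_fail", "explore_sd_success"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")


@dataclass(frozen=True)
class TrajectoryStyle:
    """How an intended circle is rendered as a pen path.

    aspect_jitter_sd : SD of the log axis ratio of the drawn ellipse.
    center_jitter_sd : cm — SD of the per-trial circle-center scatter.
    angular_speed_modulation : in [0, 1) — depth of the sinusoidal
        angular-speed variation along the sweep (0 = constant speed).
    samples_per_trial : samples at 60 Hz (120 ~ the typical 2 s drawing).
    closure_gap_deg : degrees left open between start and end of the loop.
    base_center : cm — mean circle center on the tablet.
    """

    aspect_jitter_sd: float = 0.05
    center_jitter_sd: float = 0.5
    angular_speed_modulation: float = 0.3
    samples_per_trial: int = 120
    closure_gap_deg: float = 4.0
    base_center: tuple[float, float] = (14.0, 11.0)

    def __post_init__(self) -> None:
        if self.samples_per_trial < 10:
            raise ValueError("samples_per_trial must be >= 10")
        if not 0.0 <= self.angular_speed_modulation < 1.0:
            raise ValueError("angular_speed_modulation must be in [0, 1)")


#: The reference learner used for calibration runs.
REFERENCE_AGENT = AgentParams()

#: Named parameter sets; children are more variable than adults (larger
#: motor noise and exploration) and draw slightly larger baselines.
DEFAULT_CHILD = AgentParams(
    baseline_radius=2.8,
    motor_noise_sd=0.08,
    explore_sd_fail=0.20,
    explore_sd_success=0.08,
    retention=0.85,
)
DEFAULT_ADULT = AgentParams(
    baseline_radius=2.3,
    motor_noise_sd=0.05,
    explore_sd_fail=0.15,
    explore_sd_success=0.05,
    retention=0.9,
)

_NAMED = {
    "reference": REFERENCE_AGENT,
    "default_child": DEFAULT_CHILD,
    "default_adult": DEFAULT_ADULT,
}


def named_params(name: str) -> AgentParams:
    """Look up a named agent parameter set."""
    try:
        return _NAMED[name]
    except KeyError:
        raise KeyError(
            f"unknown agent parameter set {name!r}; available: {sorted(_NAMED)}"
        ) from None


def step_intended_radius(
    current_log_radius: float,
    last_rewarded_log_radius: float,
    rewarded_prev: bool,
    p: AgentParams,
    rng: np.random.Generator,
) -> float:
    """One learning update of the intended log radius.

    ``(1 - retention) * current + retention * last_rewarded + eps`` with
    ``eps ~ N(0, explore_sd_success)`` if the previous trial was rewarded
    and ``N(0, explore_sd_fail)`` otherwise.
    """
    sd = p.explore_sd_success if rewarded_prev else p.explore_sd_fail
    eps = rng.normal(0.0, sd) if sd > 0 else 0.0
    return (
        (1.0 - p.retention) * current_log_radius
        + p.retention * last_rewarded_log_radius
        + eps
    )


def execute_trial(
    intended_log_radius: float,
    p: AgentParams,
    style: TrajectoryStyle,
    rng: np.random.Generator,
) -> RawTrajectory:
    """Render one intended circle as a raw pen trajectory.

    The executed radius is ``exp(intended + N(0, motor_noise_sd))``; the
    path is an ellipse with a random log-normal axis ratio and random
    orientation, center jittered around the style's base center, swept
    over ``360° - closure_gap_deg`` starting at a random phase with a
    sinusoidally modulated angular speed, time-stamped at 60 Hz.
    """
    r = math.exp(intended_log_radius + rng.normal(0.0, p.motor_noise_sd))
    q = math.exp(rng.normal(0.0, style.aspect_jitter_sd))  # axis ratio a/b
    a = r * math.sqrt(q)
    b = r / math.sqrt(q)
    cx = style.base_center[0] + rng.normal(0.0, style.center_jitter_sd)
    cy = style.base_center[1] + rng.normal(0.0, style.center_jitter_sd)
    orientation = rng.uniform(0.0, math.pi)
    start_angle = rng.uniform(0.0, 2.0 * math.pi)

    n = style.samples_per_trial
    u = np.linspace(0.0, 1.0, n)
    m = style.angular_speed_modulation
    # monotone time warp: w(0)=0, w(1)=1, w'(u) = 1 + m*cos(2*pi*u) > 0
    w = u + m * np.sin(2.0 * np.pi * u) / (2.0 * np.pi)
    sweep = 2.0 * np.pi - math.radians(style.closure_gap_deg)
    theta = start_angle + sweep * w

    ex = a * np.cos(theta)
    ey = b * np.sin(theta)
    co, so = math.cos(orientation), math.sin(orientation)
    x = cx + co * ex - so * ey
    y = cy + so * ex + co * ey
    t = np.arange(n) / SAMPLE_RATE
    return RawTrajectory(t=t, x=x, y=y)


def _executed_radius(
    intended_log_radius: float, p: AgentParams, rng: np.random.Generator
) -> float:
    """Executed radius without rendering a path (same noise model)."""
    return math.exp(intended_log_radius + rng.normal(0.0, p.motor_noise_sd))


def simulate_agent(
    p: AgentParams,
    rng: np.random.Generator,
    *,
    style: Optional[TrajectoryStyle] = None,
    rule: Optional[TargetRule] = None,
    n_trials: int = N_MAIN_TRIALS,
    render: bool = True,
    participant_id: str = "sim-000",
    group: str = "adult",
    age: int = 30,
    trajectory_sink: Optional[list[RawTrajectory]] = None,
) -> Session:
    """Play one agent through the closed-loop task.

    With ``render=True`` (default) every trial produces a full pen
    trajectory that the engine reduces through the geometry stage; with
    ``render=False`` only the executed radius is scored — statistically
    equivalent for radius-based metrics and much faster for large
    Monte-Carlo runs.  When ``trajectory_sink`` is a list, every rendered
    trajectory is appended to it in trial order.
    """
    if style is None:
        style = TrajectoryStyle()
    intended = math.log(p.baseline_radius)
    last_rewarded = intended
    state = {"intended": intended, "last_rewarded": last_rewarded}

    def source(prev: Optional[TrialRecord]):
        if prev is not None:
            if prev.rewarded:
                state["last_rewarded"] = state["intended"]
            state["intended"] = step_intended_radius(
                state["intended"], state["last_rewarded"], prev.rewarded, p, rng
            )
        if render:
            traj = execute_trial(state["intended"], p, style, rng)
            if trajectory_sink is not None:
                trajectory_sink.append(traj)
            return traj
        return _executed_radius(state["intended"], p, rng)

    records = run_session(source, rule=rule, n_trials=n_trials)
    return Session(
        participant_id=participant_id,
        group=group,
        age=age,
        trials=records,
        n_main_trials=n_trials,
    )


ParamsSampler = Callable[[int, np.random.Generator], AgentParams]


def simulate_cohort(
    n_agents: int,
    master_seed: int,
    *,
    params_sampler: Optional[ParamsSampler] = None,
    params: Optional[AgentParams] = None,
    style: Optional[TrajectoryStyle] = None,
    rule: Optional[TargetRule] = None,
    n_trials: int = N_MAIN_TRIALS,
    render: bool = True,
    group: str = "adult",
    age_sampler: Optional[Callable[[int, np.random.Generator], int]] = None,
    trajectory_sinks: Optional[dict[str, list[RawTrajectory]]] = None,
    id_prefix: str = "sim",
) -> list[Session]:
    """Simulate a cohort of independent agents.

    One master seed spawns per-agent independent substreams via
    ``np.random.SeedSequence(master_seed).spawn(n_agents)``, so cohorts
    are reproducible and agents statistically independent.  Per-agent
    parameters come from ``params_sampler(i, rng)`` when given, else
    from ``params`` (default: the reference agent).
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    if params is None:
        params = REFERENCE_AGENT
    streams = np.random.SeedSequence(master_seed).spawn(n_agents)
    sessions: list[Session] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        p = params_sampler(i, rng) if params_sampler is not None else params
        age = age_sampler(i, rng) if age_sampler is not None else (10 if group == "child" else 30)
        pid = f"{id_prefix}-{i:03d}"
        sink: Optional[list[RawTrajectory]] = None
        if trajectory_sinks is not None:
            sink = trajectory_sinks.setdefault(pid, [])
        sessions.append(
            simulate_agent(
                p,
                rng,
                style=style,
                rule=rule,
                n_trials=n_trials,
                render=render,
                participant_id=pid,
                group=group,
                age=age,
                trajectory_sink=sink,
            )
        )
    return sessions


def null_params(base: AgentParams = REFERENCE_AGENT) -> AgentParams:
    """Reward-independent control parameters.

    Equal exploration SDs after success and failure *and* zero retention:
    with both reward-dependent paths removed, reward feedback has no
    causal route into behavior, so conditional variability measures obey
    their null hypothesis exactly.  Used for type-I-error calibration.
    """
    return replace(
        base,
        explore_sd_success=base.explore_sd_fail,
        retention=0.0,
    )
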