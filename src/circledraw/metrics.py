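"""Per-participant outcome measures.

From a session's ordered trial records this module derives the study's
outcome measures:

* **baseline radius** — mean drawn radius of the first five main-phase
  trials (the same trials that set the target);
* **fraction learned** — mean radius of the last ten main-phase trials
  divided by the baseline radius, minus one.  Because the target is twice
  the baseline, 0 means no learning and 1 means the target radius;
* **trial-to-trial ratios** — for each interior trial t the folded ratio
  ``max(r_{t+1}/r_{t-1}, r_{t-1}/r_{t+1})`` (>= 1; halving and doubling
  count the same), assigned to the after-reward or after-no-reward group
  by the reward at trial t.  Spanning t-1 to t+1 rather than t to t+1
  avoids the sampling bias that reward-zone truncation induces on
  rewarded trials.  Variability is the median of each group;
* **success frequency** — rewarded trials / main-phase trials;
* **exclusion** — a participant is excluded when more than 20 % of their
  trials are non-circular; for included participants every trial (also
  non-circular ones) contributes to the metrics.

Task-irrelevant variability (circle location and aspect ratio — neither
affects reward) is measured with the same t-1/t+1 pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Optional, Sequence

from .task_engine import TrialRecord

__all__ = [
    "EXCLUSION_PCT",
    "Session",
    "ParticipantSummary",
    "baseline_radius",
    "fraction_learned",
    "folded_ratio",
    "trial_to_trial_ratios",
    "task_irrelevant_changes",
    "summarize",
]

#: Participants with more than this percentage of non-circular trials
#: are excluded from the analysis.
EXCLUSION_PCT = 20.0

#: Trials defining the baseline (and, x2, the target).
N_BASELINE = 5

#: Trials at the end of the main phase defining final performance.
N_FINAL = 10


@dataclass
class Session:
    """One participant's ordered trials plus metadata."""

    participant_id: str
    group: str  # "child" | "adult"
    age: int  # rounded-down years
    trials: list[TrialRecord]
    handedness: str = "right"
    language: str = "dutch"
    n_main_trials: Optional[int] = None  # defaults to len(trials)

    def __post_init__(self) -> None:
        if self.group not in ("child", "adult"):
            raise ValueError("group must be 'child' or 'adult'")
        if self.n_main_trials is None:
            self.n_main_trials = len(self.trials)

    @property
    def main_trials(self) -> list[TrialRecord]:
        return self.trials[: self.n_main_trials]


@dataclass(frozen=True)
class ParticipantSummary:
    """Derived outcome measures for one participant.

    Missing medians (an empty reward condition) are NaN.
    """

    participant_id: str
    group: str
    age: int
    baseline_radius: float
    fraction_learned: float
    median_ratio_after_reward: float
    median_ratio_after_no_reward: float
    success_frequency: float
    pct_noncircular: float
    excluded: bool


def baseline_radius(s: Session) -> float:
    """Mean drawn radius of the first five main-phase trials."""
    trials = s.main_trials
    if len(trials) < N_BASELINE:
        raise ValueError(f"need >= {N_BASELINE} main-phase trials")
    return sum(t.radius for t in trials[:N_BASELINE]) / N_BASELINE


def fraction_learned(s: Session) -> float:
    """mean(last ten radii) / baseline - 1; 0 = no learning, 1 = target."""
    trials = s.main_trials
    if len(trials) < N_FINAL:
        raise ValueError(f"need >= {N_FINAL} main-phase trials")
    final = sum(t.radius for t in trials[-N_FINAL:]) / N_FINAL
    return final / baseline_radius(s) - 1.0


def folded_ratio(a: float, b: float) -> float:
    """max(a/b, b/a): direction-free change measure, >= 1."""
    if a <= 0 or b <= 0:
        raise ValueError("ratios need positive inputs")
    return max(a / b, b / a)


def trial_to_trial_ratios(s: Session) -> tuple[list[float], list[float]]:
    """Folded radius ratios split by the reward at the middle trial.

    Returns ``(after_reward, after_no_reward)``.  For each trial t with
    2 <= t <= N-1, ``folded_ratio(r_{t+1}, r_{t-1})`` goes to the first
    list when trial t was rewarded, else to the second.  Boundary trials
    have no ratio.
    """
    trials = s.main_trials
    if len(trials) < 3:
        raise ValueError("need >= 3 main-phase trials")
    after_reward: list[float] = []
    after_no_reward: list[float] = []
    for t in range(1, len(trials) - 1):
        ratio = folded_ratio(trials[t + 1].radius, trials[t - 1].radius)
        (after_reward if trials[t].rewarded else after_no_reward).append(ratio)
    return after_reward, after_no_reward


def task_irrelevant_changes(
    s: Session,
) -> dict[str, tuple[list[float], list[float]]]:
    """Trial-to-trial changes in aspect ratio and circle location.

    Uses the same t-1/t+1 pairing and reward conditioning as
    :func:`trial_to_trial_ratios`.  Aspect-ratio changes are folded
    ratios (>= 1); location changes are Euclidean distances between the
    trial centers in cm.  Returns a mapping with keys ``"aspect"`` and
    ``"center"``, each ``(after_reward, after_no_reward)``.  Trials
    without geometry are skipped.
    """
    trials = s.main_trials
    if len(trials) < 3:
        raise ValueError("need >= 3 trials with geometry")
    aspect: tuple[list[float], list[float]] = ([], [])
    center: tuple[list[float], list[float]] = ([], [])
    for t in range(1, len(trials) - 1):
        g_prev = trials[t - 1].geometry
        g_next = trials[t + 1].geometry
        if g_prev is None or g_next is None:
            continue
        cond = 0 if trials[t].rewarded else 1
        aspect[cond].append(folded_ratio(g_next.aspect_ratio, g_prev.aspect_ratio))
        center[cond].append(
            math.hypot(
                g_next.center[0] - g_prev.center[0],
                g_next.center[1] - g_prev.center[1],
            )
        )
    return {"aspect": aspect, "center": center}


def _median_or_nan(values: Sequence[float]) -> float:
    return float(median(values)) if values else math.nan


def summarize(s: Session) -> ParticipantSummary:
    """All outcome measures for one session.

    Non-circular trials count toward the exclusion percentage but their
    radii still enter the learning and variability metrics (trials
    without geometry are treated as circular).
    """
    trials = s.main_trials
    if not trials:
        raise ValueError("empty session")
    after_reward, after_no_reward = trial_to_trial_ratios(s)
    n_noncircular = sum(
        1 for t in trials if t.geometry is not None and not t.geometry.is_circular
    )
    pct = 100.0 * n_noncircular / len(trials)
    return ParticipantSummary(
        participant_id=s.participant_id,
        group=s.group,
        age=s.age,
        baseline_radius=baseline_radius(s),
        fraction_learned=fraction_learned(s),
        median_ratio_after_reward=_median_or_nan(after_reward),
        median_ratio_after_no_reward=_median_or_nan(after_no_reward),
        success_frequency=sum(t.rewarded for t in trials) / len(trials),
        pct_noncircular=pct,
        excluded=pct > EXCLUSION_PCT,
    )
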