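"""Social-evaluation task schedules.

The task presents a sequence of raters, each belonging to one of several
groups with a pre-programmed approval probability (default four groups at
87/67/33/13%).  On every trial the participant predicts whether the rater
likes them and then receives approval (1) or disapproval (0) feedback.
After every 2-3 choice trials a probe asks for a momentary self-worth
rating on a 0-1 visual-analog scale; the default design yields 75 probes
over 184 trials (one trial per rater).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TaskDesign",
    "TrialLog",
    "DesignError",
    "make_schedule",
    "probe_gap_pattern",
    "realized_approval_rate",
    "optimal_policy",
]

DEFAULT_GROUP_PROBS = (0.87, 0.67, 0.33, 0.13)


class DesignError(ValueError):
    """A task design whose constraints cannot be realized."""


@dataclass(frozen=True)
class TaskDesign:
    """Parameters of the social-evaluation task schedule.

    ``group_probs`` must be ordered from most to least approving.  In
    ``exact_frequency`` mode each group's approval count is fixed at
    round(n_group * p) (the pre-programmed schedule of the task); in
    ``bernoulli`` mode feedback is drawn independently per trial.
    """

    group_probs: tuple[float, ...] = DEFAULT_GROUP_PROBS
    n_raters: int = 184
    trials_per_rater: int = 1
    probe_cadence: tuple[int, ...] = (2, 3)
    n_probes: int = 75
    feedback_mode: str = "exact_frequency"

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.group_probs)
        object.__setattr__(self, "group_probs", probs)
        object.__setattr__(self, "probe_cadence", tuple(sorted(set(int(g) for g in self.probe_cadence))))
        if not probs:
            raise DesignError("group_probs must be non-empty")
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise DesignError(f"group_probs must lie in [0, 1], got {probs}")
        if list(probs) != sorted(probs, reverse=True):
            raise DesignError("group_probs must be ordered from most to least approving")
        if self.n_raters % len(probs) != 0:
            raise DesignError(
                f"n_raters={self.n_raters} not divisible by {len(probs)} groups"
            )
        if any(g < 1 for g in self.probe_cadence):
            raise DesignError("probe gaps must be positive integers")
        if self.feedback_mode not in ("exact_frequency", "bernoulli"):
            raise DesignError(f"unknown feedback_mode {self.feedback_mode!r}")
        if self.trials_per_rater < 1 or self.n_probes < 1:
            raise DesignError("trials_per_rater and n_probes must be >= 1")

    @property
    def n_groups(self) -> int:
        return len(self.group_probs)

    @property
    def n_trials(self) -> int:
        return self.n_raters * self.trials_per_rater

    @property
    def raters_per_group(self) -> int:
        return self.n_raters // self.n_groups


@dataclass
class TrialLog:
    """One subject's per-trial task record.

    Arrays are aligned by trial; ``trial`` is 1-based.  ``group`` holds
    0-based group indices ordered most- to least-approving.  ``choice``
    (1 = predict like, 0 = predict dislike) and ``rating`` are NaN where
    absent; ratings are present exactly on probe trials.
    """

    subject_id: str
    trial: np.ndarray
    rater_id: np.ndarray
    group: np.ndarray
    feedback: np.ndarray
    probe: np.ndarray
    choice: np.ndarray = field(default=None)  # type: ignore[assignment]
    rating: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.trial)
        self.trial = np.asarray(self.trial, dtype=int)
        self.rater_id = np.asarray(self.rater_id)
        self.group = np.asarray(self.group, dtype=int)
        self.feedback = np.asarray(self.feedback, dtype=float)
        self.probe = np.asarray(self.probe, dtype=bool)
        if self.choice is None:
            self.choice = np.full(n, np.nan)
        if self.rating is None:
            self.rating = np.full(n, np.nan)
        self.choice = np.asarray(self.choice, dtype=float)
        self.rating = np.asarray(self.rating, dtype=float)
        for name in ("rater_id", "group", "feedback", "probe", "choice", "rating"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length != {n}")
        self.validate()

    def validate(self) -> None:
        if np.any(~np.isin(self.feedback, (0.0, 1.0))):
            raise ValueError("feedback must be 0 or 1 on every trial")
        obs = np.isfinite(self.choice)
        if np.any(~np.isin(self.choice[obs], (0.0, 1.0))):
            raise ValueError("choices must be 0 or 1 where present")
        rated = np.isfinite(self.rating)
        if np.any(rated != self.probe):
            # schedules carry probe flags before any rating is simulated
            if rated.any():
                raise ValueError("ratings must be present exactly on probe trials")
        if rated.any() and (np.any(self.rating[rated] < 0) or np.any(self.rating[rated] > 1)):
            raise ValueError("self-worth ratings must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return len(self.trial)

    @property
    def n_probes(self) -> int:
        return int(self.probe.sum())

    def has_choices(self) -> bool:
        return bool(np.isfinite(self.choice).all())

    def has_ratings(self) -> bool:
        return bool(np.isfinite(self.rating[self.probe]).all()) and self.probe.any()

    def copy(self) -> "TrialLog":
        return TrialLog(
            subject_id=self.subject_id,
            trial=self.trial.copy(),
            rater_id=self.rater_id.copy(),
            group=self.group.copy(),
            feedback=self.feedback.copy(),
            probe=self.probe.copy(),
            choice=self.choice.copy(),
            rating=self.rating.copy(),
        )


def probe_gap_pattern(n_trials: int, n_probes: int, cadence: Sequence[int]) -> list[int]:
    """Deterministic sequence of gaps (choice trials between probes).

    For a two-value cadence {a, b} this solves a*x + b*y = n_trials with
    x + y = n_probes and interleaves the two gap sizes as evenly as
    possible; a single-value cadence requires an exact division.  The gap
    sequence is fixed (no randomness) so probe placement is a design
    constant, not a seed-dependent quantity.
    """
    cadence = sorted(set(int(c) for c in cadence))
    if len(cadence) == 1:
        a = cadence[0]
        if a * n_probes != n_trials:
            raise DesignError(
                f"cadence ({a},) cannot place {n_probes} probes over {n_trials} trials"
            )
        return [a] * n_probes
    if len(cadence) != 2:
        raise DesignError("probe_cadence must contain one or two gap sizes")
    a, b = cadence
    # x gaps of a, y gaps of b: a x + b y = n_trials, x + y = n_probes
    denom = b - a
    y_num = n_trials - a * n_probes
    if y_num % denom != 0:
        raise DesignError(
            f"cadence {tuple(cadence)} cannot place {n_probes} probes over {n_trials} trials"
        )
    y = y_num // denom
    x = n_probes - y
    if x < 0 or y < 0:
        raise DesignError(
            f"cadence {tuple(cadence)} cannot place {n_probes} probes over {n_trials} trials"
        )
    gaps: list[int] = []
    # interleave a/b gaps while both remain, then append the surplus
    for _ in range(min(x, y)):
        gaps.extend((a, b))
    gaps.extend([a] * (x - min(x, y)))
    gaps.extend([b] * (y - min(x, y)))
    return gaps


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_schedule(design: TaskDesign, seed: int) -> TrialLog:
    """Generate a pre-programmed task schedule (no choices or ratings yet).

    Rater order is a seeded shuffle of all raters across groups.  In
    exact_frequency mode each group's realized approval count equals
    round(n_group_trials * p_k); in bernoulli mode feedback is an
    independent draw per trial.  The same seed reproduces the schedule
    exactly.
    """
    rng = np.random.default_rng(seed)
    n_groups = design.n_groups
    per_group = design.raters_per_group
    trials_per_group = per_group * design.trials_per_rater

    rater_group = np.repeat(np.arange(n_groups), per_group)
    rater_ids = np.array(
        [f"g{g}_r{i:03d}" for g in range(n_groups) for i in range(per_group)]
    )
    # one slot per (rater, repeat)
    slot_rater = np.repeat(np.arange(design.n_raters), design.trials_per_rater)
    order = rng.permutation(len(slot_rater))
    slot_rater = slot_rater[order]
    group = rater_group[slot_rater]

    feedback = np.empty(design.n_trials)
    if design.feedback_mode == "exact_frequency":
        for g, p in enumerate(design.group_probs):
            idx = np.flatnonzero(group == g)
            n_app = _round_half_up(trials_per_group * p)
            fb = np.zeros(len(idx))
            fb[: n_app] = 1.0
            rng.shuffle(fb)
            feedback[idx] = fb
    else:
        for g, p in enumerate(design.group_probs):
            idx = np.flatnonzero(group == g)
            feedback[idx] = (rng.random(len(idx)) < p).astype(float)

    gaps = probe_gap_pattern(design.n_trials, design.n_probes, design.probe_cadence)
    probe = np.zeros(design.n_trials, dtype=bool)
    probe[np.cumsum(gaps) - 1] = True

    return TrialLog(
        subject_id="schedule",
        trial=np.arange(1, design.n_trials + 1),
        rater_id=rater_ids[slot_rater],
        group=group,
        feedback=feedback,
        probe=probe,
    )


def realized_approval_rate(log: TrialLog, group: int | None = None) -> float:
    """Fraction of approval feedback, overall or within one group."""
    if group is None:
        sel = np.ones(log.n_trials, dtype=bool)
    else:
        sel = log.group == group
    if not sel.any():
        raise ValueError(f"no trials selected (group={group})")
    return float(log.feedback[sel].mean())


def optimal_policy(design: TaskDesign) -> dict:
    """Reward-maximizing fixed policy and its expected prediction accuracy.

    The best fixed action for a group is to predict "like" iff its approval
    probability exceeds 0.5 (a tie at exactly 0.5 is scored as predicting
    "like"; accuracy is 0.5 either way).  Per-group accuracy is
    max(p, 1 - p); the overall accuracy weights groups by trial counts
    (equal under the default design).
    """
    probs = np.asarray(design.group_probs)
    actions = (probs >= 0.5).astype(int)
    per_group = np.maximum(probs, 1.0 - probs)
    weights = np.full(design.n_groups, design.raters_per_group * design.trials_per_rater)
    overall = float(np.average(per_group, weights=weights))
    return {
        "actions": tuple(int(a) for a in actions),
        "per_group_accuracy": tuple(float(a) for a in per_group),
        "overall_accuracy": overall,
    }
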