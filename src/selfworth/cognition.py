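"""Core learning models of social expectation and momentary self-worth.

Expected social value (ESV) — a running estimate of the probability that a
rater group approves — is learned by a Rescorla-Wagner delta rule: on each
trial the social prediction error SPE = feedback - ESV updates the
presented group's value by a learning rate eta.  A two-action softmax with
inverse temperature beta maps ESV to the probability of predicting "like".
Momentary self-worth is a baseline plus an exponentially decaying sum of
past SPEs: worth(t) = w0 + w1 * sum_j gamma^(t-j) SPE_j, read out (with
Gaussian measurement noise of SD sigma) on probe trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import TrialLog

__all__ = [
    "ChoiceParams",
    "SelfWorthParams",
    "LatentTrajectory",
    "init_esv",
    "esv_trajectory",
    "choice_prob",
    "selfworth_series",
    "export_modulators",
]


@dataclass(frozen=True)
class ChoiceParams:
    """Parameters of the ESV learning + softmax choice model.

    v0_hi / v0_lo are the initial ESVs of the most and least approving
    groups; interior groups start equally spaced in between.  A fit may
    return v0_lo > v0_hi (inverted initial ordering); that is flagged by
    :meth:`v0_inverted`, not rejected.
    """

    eta: float
    beta: float
    v0_hi: float
    v0_lo: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for name in ("v0_hi", "v0_lo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def v0_inverted(self) -> bool:
        return self.v0_lo > self.v0_hi


@dataclass(frozen=True)
class SelfWorthParams:
    """Parameters of the exponential-kernel self-worth model."""

    w0: float
    w1: float
    gamma: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class LatentTrajectory:
    """Model-implied per-trial series.

    ``esv`` is the presented group's value *before* feedback; ``spe`` the
    prediction error at feedback; ``esv_by_group`` the full pre-feedback
    value matrix (n_trials x n_groups).  Self-worth fields are filled by
    :func:`selfworth_series`.
    """

    esv: np.ndarray
    spe: np.ndarray
    esv_by_group: np.ndarray
    choice_prob: np.ndarray | None = None
    decayed_sum: np.ndarray | None = None
    predicted_self_worth: np.ndarray | None = None
    update: np.ndarray | None = None


def init_esv(params: ChoiceParams, n_groups: int) -> np.ndarray:
    """Initial ESV per group: v0_hi down to v0_lo, linearly interpolated."""
    if n_groups < 2:
        raise ValueError("need at least 2 rater groups")
    return np.linspace(params.v0_hi, params.v0_lo, n_groups)


def esv_trajectory(params: ChoiceParams, log: TrialLog) -> LatentTrajectory:
    """Run the delta rule over a trial log.

    Only the presented group's ESV updates on each trial; the others carry
    forward.  SPE is computed from the pre-update ESV.  With eta and all
    initial values in [0, 1] and binary feedback every ESV stays in [0, 1]
    (each update is a convex combination of the old value and the
    feedback).
    """
    n_groups = int(log.group.max()) + 1 if log.n_trials else 2
    n_groups = max(n_groups, 2)
    v = init_esv(params, n_groups).copy()
    esv = np.empty(log.n_trials)
    spe = np.empty(log.n_trials)
    by_group = np.empty((log.n_trials, n_groups))
    eta = params.eta
    groups = log.group
    feedback = log.feedback
    if np.any(~np.isin(feedback, (0.0, 1.0))):
        raise ValueError("feedback must be binary")
    for t in range(log.n_trials):
        k = groups[t]
        by_group[t] = v
        esv[t] = v[k]
        spe[t] = feedback[t] - v[k]
        v[k] += eta * spe[t]
    p_like = choice_prob(esv, params.beta)
    return LatentTrajectory(esv=esv, spe=spe, esv_by_group=by_group, choice_prob=p_like)


def choice_prob(esv: np.ndarray | float, beta: float) -> np.ndarray | float:
    """Softmax probability of predicting "like" given ESV.

    Two-action softmax over action values {esv, 1 - esv}:
    P(like) = 1 / (1 + exp(-beta * (2 esv - 1))).  beta = 0 yields
    indifference (0.5) for any ESV.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.multiply(2.0, esv) - 1.0
    return 1.0 / (1.0 + np.exp(-beta * x))


def selfworth_series(params: SelfWorthParams, trajectory: LatentTrajectory) -> LatentTrajectory:
    """Fill in the deterministic self-worth prediction for every trial.

    The decayed SPE sum follows the recursion S_t = gamma * S_{t-1} + SPE_t
    with S_0 = 0 (no pre-task history), so S_t equals the explicit kernel
    sum over all previous choice trials.  The prediction is w0 + w1 * S_t;
    measurement noise is not added here.
    """
    spe = trajectory.spe
    s = np.empty_like(spe)
    acc = 0.0
    g = params.gamma
    for t in range(len(spe)):
        acc = g * acc + spe[t]
        s[t] = acc
    trajectory.decayed_sum = s
    trajectory.predicted_self_worth = params.w0 + params.w1 * s
    trajectory.update = params.w1 * spe
    return trajectory


def export_modulators(
    choice_params: ChoiceParams,
    selfworth_params: SelfWorthParams,
    log: TrialLog,
):
    """Per-trial parametric-modulator table for event-related analyses.

    Columns: ESV at cue onset, SPE at feedback onset, the self-worth
    update w1 * SPE at feedback, and the subject's observed probe rating
    z-scored against their own probe ratings (NaN off-probe).  Rows align
    with 1-based trial indices.
    """
    import pandas as pd

    traj = esv_trajectory(choice_params, log)
    traj = selfworth_series(selfworth_params, traj)
    ratings = log.rating[log.probe]
    ratings = ratings[np.isfinite(ratings)]
    if len(ratings) < 2:
        raise ValueError("z-scoring requires at least 2 probe ratings")
    sd = ratings.std(ddof=0)
    if sd == 0:
        raise ValueError("z-scoring undefined: probe ratings have zero variance")
    rating_z = (log.rating - ratings.mean()) / sd
    return pd.DataFrame(
        {
            "trial": log.trial,
            "esv_cue": traj.esv,
            "spe_feedback": traj.spe,
            "update_feedback": traj.update,
            "rating_z": rating_z,
        }
    )
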