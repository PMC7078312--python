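"""Synthetic cohorts with a planted vulnerability dimension.

A per-subject scalar latent factor ("interpersonal vulnerability") is
drawn around a group-specific mean (recruited low self-esteem subjects sit
high, high self-esteem subjects low).  The factor generates both the
subject's model parameters (through loadings on logit/log scales, keeping
each parameter inside its bounds) and their symptom questionnaire scores,
plus independent noise — so symptoms and computational parameters co-vary
along a single dimension by construction, and a two-group cohort with the
configured group contrasts (learning-rate medians, baseline self-worth)
falls out of the same draw.

Also provides the learning-environment simulations: how fast agents with
given learning parameters develop accurate approval expectations when the
environment's average approval rate is shifted (e.g. 75% or 25% instead of
the task's 50%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cognition import ChoiceParams, SelfWorthParams, esv_trajectory, selfworth_series
from .task import TaskDesign, TrialLog, make_schedule

__all__ = [
    "SymptomProfile",
    "SYMPTOM_INSTRUMENTS",
    "CohortConfig",
    "Cohort",
    "sample_subject",
    "simulate_subject",
    "generate_cohort",
    "environment_simulation",
    "planted_factor_blocks",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# (overall base, loading per SD of vulnerability, residual noise SD, instrument range)
SYMPTOM_INSTRUMENTS: dict[str, tuple[float, float, float, tuple[float, float]]] = {
    "global_self_esteem": (21.5, -6.5, 2.0, (0.0, 30.0)),
    "fear_negative_evaluation": (2.58, 0.75, 0.5, (0.0, 5.0)),
    "rejection_sensitivity": (8.95, 2.3, 1.5, (0.0, 18.0)),
    "state_anxiety": (1.45, 0.25, 0.2, (1.0, 4.0)),
    "trait_anxiety": (2.07, 0.58, 0.25, (1.0, 4.0)),
    "social_anxiety": (0.75, 0.20, 0.3, (0.0, 3.0)),
    "depressed_mood": (13.5, 7.0, 6.0, (0.0, 66.0)),
}

# per-group parameter medians (low self-esteem group, high self-esteem group)
_PARAM_MEDIANS: dict[str, tuple[float, float]] = {
    "eta": (0.01, 0.05),
    "beta": (8.0, 8.0),
    "v0_hi": (0.70, 0.85),
    "v0_lo": (0.15, 0.30),
    "w0": (0.62, 0.80),
    "w1": (0.05, 0.03),
    "gamma": (0.40, 0.40),
    "sigma": (0.08, 0.05),
}

# loadings of the latent factor on each parameter's unconstrained scale
# (logit for probabilities, log for beta/sigma); signs follow the
# vulnerability pattern: slower learning, lower baseline worth and initial
# expectations, stronger feedback dependence, noisier ratings.
_PARAM_LOADINGS: dict[str, float] = {
    "eta": -0.50,
    "beta": 0.0,
    "v0_hi": -0.30,
    "v0_lo": -0.30,
    "w0": -0.35,
    "w1": 0.40,
    "gamma": 0.0,
    "sigma": 0.20,
}

_PARAM_NOISE_SD: dict[str, float] = {
    "eta": 0.60,
    "beta": 0.30,
    "v0_hi": 0.40,
    "v0_lo": 0.40,
    "w0": 0.25,
    "w1": 0.50,
    "gamma": 0.50,
    "sigma": 0.25,
}

_LOG_SCALE = ("beta", "sigma")  # log-normal; everything else logit-normal


@dataclass
class SymptomProfile:
    """Seven questionnaire scores for one subject."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for name, (_, _, _, (lo, hi)) in SYMPTOM_INSTRUMENTS.items():
            if name not in self.scores:
                raise ValueError(f"missing symptom score {name!r}")
            v = self.scores[name]
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside instrument range [{lo}, {hi}]")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for a two-group synthetic cohort."""

    n_low: int = 30
    n_high: int = 31
    param_medians: dict = field(default_factory=lambda: dict(_PARAM_MEDIANS))
    param_loadings: dict = field(default_factory=lambda: dict(_PARAM_LOADINGS))
    param_noise_sd: dict = field(default_factory=lambda: dict(_PARAM_NOISE_SD))
    loading_scale: float = 1.0
    symptom_noise_sd: float = 1.0
    latent_group_means: tuple[float, float] = (1.0, -1.0)  # (low-SE, high-SE)
    design: TaskDesign = field(default_factory=TaskDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 2 or self.n_high < 2:
            raise ValueError("group sizes must be >= 2")
        for name, (m_low, m_high) in self.param_medians.items():
            if name not in _LOG_SCALE:
                for m in (m_low, m_high):
                    if not 0.0 < m < 1.0:
                        raise ValueError(
                            f"median for {name} must lie in (0, 1), got {m}"
                        )
        for vals in (self.param_loadings, self.param_noise_sd):
            if any(not np.isfinite(v) for v in vals.values()):
                raise ValueError("loadings and noise SDs must be finite")


@dataclass
class Cohort:
    """Generated trial logs, symptoms and the ground truth behind them."""

    logs: list
    symptoms: pd.DataFrame
    truth: dict
    config: CohortConfig

    @property
    def subject_ids(self) -> list[str]:
        return [log.subject_id for log in self.logs]

    def group_of(self, subject_id: str) -> str:
        return self.truth[subject_id]["group"]


def sample_subject(
    config: CohortConfig, group: str, seed: int
) -> tuple[ChoiceParams, SelfWorthParams, SymptomProfile, float]:
    """Draw one subject's parameters, symptoms and latent vulnerability.

    The latent factor z is Normal(group mean, 1).  Each parameter's
    unconstrained value is its group median plus loading * (z - group
    mean) plus noise, mapped back through the logit (bounded parameters)
    or exp (beta, sigma); group medians are therefore exact medians of the
    generated distributions.  Symptoms are base + loading * z + noise,
    clipped to each instrument's range.
    """
    if group not in ("low", "high"):
        raise ValueError("group must be 'low' or 'high'")
    rng = np.random.default_rng(seed)
    gi = 0 if group == "low" else 1
    mu = config.latent_group_means[gi]
    z = float(mu + rng.standard_normal())

    vals: dict[str, float] = {}
    for name, medians in config.param_medians.items():
        med = medians[gi]
        lam = config.loading_scale * config.param_loadings.get(name, 0.0)
        tau = config.param_noise_sd.get(name, 0.0)
        shift = lam * (z - mu) + tau * rng.standard_normal()
        if name in _LOG_SCALE:
            vals[name] = math.exp(math.log(med) + shift)
        else:
            vals[name] = _expit(_logit(med) + shift)
    vals["beta"] = min(vals["beta"], 50.0)

    scores: dict[str, float] = {}
    for name, (base, lam, tau, (lo, hi)) in SYMPTOM_INSTRUMENTS.items():
        raw = base + config.loading_scale * lam * z + config.symptom_noise_sd * tau * rng.standard_normal()
        scores[name] = float(np.clip(raw, lo, hi))

    choice = ChoiceParams(eta=vals["eta"], beta=vals["beta"], v0_hi=vals["v0_hi"], v0_lo=vals["v0_lo"])
    worth = SelfWorthParams(w0=vals["w0"], w1=vals["w1"], gamma=vals["gamma"], sigma=vals["sigma"])
    return choice, worth, SymptomProfile(scores), z


def simulate_subject(
    choice_params: ChoiceParams,
    selfworth_params: SelfWorthParams,
    schedule: TrialLog,
    seed: int,
    subject_id: str | None = None,
) -> TrialLog:
    """Play the agent through a pre-programmed schedule.

    Choices are Bernoulli draws from the softmax probabilities (feedback is
    pre-programmed, so the latent trajectory does not depend on choices);
    probe ratings are the kernel-model prediction plus Gaussian noise,
    clipped to the [0, 1] rating scale.
    """
    rng = np.random.default_rng(seed)
    log = schedule.copy()
    if subject_id is not None:
        log.subject_id = subject_id
    traj = esv_trajectory(choice_params, log)
    traj = selfworth_series(selfworth_params, traj)
    log.choice = (rng.random(log.n_trials) < traj.choice_prob).astype(float)
    rating = np.full(log.n_trials, np.nan)
    probe_idx = np.flatnonzero(log.probe)
    noise = selfworth_params.sigma * rng.standard_normal(len(probe_idx))
    rating[probe_idx] = np.clip(
        traj.predicted_self_worth[probe_idx] + noise, 0.0, 1.0
    )
    log.rating = rating
    log.validate()
    return log


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full two-group cohort with retained ground truth."""
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_low + config.n_high
    child_seeds = ss.generate_state(2 * n_total) % (2**31)
    logs = []
    truth: dict[str, dict] = {}
    rows = []
    groups = ["low"] * config.n_low + ["high"] * config.n_high
    for i, group in enumerate(groups):
        sid = f"{group}_{i:03d}"
        cp, sp, prof, z = sample_subject(config, group, int(child_seeds[2 * i]))
        schedule = make_schedule(config.design, int(child_seeds[2 * i + 1]))
        log = simulate_subject(cp, sp, schedule, int(child_seeds[2 * i + 1]) + 1, subject_id=sid)
        logs.append(log)
        truth[sid] = {"group": group, "choice_params": cp, "selfworth_params": sp, "latent": z}
        rows.append({"subject_id": sid, "group": group, **prof.scores})
    return Cohort(logs=logs, symptoms=pd.DataFrame(rows), truth=truth, config=config)


def environment_simulation(
    params: ChoiceParams,
    approval_mean: float,
    horizon: int = 200,
    n_sims: int = 500,
    seed: int = 0,
    design: TaskDesign | None = None,
    accuracy_eps: float = 0.10,
) -> dict:
    """Learning-curve summaries in an approval-shifted environment.

    The four group probabilities are shifted by a constant so their mean
    equals ``approval_mean`` (clipped to [0.01, 0.99]), feedback is
    Bernoulli, and the presented group is drawn uniformly per trial.
    Reports the mean ESV per trial and group, the mean absolute gap
    |ESV - true p| averaged over groups and simulations (computed on
    pre-trial values), and the first trial at which that gap falls to
    ``accuracy_eps``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    design = design or TaskDesign()
    probs = np.asarray(design.group_probs, dtype=float)
    shifted = np.clip(probs + (approval_mean - probs.mean()), 0.01, 0.99)
    n_groups = len(shifted)

    rng = np.random.default_rng(seed)
    v0 = np.linspace(params.v0_hi, params.v0_lo, n_groups)
    v = np.tile(v0, (n_sims, 1))
    mean_esv = np.empty((horizon, n_groups))
    mean_abs_error = np.empty(horizon)
    for t in range(horizon):
        mean_esv[t] = v.mean(axis=0)
        mean_abs_error[t] = np.abs(v - shifted).mean()
        k = rng.integers(0, n_groups, size=n_sims)
        p = shifted[k]
        f = (rng.random(n_sims) < p).astype(float)
        vk = v[np.arange(n_sims), k]
        v[np.arange(n_sims), k] = vk + params.eta * (f - vk)
    below = np.flatnonzero(mean_abs_error <= accuracy_eps)
    return {
        "group_probs": shifted,
        "mean_esv": mean_esv,
        "mean_abs_error": mean_abs_error,
        "trials_to_accuracy": int(below[0]) + 1 if len(below) else None,
    }


def planted_factor_blocks(
    n: int, p: int, q: int, rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two data blocks sharing one latent factor at cross-block correlation rho.

    Each of the p (resp. q) columns loads on a common standard-normal
    factor with unit residual noise; loadings are chosen so the population
    first canonical correlation between the blocks equals rho.  Used for
    calibration studies of the dimensional analysis.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    # per-block factor correlation sqrt(rho) so the product is rho
    a = math.sqrt(rho / (p * (1.0 - rho)))
    b = math.sqrt(rho / (q * (1.0 - rho)))
    X = a * z[:, None] + rng.standard_normal((n, p))
    Y = b * z[:, None] + rng.standard_normal((n, q))
    return X, Y
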