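"""Maximum-likelihood fitting and penalized model comparison.

The choice model (delta-rule ESV + softmax) is fit by bounded multi-start
Powell optimization of the negative log-likelihood.  The self-worth model
is fit by a grid search over the forgetting factor gamma with a
closed-form least-squares solution for (w0, w1) at each grid point, which
is exact on the grid.  Model families are compared by BIC summed over
subjects, the standard complexity-penalizing surrogate for group-level
Bayesian model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cognition import ChoiceParams, LatentTrajectory, SelfWorthParams, esv_trajectory, selfworth_series
from .task import TrialLog

__all__ = [
    "ModelSpec",
    "FitResult",
    "CHOICE_BOUNDS",
    "choice_nll",
    "pseudo_r2",
    "selfworth_nll",
    "fit_choice_model",
    "fit_selfworth_model",
    "compare_models",
    "model_free_feedback_effect",
    "bic",
]

PROB_FLOOR = 1e-12
CHOICE_BOUNDS = {"eta": (0.0, 1.0), "beta": (0.0, 50.0), "v0_hi": (0.0, 1.0), "v0_lo": (0.0, 1.0)}

CHOICE_VARIANTS = ("full", "no_learning")
SELFWORTH_VARIANTS = ("full", "no_spe", "no_decay")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family under comparison.

    ``no_learning`` freezes eta at 0 (static expectations); ``no_spe``
    freezes w1 at 0 (self-worth untouched by feedback); ``no_decay``
    freezes gamma at 0 (only the latest SPE matters).  Frozen parameters
    are excluded from the free-parameter counts.
    """

    name: str
    choice_variant: str = "full"
    selfworth_variant: str | None = "full"

    def __post_init__(self) -> None:
        if self.choice_variant not in CHOICE_VARIANTS:
            raise ValueError(f"unknown choice variant {self.choice_variant!r}")
        if self.selfworth_variant is not None and self.selfworth_variant not in SELFWORTH_VARIANTS:
            raise ValueError(f"unknown self-worth variant {self.selfworth_variant!r}")

    @property
    def k_choice(self) -> int:
        return 4 if self.choice_variant == "full" else 3

    @property
    def k_selfworth(self) -> int:
        if self.selfworth_variant is None:
            return 0
        # sigma is a fitted scale parameter and counts as free
        return {"full": 4, "no_spe": 2, "no_decay": 3}[self.selfworth_variant]

    @property
    def k(self) -> int:
        return self.k_choice + self.k_selfworth


@dataclass
class FitResult:
    """Estimated parameters with likelihood-based fit indices."""

    params: dict
    nll: float
    n_obs: int
    k: int
    bic: float
    aic: float
    pseudo_r2: float | None = None
    r2: float | None = None
    n_restarts_converged: int = 0
    best_restart_seed: int | None = None
    flags: list = field(default_factory=list)

    @property
    def choice_params(self) -> ChoiceParams:
        return ChoiceParams(
            eta=self.params["eta"], beta=self.params["beta"],
            v0_hi=self.params["v0_hi"], v0_lo=self.params["v0_lo"],
        )

    @property
    def selfworth_params(self) -> SelfWorthParams:
        return SelfWorthParams(
            w0=self.params["w0"], w1=self.params["w1"],
            gamma=self.params["gamma"], sigma=self.params["sigma"],
        )


def bic(nll: float, k: int, n_obs: int) -> float:
    return 2.0 * nll + k * math.log(n_obs)


def _choice_nll_core(
    eta: float, beta: float, v0: list[float],
    groups: list[int], feedback: list[float], choices: list[float],
) -> float:
    """Plain-float inner loop; avoids numpy overhead at ~200 trials."""
    v = list(v0)
    nll = 0.0
    for k_t, f_t, c_t in zip(groups, feedback, choices):
        esv = v[k_t]
        p_like = 1.0 / (1.0 + math.exp(-beta * (2.0 * esv - 1.0)))
        p = p_like if c_t == 1.0 else 1.0 - p_like
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        nll -= math.log(p)
        v[k_t] = esv + eta * (f_t - esv)
    return nll


def _log_arrays(log: TrialLog) -> tuple[list[int], list[float], list[float], int]:
    if not log.has_choices():
        raise ValueError("trial log is missing choices")
    n_groups = max(int(log.group.max()) + 1, 2)
    return (
        [int(g) for g in log.group],
        [float(f) for f in log.feedback],
        [float(c) for c in log.choice],
        n_groups,
    )


def choice_nll(params: ChoiceParams, log: TrialLog) -> float:
    """Negative log-likelihood of observed predictions under the model.

    Per-trial choice probabilities are floored at 1e-12 before taking
    logs so deterministic agents evaluated off their argmax do not yield
    infinite values.
    """
    groups, feedback, choices, n_groups = _log_arrays(log)
    v0 = list(np.linspace(params.v0_hi, params.v0_lo, n_groups))
    return _choice_nll_core(params.eta, params.beta, v0, groups, feedback, choices)


def pseudo_r2(nll: float, n_trials: int) -> float:
    """Likelihood-ratio pseudo-r^2 against the two-action chance baseline."""
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    return 1.0 - nll / (n_trials * math.log(2.0))


def selfworth_nll(params: SelfWorthParams, log: TrialLog, trajectory: LatentTrajectory) -> float:
    """Gaussian negative log-likelihood of probe ratings around the model mean."""
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    traj = selfworth_series(params, trajectory)
    mask = log.probe & np.isfinite(log.rating)
    if mask.sum() < 2:
        raise ValueError("need at least 2 probe ratings")
    resid = log.rating[mask] - traj.predicted_self_worth[mask]
    n = len(resid)
    return 0.5 * float(np.sum(resid**2)) / params.sigma**2 + n * math.log(
        params.sigma * math.sqrt(2.0 * math.pi)
    )


def fit_choice_model(
    log: TrialLog,
    spec: ModelSpec | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit the choice model by bounded multi-start Powell search.

    Starts are drawn uniformly within the parameter bounds from a seeded
    generator; the best of ``n_restarts`` local optima is returned, so the
    result is deterministic given the seed.
    """
    spec = spec or ModelSpec("choice_full")
    groups, feedback, choices, n_groups = _log_arrays(log)
    n = len(groups)
    freeze_eta = spec.choice_variant == "no_learning"

    names = (["beta", "v0_hi", "v0_lo"] if freeze_eta else ["eta", "beta", "v0_hi", "v0_lo"])
    bounds = [CHOICE_BOUNDS[nm] for nm in names]

    def objective(x: np.ndarray) -> float:
        vals = dict(zip(names, x))
        eta = 0.0 if freeze_eta else vals["eta"]
        v0 = list(np.linspace(vals["v0_hi"], vals["v0_lo"], n_groups))
        return _choice_nll_core(eta, vals["beta"], v0, groups, feedback, choices)

    rng = np.random.default_rng(seed)
    best = None
    best_seed = None
    n_converged = 0
    failures = []
    for i in range(n_restarts):
        x0 = np.array([lo + (hi - lo) * rng.random() for lo, hi in bounds])
        try:
            res = optimize.minimize(
                objective, x0, method="Powell", bounds=bounds,
                options={"xtol": 1e-6, "ftol": 1e-6, "maxiter": 2000},
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        n_converged += 1
        if best is None or res.fun < best.fun:
            best, best_seed = res, i
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures[:3]}")

    vals = dict(zip(names, best.x))
    params = {
        "eta": 0.0 if freeze_eta else float(vals["eta"]),
        "beta": float(vals["beta"]),
        "v0_hi": float(vals["v0_hi"]),
        "v0_lo": float(vals["v0_lo"]),
    }
    nll = float(best.fun)
    k = spec.k_choice
    result = FitResult(
        params=params, nll=nll, n_obs=n, k=k,
        bic=bic(nll, k, n), aic=2.0 * nll + 2.0 * k,
        pseudo_r2=pseudo_r2(nll, n),
        n_restarts_converged=n_converged, best_restart_seed=best_seed,
    )
    if params["v0_lo"] > params["v0_hi"]:
        result.flags.append("v0_inverted")
    return result


def _kernel_sums(spe: np.ndarray, gamma: float) -> np.ndarray:
    s = np.empty_like(spe)
    acc = 0.0
    for t in range(len(spe)):
        acc = gamma * acc + spe[t]
        s[t] = acc
    return s


def fit_selfworth_model(
    log: TrialLog,
    trajectory: LatentTrajectory,
    spec: ModelSpec | None = None,
    gamma_grid: np.ndarray | None = None,
) -> FitResult:
    """Fit the self-worth kernel model by gamma-grid least squares.

    For each gamma on a 0.01-step grid the decayed SPE sum at probe trials
    is a fixed regressor, so (w0, w1) have a closed-form OLS solution and
    the grid minimum is exact.  sigma is the maximum-likelihood residual
    SD.  Ratings with zero variance fall back to w1 = 0 with r^2 = 0 (the
    degenerate-variance convention).
    """
    spec = spec or ModelSpec("selfworth_full")
    mask = log.probe & np.isfinite(log.rating)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 probe ratings")
    y = log.rating[mask]
    spe = trajectory.spe

    variant = spec.selfworth_variant or "full"
    if gamma_grid is None:
        gamma_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    if variant == "no_decay":
        gamma_grid = np.array([0.0])

    sst = float(np.sum((y - y.mean()) ** 2))
    flags: list[str] = []

    if variant == "no_spe":
        w0 = float(y.mean())
        w1, gamma = 0.0, 0.0
        sse = sst
        r2 = 0.0 if sst == 0 else 0.0  # no regressor: r2 vs mean is 0 by definition
    elif sst == 0.0:
        w0, w1, gamma = float(y.mean()), 0.0, 0.0
        sse, r2 = 0.0, 0.0
        flags.append("constant_ratings")
    else:
        best = None
        for g in gamma_grid:
            s = _kernel_sums(spe, float(g))[mask]
            sx = s - s.mean()
            denom = float(np.sum(sx**2))
            if denom == 0.0:
                b1 = 0.0
            else:
                b1 = float(np.sum(sx * (y - y.mean())) / denom)
            b0 = float(y.mean() - b1 * s.mean())
            sse_g = float(np.sum((y - b0 - b1 * s) ** 2))
            if best is None or sse_g < best[0]:
                best = (sse_g, b0, b1, float(g))
        sse, w0, w1, gamma = best
        r2 = 1.0 - sse / sst

    sigma = math.sqrt(max(sse / n, 1e-12))
    nll = 0.5 * sse / sigma**2 + n * math.log(sigma * math.sqrt(2.0 * math.pi))
    k = spec.k_selfworth or 4
    params = {"w0": w0, "w1": w1, "gamma": gamma, "sigma": sigma}
    return FitResult(
        params=params, nll=nll, n_obs=n, k=k,
        bic=bic(nll, k, n), aic=2.0 * nll + 2.0 * k,
        r2=r2, flags=flags,
    )


def _fit_subject(log: TrialLog, spec: ModelSpec, n_restarts: int, seed: int) -> dict:
    out: dict = {"subject_id": log.subject_id, "spec": spec.name}
    choice_fit = fit_choice_model(log, spec, n_restarts=n_restarts, seed=seed)
    out["choice"] = choice_fit
    total_nll, total_bic, k = choice_fit.nll, choice_fit.bic, choice_fit.k
    if spec.selfworth_variant is not None and log.has_ratings():
        traj = esv_trajectory(choice_fit.choice_params, log)
        sw_fit = fit_selfworth_model(log, traj, spec)
        out["selfworth"] = sw_fit
        total_nll += sw_fit.nll
        total_bic += sw_fit.bic
        k += sw_fit.k
    out.update(nll=total_nll, bic=total_bic, k=k)
    return out


def compare_models(
    logs: list[TrialLog],
    specs: list[ModelSpec],
    n_restarts: int = 20,
    seed: int = 0,
):
    """Per-subject fits and BIC summed over subjects for each model spec.

    The spec with the lowest summed BIC wins; ties break toward fewer free
    parameters.  Fit failures are recorded per subject and excluded from
    the sums of every spec (so sums stay comparable).
    """
    import pandas as pd

    if not logs:
        raise ValueError("need at least 1 subject")
    if not specs:
        raise ValueError("need at least 1 model spec")
    rows = []
    failures = []
    for i, log in enumerate(logs):
        for spec in specs:
            try:
                fit = _fit_subject(log, spec, n_restarts, seed + i)
            except Exception as exc:
                failures.append({"subject_id": log.subject_id, "spec": spec.name, "error": str(exc)})
                continue
            choice_fit = fit["choice"]
            rows.append(
                {
                    "subject_id": log.subject_id,
                    "spec": spec.name,
                    "nll": fit["nll"],
                    "k": fit["k"],
                    "bic": fit["bic"],
                    "pseudo_r2": choice_fit.pseudo_r2,
                    "r2": fit["selfworth"].r2 if "selfworth" in fit else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    failed_subjects = {f["subject_id"] for f in failures}
    ok = table[~table.subject_id.isin(failed_subjects)]
    summed = (
        ok.groupby("spec", sort=False)
        .agg(total_bic=("bic", "sum"), k=("k", "first"), n_subjects=("subject_id", "nunique"))
        .reset_index()
    )
    summed = summed.sort_values(["total_bic", "k"], kind="stable").reset_index(drop=True)
    winner = str(summed.iloc[0]["spec"])
    return {"table": table, "summary": summed, "winner": winner, "failures": failures}


def model_free_feedback_effect(log: TrialLog) -> dict:
    """Slope of self-worth change on recent feedback valence, model-free.

    For each probe after the first, the rating change from the previous
    probe is regressed on the mean feedback valence (+1 approval, -1
    disapproval) of the choice trials since that probe.  A positive slope
    means approval lifts reported self-worth.  Undefined (flagged) when
    feedback valence never varies across intervals.
    """
    mask = log.probe & np.isfinite(log.rating)
    idx = np.flatnonzero(mask)
    if len(idx) < 5:
        raise ValueError("need at least 5 probe ratings")
    valence = 2.0 * log.feedback - 1.0
    x, dy = [], []
    for prev, cur in zip(idx[:-1], idx[1:]):
        x.append(valence[prev + 1 : cur + 1].mean())
        dy.append(log.rating[cur] - log.rating[prev])
    x = np.asarray(x)
    dy = np.asarray(dy)
    if np.allclose(x, x[0]):
        return {"coefficient": np.nan, "defined": False, "n_intervals": len(x)}
    xc = x - x.mean()
    slope = float(np.sum(xc * (dy - dy.mean())) / np.sum(xc**2))
    return {"coefficient": slope, "defined": True, "n_intervals": len(x)}
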