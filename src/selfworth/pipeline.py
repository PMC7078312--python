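"""End-to-end orchestration: simulate -> fit -> compare -> CCA.

Every stage is deterministic given the seeds in the configuration; the
report bundle records a configuration hash and all seeds so a rerun with
the same configuration reproduces the deterministic artifacts exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cognition import esv_trajectory
from .cohort import Cohort, CohortConfig, generate_cohort
from .fitting import ModelSpec, compare_models, fit_choice_model, fit_selfworth_model
from .vulnerability import cca_fit, sequential_dimension_tests, vulnerability_scores
from . import io as sw_io

__all__ = [
    "PipelineConfig",
    "PARAM_COLUMNS",
    "fit_cohort",
    "recovery_report",
    "cca_stage",
    "run_pipeline",
    "DEFAULT_SPECS",
]

PARAM_COLUMNS = ["eta", "beta", "v0_hi", "v0_lo", "w0", "w1", "gamma", "sigma"]

DEFAULT_SPECS = (
    ModelSpec("full", "full", "full"),
    ModelSpec("no_learning", "no_learning", "full"),
    ModelSpec("no_spe", "full", "no_spe"),
    ModelSpec("no_decay", "full", "no_decay"),
)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_restarts: int = 20
    fit_seed: int = 0
    specs: tuple = DEFAULT_SPECS
    compare_restarts: int = 10
    cca_param_columns: tuple = tuple(PARAM_COLUMNS)
    out_dir: str | None = None

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def fit_cohort(cohort: Cohort, n_restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fit the full choice + self-worth model to every subject.

    Fitting is sequential: the choice model is fit first and its implied
    SPE series feeds the self-worth kernel fit.  Returns one row per
    subject with fitted parameters, fit indices and the fitted model's
    choice accuracy (fraction of observed choices matching the model's
    argmax prediction).
    """
    rows = []
    for i, log in enumerate(cohort.logs):
        cfit = fit_choice_model(log, ModelSpec("full"), n_restarts=n_restarts, seed=seed + i)
        traj = esv_trajectory(cfit.choice_params, log)
        pred = (traj.choice_prob >= 0.5).astype(float)
        accuracy = float((pred == log.choice).mean())
        sfit = fit_selfworth_model(log, traj)
        rows.append(
            {
                "subject_id": log.subject_id,
                "group": cohort.group_of(log.subject_id),
                **cfit.params,
                **sfit.params,
                "choice_accuracy": accuracy,
                "pseudo_r2": cfit.pseudo_r2,
                "r2": sfit.r2,
                "choice_nll": cfit.nll,
                "selfworth_nll": sfit.nll,
                "n_restarts_converged": cfit.n_restarts_converged,
                "mean_rating": float(np.nanmean(log.rating)),
            }
        )
    return pd.DataFrame(rows)


def recovery_report(cohort: Cohort, fits: pd.DataFrame) -> pd.DataFrame:
    """True-vs-fitted correlations per parameter (Pearson and Spearman)."""
    rows = []
    for name in PARAM_COLUMNS:
        holder = "choice_params" if name in ("eta", "beta", "v0_hi", "v0_lo") else "selfworth_params"
        true = np.array([getattr(cohort.truth[s][holder], name) for s in fits.subject_id])
        fitted = fits[name].to_numpy()
        rows.append(
            {
                "parameter": name,
                "pearson_r": float(stats.pearsonr(true, fitted)[0]),
                "spearman_rho": float(stats.spearmanr(true, fitted)[0]),
                "true_median": float(np.median(true)),
                "fitted_median": float(np.median(fitted)),
            }
        )
    return pd.DataFrame(rows)


def cca_stage(symptoms: pd.DataFrame, fits: pd.DataFrame, param_columns=tuple(PARAM_COLUMNS)) -> dict:
    """Run the vulnerability CCA on symptom and fitted-parameter blocks."""
    merged = symptoms.merge(fits[["subject_id", *param_columns]], on="subject_id")
    symptom_cols = [c for c in symptoms.columns if c not in ("subject_id", "group")]
    result = cca_fit(merged[symptom_cols], merged[list(param_columns)])
    groups = merged["group"] if "group" in merged.columns else None
    scores = vulnerability_scores(result, groups=groups)
    return {
        "result": result,
        "scores": scores,
        "dimension_tests": sequential_dimension_tests(result),
        "subject_ids": merged["subject_id"].tolist(),
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> fit -> compare -> cca and return the report bundle.

    A stage failure raises :class:`StageError` naming the stage; partial
    outputs written so far are retained.  If ``config.out_dir`` is set,
    artifacts are written there as CSV/JSON.
    """
    bundle: dict = {
        "config_hash": config.config_hash(),
        "seeds": {"cohort": config.cohort.seed, "fit": config.fit_seed},
    }
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = generate_cohort(config.cohort)
        bundle["cohort"] = cohort
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    if out:
        sw_io.write_trials(cohort.logs, out / "trials.csv")
        sw_io.write_symptoms(cohort.symptoms, out / "symptoms.csv")

    try:
        fits = fit_cohort(cohort, n_restarts=config.n_restarts, seed=config.fit_seed)
        bundle["fits"] = fits
        bundle["recovery"] = recovery_report(cohort, fits)
    except Exception as exc:
        raise StageError("fit", exc) from exc
    if out:
        fits.to_csv(out / "fits.csv", index=False)
        bundle["recovery"].to_csv(out / "recovery.csv", index=False)

    try:
        comparison = compare_models(
            cohort.logs, list(config.specs),
            n_restarts=config.compare_restarts, seed=config.fit_seed,
        )
        bundle["comparison"] = comparison
    except Exception as exc:
        raise StageError("compare", exc) from exc
    if out:
        comparison["summary"].to_csv(out / "comparison.csv", index=False)

    try:
        cca = cca_stage(cohort.symptoms, fits, config.cca_param_columns)
        bundle["cca"] = cca
    except Exception as exc:
        raise StageError("cca", exc) from exc
    if out:
        result = cca["result"]
        scores = cca["scores"]
        payload = {
            "config_hash": bundle["config_hash"],
            "seeds": bundle["seeds"],
            "canonical_correlations": result.canonical_correlations.tolist(),
            "wilks_lambda": result.wilks_lambda,
            "f_stat": result.f_stat,
            "df": list(result.df),
            "p_value": result.p_value,
            "x_coef_dim1": dict(zip(result.x_names, result.x_coef[:, 0].tolist())),
            "y_coef_dim1": dict(zip(result.y_names, result.y_coef[:, 0].tolist())),
            "within_group_correlation": scores.get("within_group_correlation"),
        }
        (out / "cca.json").write_text(json.dumps(payload, indent=2) + "\n")
        pd.DataFrame(
            {
                "subject_id": cca["subject_ids"],
                "symptom_score": scores["symptom_scores"],
                "parameter_score": scores["parameter_scores"],
            }
        ).to_csv(out / "scores.csv", index=False)
    return bundle
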