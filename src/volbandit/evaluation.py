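"""Accuracy, model validation and recovery reporting.

Accuracy follows the schedule-aware definition: a response is correct
when it selects the option the generative reward schedule currently
favours (p > 0.5), regardless of the realised outcome.  Model validation
compares model-derived values of chosen versus unchosen options and
juxtaposes running-average choice curves of data against simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import ModelParams, run_model
from .task import STABLE, VOLATILE, SessionRecord, TaskSchedule


def accuracy(choices: np.ndarray, reward_schedule: TaskSchedule) -> dict[str, float]:
    """Proportion of schedule-correct responses, overall and by phase.

    Trials with p = 0.5 have no correct option and are excluded from the
    denominator.
    """
    choices = np.asarray(choices, dtype=int)
    p = reward_schedule.per_trial_p
    defined = p != 0.5
    correct = (choices == (p > 0.5).astype(int)) & defined
    labels = reward_schedule.per_trial_volatility
    out = {"overall": float(correct[defined].mean()) if defined.any() else np.nan}
    for vol in (STABLE, VOLATILE):
        m = defined & (labels == vol)
        out[vol] = float(correct[m].mean()) if m.any() else np.nan
    return out


def chosen_vs_unchosen(
    params: ModelParams,
    sessions: Sequence[tuple] | SessionRecord,
) -> tuple[float, float]:
    """Mean model value of chosen and of unchosen options across sessions.

    The blue option's value on trial i is the integrated value vB; the
    green option's is 1 - vB, so the two per-trial values always sum to 1.
    """
    if isinstance(sessions, SessionRecord):
        sessions = [sessions]
    chosen, unchosen = [], []
    for item in sessions:
        if isinstance(item, SessionRecord):
            trials, reward, advice = item.trials, item.reward_schedule, item.advice_schedule
        else:
            trials, reward, advice = item
        if trials.choice is None:
            raise ValueError("chosen_vs_unchosen requires observed choices")
        trace = run_model(params, trials, reward, advice)
        vb = trace.vb
        c = np.where(trials.choice == 1, vb, 1.0 - vb)
        chosen.append(c)
        unchosen.append(1.0 - c)
    return float(np.mean(np.concatenate(chosen))), float(np.mean(np.concatenate(unchosen)))


def running_average(series: np.ndarray, window: int = 5, mode: str = "trailing") -> np.ndarray:
    """Moving mean with edge handling by available samples.

    ``trailing`` (default) averages the current and previous window-1
    samples, avoiding future leakage; ``centered`` matches typical figure
    smoothing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if mode == "trailing":
        return s.rolling(window, min_periods=1).mean().to_numpy()
    if mode == "centered":
        return s.rolling(window, min_periods=1, center=True).mean().to_numpy()
    raise ValueError(f"mode must be 'trailing' or 'centered', got {mode!r}")


def recovery_report(
    true_params: Sequence[ModelParams],
    fitted_params: Sequence[ModelParams],
) -> pd.DataFrame:
    """Per-parameter bias, RMSE and Spearman correlation of recovery."""
    from .optimal import PARAM_FIELDS

    if len(true_params) != len(fitted_params):
        raise ValueError("true/fitted lengths differ")
    rows = []
    for name in PARAM_FIELDS:
        t = np.array([getattr(p, name) for p in true_params], dtype=float)
        f = np.array([getattr(p, name) for p in fitted_params], dtype=float)
        err = f - t
        rho = spearmanr(t, f).statistic if len(t) > 2 and np.std(t) > 0 else np.nan
        rows.append(
            {
                "parameter": name,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "spearman_rho": float(rho) if rho == rho else np.nan,
                "flagged": bool(rho == rho and rho <= 0),
                "n": len(t),
            }
        )
    return pd.DataFrame(rows)


def model_recovery_confusion(
    generator_labels: Sequence[str],
    selected_labels: Sequence[str],
    models: Sequence[str] = ("M1", "M2", "M3"),
) -> pd.DataFrame:
    """Confusion matrix: rows = generating model, columns = selected model."""
    mat = pd.DataFrame(0, index=list(models), columns=list(models))
    for g, s in zip(generator_labels, selected_labels, strict=True):
        mat.loc[g, s] += 1
    mat.index.name = "generated"
    mat.columns.name = "selected"
    return mat


def parameter_recovery_study(
    n_subjects: int = 60,
    seed: int = 0,
    variant: str = "M3",
    params_distribution: dict | None = None,
) -> dict:
    """Simulate a cohort at spread parameter values and refit each subject
    jointly over their two sessions.

    Returns a dict with the per-parameter recovery table ("report"), the
    true and fitted parameter lists, and the generated and recovered
    group-mean volatile-stable learning-rate differences.
    """
    from .inference import fit_map
    from .task import CohortSpec, make_cohort

    spec = CohortSpec(n_subjects=n_subjects, seed=seed,
                      params_distribution=params_distribution or {})
    by_subject: dict[int, list] = {}
    for rec in make_cohort(spec):
        by_subject.setdefault(rec.subject_id, []).append(rec)
    true_list, fitted_list = [], []
    for subj, recs in sorted(by_subject.items()):
        fit = fit_map(recs, variant=variant)
        true_list.append(recs[0].true_params)
        fitted_list.append(fit.map_params)

    def _vol_minus_stable(params_list, ltype):
        return float(np.mean([
            getattr(p, f"alpha_volatile_{ltype}") - getattr(p, f"alpha_stable_{ltype}")
            for p in params_list
        ]))

    return {
        "report": recovery_report(true_list, fitted_list),
        "true_params": true_list,
        "fitted_params": fitted_list,
        "generated_diff": {lt: _vol_minus_stable(true_list, lt)
                           for lt in ("experienced", "inferred")},
        "recovered_diff": {lt: _vol_minus_stable(fitted_list, lt)
                           for lt in ("experienced", "inferred")},
    }


def _jittered_generator_params(variant: str, rng: np.random.Generator) -> ModelParams:
    # discriminable generating conditions: M2 separates phases, M3 crosses
    # experienced/inferred so M2's equality constraint is violated
    beta = float(np.clip(4.0 + rng.normal(0, 0.5), 2.0, 8.0))
    zeta = float(np.clip(0.5 + rng.normal(0, 0.05), 0.3, 0.7))
    lo = lambda: float(np.clip(0.15 + rng.normal(0, 0.03), 0.03, 0.9))
    hi = lambda: float(np.clip(0.52 + rng.normal(0, 0.05), 0.05, 0.95))
    if variant == "M1":
        a = float(np.clip(0.30 + rng.normal(0, 0.05), 0.05, 0.9))
        return ModelParams.m1(a, beta, zeta)
    if variant == "M2":
        return ModelParams.m2(lo(), hi(), beta, zeta)
    return ModelParams(lo(), hi(), hi(), lo(), beta, zeta)


def model_recovery_study(
    n_subjects_per_generator: int = 20,
    seed: int = 0,
    variants: Sequence[str] = ("M1", "M2", "M3"),
    n_sessions: int = 2,
) -> pd.DataFrame:
    """Simulate data under each model variant, fit all variants, and
    select per subject by Laplace log evidence.

    Returns the confusion matrix (rows = generating model, columns =
    selected model).  Generating parameters are jittered around fixed
    discriminable values; schedules cycle the four canonical layouts.
    """
    from . import task
    from .inference import fit_map, log_model_evidence

    rng = np.random.default_rng(seed)
    gen_labels, sel_labels = [], []
    for gen_variant in variants:
        for s in range(n_subjects_per_generator):
            params = _jittered_generator_params(gen_variant, rng)
            reward, advice_sched = task.canonical_schedules(1 + s % 4)
            sessions = []
            for _ in range(n_sessions):
                outcomes = task.generate_outcomes(reward, rng=rng)
                advice, _ = task.generate_advice(advice_sched, outcomes, rng=rng)
                trials = task.simulate_agent(params, reward, advice_sched,
                                             outcomes, advice, rng=rng)
                sessions.append((trials, reward, advice_sched))
            evidences = []
            for fit_variant in variants:
                fit = fit_map(sessions, variant=fit_variant)
                fit = log_model_evidence(fit, sessions)
                evidences.append(fit.log_evidence)
            gen_labels.append(gen_variant)
            sel_labels.append(variants[int(np.argmax(evidences))])
    return model_recovery_confusion(gen_labels, sel_labels, models=variants)


@dataclass
class ValidationReport:
    """Chosen/unchosen model values plus data-vs-simulation choice curves."""

    mean_chosen: float
    mean_unchosen: float
    data_curve: np.ndarray
    sim_curve: np.ndarray
    accuracy_data: dict[str, float]
    accuracy_sim: dict[str, float]


def validate_fit(
    params: ModelParams,
    record: SessionRecord,
    window: int = 5,
    seed: int | None = 0,
    mode: str = "trailing",
) -> ValidationReport:
    """Simulate the fitted model on the session's schedule and compare
    running-average blue-choice curves and accuracy with the data."""
    from .task import simulate_agent

    mean_c, mean_u = chosen_vs_unchosen(params, record)
    sim = simulate_agent(
        params, record.reward_schedule, record.advice_schedule,
        record.trials.outcome, record.trials.advice, seed=seed,
    )
    return ValidationReport(
        mean_chosen=mean_c,
        mean_unchosen=mean_u,
        data_curve=running_average(record.trials.choice, window, mode),
        sim_curve=running_average(sim.choice, window, mode),
        accuracy_data=accuracy(record.trials.choice, record.reward_schedule),
        accuracy_sim=accuracy(sim.choice, record.reward_schedule),
    )
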