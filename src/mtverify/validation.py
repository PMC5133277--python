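"""Simulation studies validating the generator-analysis loop.

These harnesses close the loop between the synthetic-experiment generator
and the inference machinery: type-I error calibration of the interaction
test under a null generator, confidence-interval coverage for known
generator coefficients, conflict-sweep monotonicity of the trajectory
measures, and the qualitative condition-cell ordering.  Study sizes default
to 16 participants x 40 trials (a 40-scene bank), a scale at which a full
calibration run completes in minutes; coverage and calibration are
size-invariant properties, so the small scale does not change what a pass
means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design
from .contrasts import code_vector
from .inference import fit_accuracy_glmm, fit_lmm_maximal
from .measures import auc, measure_trials, summarize_cells, xflips
from .preprocess import canonicalize, filter_rt_outliers, preprocess_trials
from .simulate import (
    ScreenGeometry,
    SimulationParams,
    simulate_experiment,
    simulate_trajectory,
)

#: Generator with every condition effect and random variance switched off
#: (accuracy saturated so the correctness restriction removes nothing).
NULL_PARAMS = SimulationParams(
    beta_conflict=(11.0, 0, 0, 0, 0, 0, 0, 0),
    beta_accuracy=(50.0, 0, 0, 0, 0, 0, 0, 0),
    beta_rt_s=(0.0, 0, 0, 0, 0, 0, 0, 0),
    participant_sd=0.0,
    scene_sd=0.0,
    rt_participant_sd_s=0.0,
    rt_scene_sd_s=0.0,
)


def small_design(
    n_scenes: int = 40,
    n_participants: int = 16,
    per_participant: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """A reduced replica of the full design used by the simulation studies."""
    bank = design.build_item_bank(n_scenes)
    lists = design.build_latin_lists(bank, 4, seed=seed)
    return design.build_schedules(lists, n_participants, per_participant, seed=seed)


def _batched_trials(
    params: SimulationParams, n_sims: int, seed: int, *, correct_only: bool = True
) -> pd.DataFrame:
    schedules = small_design(seed=seed)
    frames = []
    for i in range(n_sims):
        trials, _ = simulate_experiment(schedules, params, seed=seed + 1 + i)
        if correct_only:
            retained, _ = preprocess_trials(trials, k=4.0)
        else:
            retained, _ = filter_rt_outliers(trials, k=4.0)
        retained = retained.copy()
        retained["sim"] = i
        frames.append(retained)
    return pd.concat(frames, ignore_index=True)


def type1_error_study(
    n_sims: int = 200,
    *,
    term: str = "Plausibility:Congruency",
    response: str = "rt_s",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the interaction test under the null generator.

    Every fixed effect and every random variance in the generator is zero,
    so the nominal rate is ``alpha``; each simulated experiment runs through
    the standard exclusion rules before the maximal model is fit.
    """
    data = _batched_trials(NULL_PARAMS, n_sims, seed)
    fits = fit_lmm_maximal(data, response, batch="sim")
    pvals = np.array([f.coef(term)["p"] for f in fits])
    return {
        "n_sims": n_sims,
        "alpha": alpha,
        "rejections": int((pvals < alpha).sum()),
        "type1_error": float((pvals < alpha).mean()),
        "p_values": pvals,
    }


def rt_recovery_study(
    n_reps: int = 100,
    *,
    true_interaction: float = -0.06,
    seed: int = 0,
) -> dict:
    """CI coverage of a known RT plausibility x congruency effect.

    The generator adds ``true_interaction`` seconds through the interaction
    term of the dwell model, keeps the conflict pull condition-independent
    (so movement time carries no condition signal) and saturates accuracy;
    the fitted maximal model's 95% Wald CI should cover the truth at its
    nominal rate.
    """
    params = SimulationParams(
        beta_conflict=(11.0, 0, 0, 0, 0, 0, 0, 0),
        beta_accuracy=(50.0, 0, 0, 0, 0, 0, 0, 0),
        beta_rt_s=(0.0, 0, 0, 0, true_interaction, 0, 0, 0),
    )
    data = _batched_trials(params, n_reps, seed)
    fits = fit_lmm_maximal(data, "rt_s", batch="sim")
    rows = [f.coef("Plausibility:Congruency") for f in fits]
    est = np.array([r["beta"] for r in rows])
    se = np.array([r["se"] for r in rows])
    covered = np.abs(est - true_interaction) <= 1.959964 * se
    return {
        "n_reps": n_reps,
        "true_value": true_interaction,
        "coverage": float(covered.mean()),
        "sign_negative": float((est < 0).mean()),
        "estimates": est,
    }


def accuracy_recovery_study(
    n_reps: int = 100,
    *,
    true_intercept: float = 2.87,
    seed: int = 0,
) -> dict:
    """CI coverage of a known accuracy-logit intercept.

    The generator draws correctness from ``logistic(true_intercept + u_p +
    u_s)`` with no condition effects; the binomial GLMM (random intercepts)
    should cover the conditional intercept at its nominal 95% rate, and the
    implied mean accuracy is ``logistic(true_intercept)`` (~0.95).
    """
    params = SimulationParams(
        beta_conflict=(11.0, 0, 0, 0, 0, 0, 0, 0),
        beta_accuracy=(true_intercept, 0, 0, 0, 0, 0, 0, 0),
        beta_rt_s=(0.0, 0, 0, 0, 0, 0, 0, 0),
        participant_sd=0.5,
        scene_sd=0.3,
    )
    data = _batched_trials(params, n_reps, seed, correct_only=False)
    fits = fit_accuracy_glmm(data, batch="sim")
    rows = [f.coef("Intercept") for f in fits]
    est = np.array([r["beta"] for r in rows])
    se = np.array([r["se"] for r in rows])
    covered = np.abs(est - true_intercept) <= 1.959964 * se
    return {
        "n_reps": n_reps,
        "true_value": true_intercept,
        "coverage": float(covered.mean()),
        "mean_accuracy": float(data["correct"].mean()),
        "estimates": est,
    }


def conflict_sweep(
    lams: tuple[float, ...] = (0.0, 2.0, 4.0),
    n_reps: int = 200,
    *,
    motor_noise_px: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC and x-flips of replicate trajectories across fixed pull strengths."""
    geometry = ScreenGeometry()
    params = SimulationParams(motor_noise_px=motor_noise_px)
    codes = code_vector("plausible", "congruent", "scene_first")
    rows = []
    for lam in lams:
        rng = np.random.default_rng(seed)
        for rep in range(n_reps):
            traj = simulate_trajectory(
                codes, params, geometry, "left", True, rng,
                conflict=lam, dwell_s=0.05,
            )
            ct = canonicalize(traj, "left")
            rows.append((lam, rep, auc(ct), xflips(ct)))
    return pd.DataFrame(rows, columns=["lam", "rep", "auc", "xflips"])


def bootstrap_diff_ci(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``mean(b) - mean(a)``."""
    rng = np.random.default_rng(seed)
    a, b = np.asarray(a, float), np.asarray(b, float)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = (
            rng.choice(b, size=len(b)).mean() - rng.choice(a, size=len(a)).mean()
        )
    q = (1.0 - level) / 2.0
    return float(np.quantile(diffs, q)), float(np.quantile(diffs, 1.0 - q))


def cell_ordering_study(n_reps: int = 20, *, seed: int = 0) -> dict:
    """Condition-cell ordering under the default generator.

    Pools ``n_reps`` replicate experiments and checks that the
    implausible + congruent cell is the least accurate and shows the
    largest AUC and x-flip means among accurate trials.
    """
    schedules = small_design(seed=seed)
    params = SimulationParams()
    frames = []
    for i in range(n_reps):
        trials, samples = simulate_experiment(schedules, params, seed=seed + 1 + i)
        # keep error trials: the accuracy ordering is about them
        post_rt, _ = filter_rt_outliers(trials, k=4.0)
        frames.append(measure_trials(post_rt, samples))
    pooled = pd.concat(frames, ignore_index=True)
    summary = summarize_cells(pooled)

    def cell_extreme(measure: str, how: str) -> tuple[str, str]:
        sub = summary[summary["measure"] == measure]
        agg = sub.groupby(["plausibility", "congruency"])["mean"].mean()
        key = agg.idxmin() if how == "min" else agg.idxmax()
        return key

    return {
        "n_reps": n_reps,
        "lowest_accuracy_cell": cell_extreme("accuracy", "min"),
        "highest_auc_cell": cell_extreme("auc", "max"),
        "highest_xflips_cell": cell_extreme("xflips", "max"),
    }
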