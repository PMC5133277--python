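"""Synthetic mouse-tracking experiments for the verification task.

The cursor is modelled as a two-choice attractor: after a pre-movement dwell
at the calibration circle, each 60-Hz step moves at a base speed toward the
responded button while a conflict pull of strength ``lambda`` drags it toward
the competing button.  The pull decays linearly to zero over the first part
of the expected path, so competition shows up early (initial angle) and as
lateral deviation (area under the curve, x-flips), mirroring the qualitative
signature of two-alternative decision trajectories.

The conflict strength is ``softplus(beta_conflict . codes)`` where ``codes``
are the ±0.5 contrast codes of the trial's condition cell, so condition
effects on trajectory complexity are controlled by a coefficient vector in
the same parameterization the analysis models use.  Response accuracy is
Bernoulli on a logit scale with participant and scene random intercepts, and
the pre-movement dwell carries additive condition effects on the seconds
scale plus participant/scene intercepts, giving known ground-truth fixed
effects for recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .contrasts import code_vector

N_TERMS = 8  # intercept, 3 mains, 3 two-way, 1 three-way


class SimulationRunawayError(RuntimeError):
    """A simulated trajectory failed to reach its button within the step cap."""


def softplus(x: float) -> float:
    """Numerically stable log(1 + exp(x))."""
    return float(np.logaddexp(0.0, x))


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen layout of the verification display, in pixels.

    The calibration circle sits at the bottom-center of the screen; the
    yes/no buttons sit in the top corners, equally spaced from the vertical
    midline, inset 15% from the screen edges.  Screen coordinates follow the
    display convention: y grows downward.
    """

    width_px: float = 1024.0
    height_px: float = 768.0
    start: tuple[float, float] = (512.0, 750.0)
    yes_pos: tuple[float, float] = (153.6, 115.2)
    no_pos: tuple[float, float] = (870.4, 115.2)
    start_radius_px: float = 50.0
    button_radius_px: float = 40.0
    sample_rate_hz: float = 60.0

    def __post_init__(self):
        if self.start_radius_px <= 0:
            raise ValueError("start_radius_px must be positive")
        if tuple(self.yes_pos) == tuple(self.no_pos):
            raise ValueError("yes and no buttons must differ")
        mid = self.width_px / 2.0
        if not np.isclose(abs(self.yes_pos[0] - mid), abs(self.no_pos[0] - mid)):
            raise ValueError("yes/no buttons must be equidistant from the screen midline")

    def button_positions(self, counterbalance: str) -> dict[str, tuple[float, float]]:
        """Map response labels to screen positions for a counterbalancing arm."""
        left = min(self.yes_pos, self.no_pos, key=lambda p: p[0])
        right = max(self.yes_pos, self.no_pos, key=lambda p: p[0])
        if counterbalance == "yes_left":
            return {"yes": left, "no": right, "left": left, "right": right}
        if counterbalance == "yes_right":
            return {"yes": right, "no": left, "left": left, "right": right}
        raise ValueError(f"unknown counterbalance {counterbalance!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Generator coefficients and noise levels.

    Coefficient vectors are length 8 over (intercept, plausibility,
    congruency, order, P:C, P:O, C:O, P:C:O) with the ±0.5 contrast codes.
    ``beta_accuracy`` acts on the accuracy logit and ``beta_rt_s`` adds
    seconds to the pre-movement dwell; both default to the reference
    effect structure in which implausible-but-congruent trials are the
    least accurate, slowest and most conflicted cell.  ``beta_conflict``
    sets the attractor pull through a softplus link.
    """

    beta_conflict: tuple[float, ...] = (11.0, -1.0, 0.0, 0.0, -3.0, 0.0, 0.0, 0.0)
    beta_accuracy: tuple[float, ...] = (2.87, 0.51, 0.005, -0.45, 0.83, 0.26, -0.49, 0.0)
    beta_rt_s: tuple[float, ...] = (0.0, -0.07, 0.02, -0.02, -0.06, 0.04, -0.06, -0.01)
    participant_sd: float = 0.8  # accuracy-logit random intercept SD
    scene_sd: float = 0.5  # accuracy-logit random intercept SD
    rt_participant_sd_s: float = 0.08
    rt_scene_sd_s: float = 0.04
    motor_noise_px: float = 4.0
    base_speed_px_per_step: float = 14.0
    latency_base_s: float = 0.45
    latency_jitter_s: float = 0.08
    conflict_decay_frac: float = 0.6  # fraction of the expected path with pull
    max_duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("beta_conflict", "beta_accuracy", "beta_rt_s"):
            vec = tuple(float(v) for v in getattr(self, name))
            if len(vec) != N_TERMS:
                raise ValueError(f"{name} must have length {N_TERMS}")
            object.__setattr__(self, name, vec)
        for name in (
            "participant_sd", "scene_sd", "rt_participant_sd_s",
            "rt_scene_sd_s", "motor_noise_px", "latency_jitter_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.base_speed_px_per_step <= 0:
            raise ValueError("base_speed_px_per_step must be positive")


@dataclass(frozen=True)
class Trajectory:
    """A sampled cursor path: rows of (t_ms, x_px, y_px) at 60 Hz."""

    samples: np.ndarray
    geometry: ScreenGeometry
    chosen_side: str  # "left" | "right"

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 1:
            raise ValueError("samples must be an (n, 3) array")
        if np.any(np.diff(s[:, 0]) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def simulate_trajectory(
    codes: np.ndarray,
    params: SimulationParams,
    geometry: ScreenGeometry,
    correct_side: str,
    responds_correctly: bool,
    rng: np.random.Generator,
    *,
    counterbalance: str = "yes_left",
    conflict: float | None = None,
    dwell_s: float | None = None,
) -> Trajectory:
    """Simulate one cursor path from the calibration circle to a button.

    ``conflict`` overrides the softplus-linked pull (useful for sweeping the
    attractor strength directly); ``dwell_s`` overrides the pre-movement hold
    duration.  Identical inputs and generator state reproduce the identical
    sample list.
    """
    if correct_side not in ("left", "right"):
        raise ValueError("correct_side must be 'left' or 'right'")
    pos_map = geometry.button_positions(counterbalance)
    chosen_side = correct_side if responds_correctly else (
        "right" if correct_side == "left" else "left"
    )
    target = np.array(pos_map[chosen_side], dtype=float)
    competitor = np.array(
        pos_map["right" if chosen_side == "left" else "left"], dtype=float
    )

    lam = softplus(float(np.dot(params.beta_conflict, codes))) if conflict is None else float(conflict)
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"conflict strength must be finite and nonnegative, got {lam}")
    if dwell_s is None:
        dwell_s = params.latency_base_s

    fs = geometry.sample_rate_hz
    dt_ms = 1000.0 / fs
    start = np.array(geometry.start, dtype=float)
    expected_steps = float(np.linalg.norm(target - start)) / params.base_speed_px_per_step
    decay_steps = max(params.conflict_decay_frac * expected_steps, 1.0)
    max_samples = int(params.max_duration_s * fs)

    n_dwell = max(1, int(round(dwell_s * fs)))
    points = [start.copy() for _ in range(n_dwell)]

    pos = start.copy()
    step = 0
    while np.linalg.norm(pos - target) > geometry.button_radius_px:
        if len(points) >= max_samples:
            raise SimulationRunawayError(
                f"trajectory exceeded {params.max_duration_s} s "
                f"(lambda={lam:.3g}, speed={params.base_speed_px_per_step})"
            )
        to_target = target - pos
        u_t = to_target / np.linalg.norm(to_target)
        to_comp = competitor - pos
        n_comp = np.linalg.norm(to_comp)
        u_c = to_comp / n_comp if n_comp > 0 else np.zeros(2)
        w = max(0.0, 1.0 - step / decay_steps)
        vel = params.base_speed_px_per_step * u_t + lam * w * u_c
        if params.motor_noise_px > 0:
            vel = vel + rng.normal(0.0, params.motor_noise_px, size=2)
        pos = pos + vel
        points.append(pos.copy())
        step += 1

    t = np.arange(len(points)) * dt_ms
    samples = np.column_stack([t, np.asarray(points)])
    return Trajectory(samples=samples, geometry=geometry, chosen_side=chosen_side)


def _draw_intercepts(keys, sd: float, rng: np.random.Generator) -> dict:
    return dict(zip(keys, rng.normal(0.0, sd, size=len(keys)) if sd > 0 else np.zeros(len(keys))))


def correct_answer(congruency: str) -> str:
    """The response the task scores as correct: congruent pairs are 'yes'."""
    return "yes" if congruency == "congruent" else "no"


def simulate_experiment(
    schedules: pd.DataFrame,
    params: SimulationParams,
    geometry: ScreenGeometry | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every scheduled trial; return (trials, cursor samples).

    Randomness is split into named substreams (effects, accuracy, motor)
    derived from ``seed`` (falling back to ``params.seed``), so the whole
    experiment is reproducible from one integer.
    """
    geometry = geometry or ScreenGeometry()
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    effects_rng, accuracy_rng, motor_rng = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    sched = schedules.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
    participants = sorted(sched["participant_id"].unique())
    scene_units = sorted(
        set(zip(sched["scene_id"], sched["plausibility"]))
    )  # scene grouping unit: each scene within each plausibility condition
    u_acc_p = _draw_intercepts(participants, params.participant_sd, effects_rng)
    u_acc_s = _draw_intercepts(scene_units, params.scene_sd, effects_rng)
    u_rt_p = _draw_intercepts(participants, params.rt_participant_sd_s, effects_rng)
    u_rt_s = _draw_intercepts(scene_units, params.rt_scene_sd_s, effects_rng)

    trial_rows = []
    sample_frames = []
    for row in sched.itertuples(index=False):
        codes = code_vector(row.plausibility, row.congruency, row.order)
        unit = (row.scene_id, row.plausibility)

        eta = (
            float(np.dot(params.beta_accuracy, codes))
            + u_acc_p[row.participant_id]
            + u_acc_s[unit]
        )
        correct = bool(accuracy_rng.random() < expit(eta))
        answer = correct_answer(row.congruency)
        response = answer if correct else ("no" if answer == "yes" else "yes")

        pos_map = geometry.button_positions(row.counterbalance)
        correct_side = "left" if pos_map[answer] == pos_map["left"] else "right"

        dwell = (
            params.latency_base_s
            + float(np.dot(params.beta_rt_s, codes))
            + u_rt_p[row.participant_id]
            + u_rt_s[unit]
            + (motor_rng.normal(0.0, params.latency_jitter_s) if params.latency_jitter_s > 0 else 0.0)
        )
        dwell = max(dwell, 0.05)

        traj = simulate_trajectory(
            codes, params, geometry, correct_side, correct, motor_rng,
            counterbalance=row.counterbalance, dwell_s=dwell,
        )
        rt_s = float(traj.samples[-1, 0]) / 1000.0

        trial_rows.append(
            (
                row.participant_id, row.trial_index, row.scene_id,
                row.plausibility, row.congruency, row.order, row.counterbalance,
                response, correct, rt_s, correct_side,
            )
        )
        frame = pd.DataFrame(traj.samples, columns=["t_ms", "x_px", "y_px"])
        frame.insert(0, "trial_index", row.trial_index)
        frame.insert(0, "participant_id", row.participant_id)
        sample_frames.append(frame)

    trials = pd.DataFrame(
        trial_rows,
        columns=[
            "participant_id", "trial_index", "scene_id", "plausibility",
            "congruency", "order", "counterbalance", "response", "correct",
            "rt_s", "correct_side",
        ],
    )
    samples = pd.concat(sample_frames, ignore_index=True)
    return trials, samples
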