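"""Per-trial trajectory measures and condition-cell summaries.

Four complementary measures characterize the decision dynamics of each
verification trial, all defined on the canonical standardized frame (origin
at the calibration point, incorrect button at +x):

- **initial degree** — signed angle from vertical of the cursor position
  when it first exits a 50-px radius around the start point; positive means
  an early pull toward the incorrect response.
- **latency** — seconds until that first exit (initial hesitation).
- **x-flips** — number of reversals in the sign of the horizontal
  displacement, after collapsing sub-jitter wobble (changes of mind).
- **AUC** — signed trapezoidal area between the cursor path and the
  straight line from the start point to the correct button; net area, so
  excursions on the correct side of the line subtract.

Angles and the start radius are evaluated in pixel-equivalent units (the
standardized frame is anisotropic); AUC is reported in standardized units.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .preprocess import CanonicalTrajectory, Y_TOP, canonicalize
from .simulate import ScreenGeometry, Trajectory

#: The six dependent measures, in reporting order.
MEASURE_COLUMNS = ("accuracy", "rt_s", "initial_degree", "latency_s", "xflips", "auc")

#: Measures computed on accurate trials only (decision-dynamics set).
CORRECT_ONLY_MEASURES = ("rt_s", "initial_degree", "latency_s", "xflips", "auc")


def _first_exit_index(ctraj: CanonicalTrajectory, start_radius_px: float) -> int | None:
    xy_px = ctraj.xy_px()
    r = np.hypot(xy_px[:, 0], xy_px[:, 1])
    out = np.nonzero(r > start_radius_px)[0]
    return int(out[0]) if out.size else None


def initial_degree(ctraj: CanonicalTrajectory, start_radius_px: float = 50.0) -> float:
    """Signed exit angle from vertical, in degrees; NaN if never exits.

    The exit sample is the first sample strictly outside the radius (no
    interpolation to the circle crossing — the record is 60-Hz sampled).
    """
    i = _first_exit_index(ctraj, start_radius_px)
    if i is None:
        return math.nan
    x_px, y_px = ctraj.xy_px()[i]
    return math.degrees(math.atan2(x_px, y_px))


def latency(ctraj: CanonicalTrajectory, start_radius_px: float = 50.0) -> float:
    """Seconds from choice-display onset to the first exit; NaN if never."""
    i = _first_exit_index(ctraj, start_radius_px)
    if i is None:
        return math.nan
    return float(ctraj.t_ms[i]) / 1000.0


def xflips(ctraj: CanonicalTrajectory, jitter_px: float = 3.0) -> int:
    """Count directional reversals along the x-axis.

    Consecutive x-displacements are accumulated until their running sum
    exceeds ``jitter_px`` in magnitude (collapsing sensor/motor wobble);
    each surviving displacement whose sign differs from the previous one
    counts as a flip.  ``jitter_px=0`` reproduces the naive sign-change
    count over nonzero displacements.
    """
    if ctraj.samples.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if jitter_px < 0:
        raise ValueError("jitter_px must be nonnegative")
    dx = np.diff(ctraj.xy[:, 0]) * ctraj.scale_x_px
    flips = 0
    last_sign = 0
    pending = 0.0
    for d in dx:
        pending += d
        if (jitter_px > 0 and abs(pending) >= jitter_px) or (jitter_px == 0 and pending != 0):
            sign = 1 if pending > 0 else -1
            if last_sign != 0 and sign != last_sign:
                flips += 1
            last_sign = sign
            pending = 0.0
    return flips


def auc(ctraj: CanonicalTrajectory) -> float:
    """Signed area between the path and the straight start-to-correct line.

    Computed by the trapezoid rule on signed perpendicular deviations as a
    function of position along the ideal line, plus the closing leg from the
    final sample to the correct button; equals the shoelace area of the
    polygon formed by the path and the reversed ideal line.  Positive area
    lies toward the incorrect response.
    """
    if ctraj.samples.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    button = np.array([-1.0, Y_TOP])
    L = float(np.linalg.norm(button))
    if L == 0:
        raise ValueError("zero-length ideal line")
    u_hat = button / L
    n_hat = np.array([u_hat[1], -u_hat[0]])  # +x side of the line is positive
    xy = ctraj.xy
    u = xy @ u_hat
    d = xy @ n_hat
    area = float(np.sum(0.5 * (d[1:] + d[:-1]) * np.diff(u)))
    # closing legs along the ideal line: start -> first sample and
    # final sample -> correct button (d = 0 at u = 0 and u = L)
    area += 0.5 * (0.0 + d[0]) * (u[0] - 0.0)
    area += 0.5 * (d[-1] + 0.0) * (L - u[-1])
    return area


def _chosen_side(correct_side: str, correct: bool) -> str:
    other = "right" if correct_side == "left" else "left"
    return correct_side if correct else other


def measure_trials(
    trials: pd.DataFrame,
    samples: pd.DataFrame,
    geometry: ScreenGeometry | None = None,
    *,
    start_radius_px: float | None = None,
    jitter_px: float = 3.0,
) -> pd.DataFrame:
    """Compute the per-trial measure set for every trial in ``trials``.

    ``samples`` is the long cursor table (participant_id, trial_index,
    t_ms, x_px, y_px).  Trials whose cursor never leaves the start radius
    get NaN initial degree and latency; everything else is always defined.
    """
    geometry = geometry or ScreenGeometry()
    radius = geometry.start_radius_px if start_radius_px is None else start_radius_px
    grouped = dict(tuple(samples.groupby(["participant_id", "trial_index"], sort=False)))

    rows = []
    for tr in trials.itertuples(index=False):
        key = (tr.participant_id, tr.trial_index)
        if key not in grouped:
            raise KeyError(f"no cursor samples for trial {key}")
        arr = grouped[key][["t_ms", "x_px", "y_px"]].to_numpy(dtype=float)
        traj = Trajectory(
            samples=arr,
            geometry=geometry,
            chosen_side=_chosen_side(tr.correct_side, bool(tr.correct)),
        )
        ctraj = canonicalize(traj, tr.correct_side)
        rows.append(
            (
                tr.participant_id, tr.trial_index, tr.scene_id, tr.plausibility,
                tr.congruency, tr.order, tr.counterbalance, bool(tr.correct),
                tr.correct_side, tr.rt_s,
                initial_degree(ctraj, radius),
                latency(ctraj, radius),
                xflips(ctraj, jitter_px),
                auc(ctraj),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "trial_index", "scene_id", "plausibility",
            "congruency", "order", "counterbalance", "correct", "correct_side",
            "rt_s", "initial_degree", "latency_s", "xflips", "auc",
        ],
    )


def summarize_cells(measures: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each measure per order x congruency x plausibility cell.

    Accuracy is summarized over all trials in the table; response time and
    the trajectory measures over accurate trials only (the set the decision
    dynamics are defined on).  SD uses the n-1 convention and is missing for
    cells with a single observation.
    """
    if measures.empty:
        raise ValueError("empty measure table")
    df = measures.copy()
    df["accuracy"] = df["correct"].astype(float)

    records = []
    for (order, cong, plaus), cell in df.groupby(["order", "congruency", "plausibility"]):
        for m in MEASURE_COLUMNS:
            sub = cell if m == "accuracy" else cell[cell["correct"]]
            vals = sub[m].dropna()
            n = len(vals)
            records.append(
                (
                    order, cong, plaus, m, n,
                    float(vals.mean()) if n else math.nan,
                    float(vals.std(ddof=1)) if n > 1 else math.nan,
                )
            )
    return pd.DataFrame(
        records,
        columns=["order", "congruency", "plausibility", "measure", "n", "mean", "sd"],
    )
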