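"""Trial exclusion and canonical trajectory coordinates.

Exclusion follows the task's two-stage rule: drop trials whose verification
time lies more than ``k`` (default 4) standard deviations above the grand
mean, then restrict the dynamics analyses to accurate trials.

Canonicalization puts every trajectory into a shared standardized frame:
origin at the calibration circle, y growing upward toward the response row
(0 at start, 1.5 at the buttons), and x in [-1, 1] with the **incorrect**
response button at +1 — so positive lateral deviation always means movement
toward the competitor, whichever physical side it was on.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .simulate import Trajectory

logger = logging.getLogger(__name__)

#: y-coordinate of the response-button row in standardized space.
Y_TOP = 1.5


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the exclusion rules (counts and the RT cutoff)."""

    n_input: int
    n_removed_rt: int
    n_removed_error_trials: int
    n_retained: int
    rt_mean_s: float
    rt_sd_s: float
    rt_cutoff_s: float

    def __post_init__(self):
        if self.n_input != self.n_retained + self.n_removed_rt + self.n_removed_error_trials:
            raise ValueError("filter counts do not conserve trials")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_rt_outliers(trials: pd.DataFrame, k: float = 4.0) -> tuple[pd.DataFrame, FilterReport]:
    """Remove trials with ``rt_s`` above ``mean + k * SD`` (upper tail only).

    Mean and SD are taken over the grand RT distribution.  Raises
    ``ValueError`` for fewer than 2 trials (the SD is undefined) or a
    non-positive ``k``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to compute an RT cutoff")
    if (trials["rt_s"] <= 0).any():
        raise ValueError("all rt_s must be positive")
    rt = trials["rt_s"].to_numpy(dtype=float)
    mean, sd = float(rt.mean()), float(rt.std(ddof=1))
    cutoff = mean + k * sd
    keep = rt <= cutoff
    retained = trials[keep].reset_index(drop=True)
    report = FilterReport(
        n_input=len(trials),
        n_removed_rt=int((~keep).sum()),
        n_removed_error_trials=0,
        n_retained=len(retained),
        rt_mean_s=mean,
        rt_sd_s=sd,
        rt_cutoff_s=cutoff,
    )
    return retained, report


def select_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only accurate trials (the basis of all dynamics analyses)."""
    retained = trials[trials["correct"].astype(bool)].reset_index(drop=True)
    logger.info("select_correct: retained %d of %d trials", len(retained), len(trials))
    if retained.empty:
        logger.warning("select_correct: no correct trials remain")
    return retained


def preprocess_trials(trials: pd.DataFrame, k: float = 4.0) -> tuple[pd.DataFrame, FilterReport]:
    """RT-outlier filter followed by the correctness restriction.

    The combined report counts RT removals and error-trial removals
    separately; ``n_input = n_retained + n_removed_rt + n_removed_error_trials``.
    """
    after_rt, rt_report = filter_rt_outliers(trials, k=k)
    retained = select_correct(after_rt)
    report = FilterReport(
        n_input=rt_report.n_input,
        n_removed_rt=rt_report.n_removed_rt,
        n_removed_error_trials=len(after_rt) - len(retained),
        n_retained=len(retained),
        rt_mean_s=rt_report.rt_mean_s,
        rt_sd_s=rt_report.rt_sd_s,
        rt_cutoff_s=rt_report.rt_cutoff_s,
    )
    return retained, report


@dataclass(frozen=True)
class CanonicalTrajectory:
    """A trajectory in the standardized analysis frame.

    ``samples`` rows are (t_ms, x_std, y_std); the correct button sits at
    (-1, 1.5), the incorrect one at (+1, 1.5).  ``scale_x_px`` and
    ``scale_y_px`` are the pixel lengths of one standardized unit on each
    axis, kept so that pixel-defined quantities (the 50-px start radius,
    x-flip jitter, movement angles) can be evaluated in physical units.
    """

    samples: np.ndarray
    scale_x_px: float
    scale_y_px: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 1:
            raise ValueError("samples must be an (n, 3) array")
        if np.any(np.diff(s[:, 0]) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.scale_x_px <= 0 or self.scale_y_px <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def t_ms(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    def xy_px(self) -> np.ndarray:
        """Positions re-expressed in pixel units (origin at the start point)."""
        return self.xy * np.array([self.scale_x_px, self.scale_y_px])


def canonicalize(traj: Trajectory | CanonicalTrajectory, correct_side: str | None = None) -> CanonicalTrajectory:
    """Map a raw screen-space trajectory into the standardized frame.

    Translation moves the calibration point to the origin; the vertical axis
    is flipped so that movement toward the response row is positive; the
    horizontal axis is reflected when needed so the incorrect button lies at
    +x, then both axes are rescaled to x in [-1, 1] and y in [0, 1.5].
    Canonical input is returned unchanged (idempotence).
    """
    if isinstance(traj, CanonicalTrajectory):
        return traj
    if correct_side not in ("left", "right"):
        raise ValueError("correct_side must be 'left' or 'right'")
    geom = traj.geometry
    pos = geom.button_positions("yes_left")
    left, right = np.array(pos["left"], float), np.array(pos["right"], float)
    start = np.array(geom.start, float)
    dx_px = abs(left[0] - start[0])
    dy_px = abs(start[1] - left[1])
    if dx_px == 0 or dy_px == 0:
        raise ValueError("degenerate geometry: buttons collinear with the start point")

    sign = 1.0 if correct_side == "left" else -1.0  # put the incorrect side at +x
    t = traj.samples[:, 0]
    x_std = sign * (traj.samples[:, 1] - start[0]) / dx_px
    y_std = (start[1] - traj.samples[:, 2]) / dy_px * Y_TOP
    return CanonicalTrajectory(
        samples=np.column_stack([t, x_std, y_std]),
        scale_x_px=dx_px,
        scale_y_px=dy_px / Y_TOP,
    )


def time_normalize(ctraj: CanonicalTrajectory, n_bins: int = 101) -> pd.DataFrame:
    """Resample a trajectory onto ``n_bins`` equally spaced time points.

    Positions are linearly interpolated; each bin also carries the signed
    movement angle (degrees from vertical, in pixel-equivalent space,
    positive toward the incorrect side) of the displacement to the next bin
    — the last bin reuses the final displacement.  Raises on trajectories
    with fewer than 2 samples or zero duration.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    s = ctraj.samples
    if s.shape[0] < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    t = s[:, 0]
    if t[-1] <= t[0]:
        raise ValueError("zero-duration trajectory")
    grid = np.linspace(t[0], t[-1], n_bins)
    x = np.interp(grid, t, s[:, 1])
    y = np.interp(grid, t, s[:, 2])
    dx_px = np.diff(x) * ctraj.scale_x_px
    dy_px = np.diff(y) * ctraj.scale_y_px
    ang = np.degrees(np.arctan2(dx_px, dy_px))
    angle = np.append(ang, ang[-1])
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "t_ms": grid, "x_std": x, "y_std": y, "angle_deg": angle}
    )


def angle_profiles(
    trials: pd.DataFrame,
    samples: pd.DataFrame,
    geometry=None,
    n_bins: int = 101,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Time-normalized angle profiles for growth-curve analysis.

    Canonicalizes and time-normalizes every trial in ``trials`` (callers
    normally pass the filtered, correct-trial set) and returns a long table
    of per-bin movement angles with the design factors attached.  With
    ``aggregate=True`` profiles are averaged within participant x condition
    cell x bin, the granularity growth-curve models are usually fit at.
    """
    from .simulate import ScreenGeometry, Trajectory  # local to avoid cycle at import

    geometry = geometry or ScreenGeometry()
    grouped = dict(tuple(samples.groupby(["participant_id", "trial_index"], sort=False)))
    frames = []
    for tr in trials.itertuples(index=False):
        key = (tr.participant_id, tr.trial_index)
        if key not in grouped:
            raise KeyError(f"no cursor samples for trial {key}")
        arr = grouped[key][["t_ms", "x_px", "y_px"]].to_numpy(dtype=float)
        side = tr.correct_side if bool(tr.correct) else (
            "right" if tr.correct_side == "left" else "left"
        )
        ctraj = canonicalize(
            Trajectory(samples=arr, geometry=geometry, chosen_side=side),
            tr.correct_side,
        )
        prof = time_normalize(ctraj, n_bins)[["bin", "angle_deg"]].copy()
        prof["participant_id"] = tr.participant_id
        prof["trial_index"] = tr.trial_index
        prof["plausibility"] = tr.plausibility
        prof["congruency"] = tr.congruency
        prof["order"] = tr.order
        frames.append(prof)
    long = pd.concat(frames, ignore_index=True)
    if not aggregate:
        return long
    return (
        long.groupby(
            ["participant_id", "plausibility", "congruency", "order", "bin"],
            sort=True, as_index=False,
        )["angle_deg"]
        .mean()
    )
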