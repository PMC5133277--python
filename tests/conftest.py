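import numpy as np
import pandas as pd
import pytest

import mtverify as mv
from mtverify.preprocess import CanonicalTrajectory


@pytest.fixture(scope="session")
def geometry():
    return mv.ScreenGeometry()


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic experiment shared across read-only tests."""
    bank = mv.build_item_bank(24)
    lists = mv.build_latin_lists(bank, 4, seed=2)
    schedules = mv.build_schedules(lists, n_participants=8, per_participant=16, seed=2)
    trials, samples = mv.simulate_experiment(schedules, mv.SimulationParams(), seed=9)
    return schedules, trials, samples


@pytest.fixture(scope="session")
def small_measures(small_experiment):
    _, trials, samples = small_experiment
    retained, report = mv.preprocess_trials(trials, k=4.0)
    return mv.measure_trials(retained, samples), report


def make_canonical(points_px, scale_x_px=358.4, scale_y_px=635.0 / 1.5, dt_ms=1000.0 / 60.0):
    """Canonical trajectory from pixel-space offsets relative to the start."""
    pts = np.asarray(points_px, dtype=float)
    std = pts / np.array([scale_x_px, scale_y_px])
    t = np.arange(len(pts)) * dt_ms
    return CanonicalTrajectory(
        samples=np.column_stack([t, std]), scale_x_px=scale_x_px, scale_y_px=scale_y_px
    )


@pytest.fixture
def make_ct():
    return make_canonical
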