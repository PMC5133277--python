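"""Trajectory measures against independent geometric oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mtverify as mv
from mtverify.measures import auc, initial_degree, latency, summarize_cells, xflips
from mtverify.preprocess import CanonicalTrajectory, Y_TOP

from conftest import make_canonical

L_IDEAL = math.hypot(1.0, Y_TOP)
U_HAT = np.array([-1.0, Y_TOP]) / L_IDEAL
N_HAT = np.array([Y_TOP, 1.0]) / L_IDEAL


def from_line_frame(ud):
    """Canonical trajectory from (along-line, deviation) coordinates."""
    ud = np.asarray(ud, dtype=float)
    xy = ud[:, :1] * U_HAT + ud[:, 1:2] * N_HAT
    t = np.arange(len(xy)) * 16.0
    return CanonicalTrajectory(np.column_stack([t, xy]), 358.4, 635.0 / Y_TOP)


class TestInitialDegree:
    def test_vertical_exit_is_zero(self):
        ct = make_canonical([(0, 0), (0, 30), (0, 80)])
        assert initial_degree(ct) == 0.0

    def test_equal_offsets_toward_incorrect_give_plus_45(self):
        ct = make_canonical([(0, 0), (60, 60)])
        assert initial_degree(ct) == pytest.approx(45.0, abs=1e-9)

    @given(
        x=st.floats(-400, 400),
        y=st.floats(-200, 650),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_atan2_oracle(self, x, y):
        if math.hypot(x, y) <= 50.0:
            return
        ct = make_canonical([(0, 0), (x, y)])
        expected = math.degrees(math.atan2(x, y))
        assert initial_degree(ct) == pytest.approx(expected, abs=1e-9)
        if x < 0 and y > 0:
            assert initial_degree(ct) == pytest.approx(
                -math.degrees(math.atan2(abs(x), y)), abs=1e-9
            )

    def test_missing_when_radius_never_exited(self):
        ct = make_canonical([(0, 0), (10, 10), (20, 30), (-20, 10)])
        assert math.isnan(initial_degree(ct))
        assert math.isnan(latency(ct))

    def test_sign_equals_exit_side_and_range_for_upward_exits(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x, y = rng.uniform(-300, 300), rng.uniform(60, 600)
            if math.hypot(x, y) <= 50:
                continue
            deg = initial_degree(make_canonical([(0, 0), (x, y)]))
            assert -90.0 <= deg <= 90.0
            if x != 0:
                assert math.copysign(1, deg) == math.copysign(1, x)


class TestLatency:
    def test_first_exit_sample_time(self):
        # exit on the 28th sample (index 27) at 60 Hz => 450 ms
        pts = [(0, 1)] * 27 + [(0, 100), (0, 200)]
        ct = make_canonical(pts)
        assert latency(ct) == pytest.approx(0.45, abs=1e-9)

    def test_first_sample_already_outside(self):
        ct = make_canonical([(80, 80), (100, 100)])
        assert latency(ct) == 0.0

    def test_matches_forward_stepping_oracle(self, geometry):
        params = mv.SimulationParams(motor_noise_px=0.0)
        rng = np.random.default_rng(0)
        codes = np.zeros(8); codes[0] = 1.0
        traj = mv.simulate_trajectory(
            codes, params, geometry, "left", True, rng, conflict=0.0, dwell_s=0.2
        )
        ct = mv.canonicalize(traj, "left")
        # independent oracle: walk the raw samples, find the first beyond 50 px
        start = np.array(geometry.start)
        oracle = None
        for t_ms, x, y in traj.samples:
            if math.hypot(x - start[0], y - start[1]) > 50.0:
                oracle = t_ms / 1000.0
                break
        assert latency(ct) == pytest.approx(oracle, abs=1e-12)


def brute_force_flips(xs, jitter=0.0):
    """Sign-change count over (jitter-collapsed) x-displacements."""
    signs = []
    pending = 0.0
    for a, b in zip(xs, xs[1:]):
        pending += b - a
        if (jitter > 0 and abs(pending) >= jitter) or (jitter == 0 and pending != 0):
            signs.append(1 if pending > 0 else -1)
            pending = 0.0
    return sum(1 for s, t in zip(signs, signs[1:]) if s != t)


class TestXFlips:
    def test_monotone_x_has_no_flips(self):
        ct = make_canonical([(0, 0), (10, 5), (25, 10), (60, 20)], scale_x_px=1, scale_y_px=1)
        assert xflips(ct, jitter_px=0.0) == 0

    def test_examples(self):
        ct = make_canonical(
            [(0, 0), (10, 0), (5, 1), (15, 2), (10, 3)], scale_x_px=1, scale_y_px=1
        )
        assert xflips(ct, jitter_px=0.0) == 3
        ct2 = make_canonical([(0, 0), (10, 0), (9, 1), (15, 2)], scale_x_px=1, scale_y_px=1)
        assert xflips(ct2, jitter_px=3.0) == 0

    def test_exhaustive_sign_sequences_up_to_length_8(self):
        for n in range(1, 9):
            for deltas in itertools.product((-1, 0, 1), repeat=n):
                xs = np.concatenate([[0.0], np.cumsum(deltas)])
                ys = np.arange(len(xs), dtype=float)
                ct = make_canonical(
                    np.column_stack([xs, ys]), scale_x_px=1, scale_y_px=1
                )
                assert xflips(ct, jitter_px=0.0) == brute_force_flips(xs)

    def test_accumulated_subjitter_reversal_counts(self):
        # five -1 px steps accumulate past the 3 px jitter => one real flip
        xs = [0, 10, 9, 8, 7, 6, 5]
        ct = make_canonical(
            np.column_stack([xs, np.arange(len(xs))]), scale_x_px=1, scale_y_px=1
        )
        assert xflips(ct, jitter_px=3.0) == 1


def shoelace(vertices):
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestAUC:
    def test_path_on_ideal_line_is_zero(self):
        ct = from_line_frame([(0, 0), (0.3, 0), (0.9, 0), (L_IDEAL, 0)])
        assert auc(ct) == pytest.approx(0.0, abs=1e-12)

    def test_triangular_detour_area(self):
        b, h, u0 = 0.6, 0.25, 0.3
        ct = from_line_frame(
            [(0, 0), (u0, 0), (u0 + b / 2, h), (u0 + b, 0), (L_IDEAL, 0)]
        )
        assert auc(ct) == pytest.approx(b * h / 2, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_shoelace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(-1.5, 1.5, size=(50, 2))
        t = np.arange(50) * 16.0
        ct = CanonicalTrajectory(np.column_stack([t, xy]), 358.4, 635.0 / Y_TOP)
        poly = np.vstack([xy, [-1.0, Y_TOP], [0.0, 0.0]])
        assert auc(ct) == pytest.approx(shoelace(poly), abs=1e-9)

    def test_reflection_across_ideal_line_negates_auc(self):
        rng = np.random.default_rng(1)
        ud = np.column_stack(
            [np.sort(rng.uniform(0, L_IDEAL, 20)), rng.normal(0, 0.3, 20)]
        )
        mirrored = ud * np.array([1.0, -1.0])
        assert auc(from_line_frame(mirrored)) == pytest.approx(
            -auc(from_line_frame(ud)), abs=1e-12
        )

    def test_reflection_across_vertical_negates_angle_keeps_latency_flips(self):
        rng = np.random.default_rng(2)
        pts = np.cumsum(rng.normal(0, 40, size=(25, 2)), axis=0)
        pts[0] = (0.0, 0.0)
        ct = make_canonical(pts)
        mirrored = make_canonical(pts * np.array([-1.0, 1.0]))
        assert initial_degree(mirrored) == -initial_degree(ct)
        assert latency(mirrored) == latency(ct)
        assert xflips(mirrored) == xflips(ct)
        assert xflips(mirrored, jitter_px=0.0) == xflips(ct, jitter_px=0.0)


class TestMeasureTrials:
    def test_one_row_per_trial_and_rerun_identical(self, small_experiment):
        _, trials, samples = small_experiment
        m1 = mv.measure_trials(trials, samples)
        m2 = mv.measure_trials(trials, samples)
        assert len(m1) == len(trials)
        assert m1.equals(m2)

    def test_latency_never_exceeds_rt(self, small_measures):
        mtable, _ = small_measures
        ok = mtable["latency_s"].dropna() <= mtable.loc[
            mtable["latency_s"].notna(), "rt_s"
        ]
        assert ok.all()

    def test_never_exiting_trial_yields_missing_angle_and_latency(
        self, small_experiment, geometry
    ):
        _, trials, samples = small_experiment
        one = trials.head(1).copy()
        key = (one["participant_id"].iloc[0], one["trial_index"].iloc[0])
        sub = samples[
            (samples["participant_id"] == key[0]) & (samples["trial_index"] == key[1])
        ].copy()
        # shrink the path into the start region so the radius is never exited
        start = geometry.start
        sub["x_px"] = start[0] + (sub["x_px"] - start[0]) * 1e-3
        sub["y_px"] = start[1] + (sub["y_px"] - start[1]) * 1e-3
        out = mv.measure_trials(one, sub, geometry)
        assert math.isnan(out["initial_degree"].iloc[0])
        assert math.isnan(out["latency_s"].iloc[0])
        assert np.isfinite(out["auc"].iloc[0])
        assert out["xflips"].iloc[0] >= 0


class TestSummaries:
    def test_manual_four_trial_oracle(self):
        rows = []
        for i, (cong, aucv, rt, correct) in enumerate(
            [
                ("congruent", 0.1, 1.0, True),
                ("congruent", 0.3, 1.2, True),
                ("incongruent", 0.5, 1.4, True),
                ("incongruent", 0.5, 2.0, False),
            ]
        ):
            rows.append(
                dict(
                    participant_id=1, trial_index=i, scene_id=i,
                    plausibility="plausible", congruency=cong,
                    order="sentence_first", counterbalance="yes_left",
                    correct=correct, correct_side="left", rt_s=rt,
                    initial_degree=0.0, latency_s=0.2, xflips=0, auc=aucv,
                )
            )
        summary = summarize_cells(pd.DataFrame(rows))
        idx = summary.set_index(["congruency", "measure"])
        cong_auc = idx.loc[("congruent", "auc")]
        assert cong_auc["mean"] == pytest.approx(0.2)
        assert cong_auc["sd"] == pytest.approx(math.sqrt(0.02))
        assert cong_auc["n"] == 2
        # accuracy over all trials; RT over correct trials only
        inc_acc = idx.loc[("incongruent", "accuracy")]
        assert inc_acc["mean"] == pytest.approx(0.5)
        inc_rt = idx.loc[("incongruent", "rt_s")]
        assert inc_rt["mean"] == pytest.approx(1.4) and inc_rt["n"] == 1
        assert math.isnan(inc_rt["sd"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_cells(pd.DataFrame())
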