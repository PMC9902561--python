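"""Bead detection, exclusion rules, variance traces and dissociation calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import cfmkinetics as cfm
from cfmkinetics.tracking import Call, _below_runs

from conftest import match_tracks_to_truth

ACQ = cfm.AcquisitionConfig(rpm=1221.0, frame_interval=5.0)


def render_frame(positions, spec, seed=0, blur_idx=()):
    """Single frame with beads at given (y, x) positions, optionally blurred."""
    truth = cfm.GroundTruth(
        pd.DataFrame(
            [[i, x, y, "normal", 1e9, 1] for i, (y, x) in enumerate(positions)],
            columns=["bead_id", "x_px", "y_px", "class", "true_time_s", "censored"],
        )
    )
    stack = cfm.render_movie(spec, truth, seed=seed).astype(float)
    frame = stack[0]
    for i in blur_idx:
        y, x = positions[i]
        y, x = int(y), int(x)
        s = 14
        frame[y - s : y + s, x - s : x + s] = gaussian_filter(
            frame[y - s : y + s, x - s : x + s], 3.0
        )
    return frame


SPEC = cfm.MovieSpec(
    frame_shape=(256, 256), bead_radius_px=6, bead_contrast=50.0,
    background_level=100.0, noise_sd=8.0, frame_interval=5.0, n_frames=3,
)


class TestDetectBeads:
    def test_dense_field_detected(self, clean_movie_100):
        spec, stack, truth, _ = clean_movie_100
        tracks = cfm.detect_beads(stack[0])
        matched = match_tracks_to_truth(tracks, truth)
        assert len(matched) >= 95

    def test_blank_noise_frame(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(100.0, 8.0, (256, 256))
        assert cfm.detect_beads(frame) == []

    def test_single_disc(self):
        frame = render_frame([(128.0, 128.0)], SPEC)
        tracks = cfm.detect_beads(frame)
        assert len(tracks) == 1
        assert abs(tracks[0].center[0] - 128.0) <= 1
        assert abs(tracks[0].center[1] - 128.0) <= 1

    def test_invalid_images_rejected(self):
        with pytest.raises(ValueError):
            cfm.detect_beads(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            cfm.detect_beads(np.full((64, 64), np.nan))
        with pytest.raises(ValueError):
            cfm.detect_beads(np.zeros((4, 4, 3)))

    def test_deterministic(self):
        frame = render_frame([(60.0, 60.0), (180.0, 120.0)], SPEC)
        a = cfm.detect_beads(frame)
        b = cfm.detect_beads(frame)
        assert [t.center for t in a] == [t.center for t in b]


class TestExclusions:
    def test_close_pair_both_clustered(self):
        positions = [(60.0, 60.0), (60.0, 63.0), (180.0, 180.0)]
        frame = render_frame([positions[2]], SPEC)
        tracks = [
            cfm.BeadTrack(bead_id=i, center=p, radius=6.0)
            for i, p in enumerate(positions)
        ]
        cfm.apply_exclusions(tracks, frame, min_separation_px=10.0)
        assert tracks[0].call == Call("excluded", reason="clustered")
        assert tracks[1].call == Call("excluded", reason="clustered")
        assert tracks[2].call is None

    def test_well_separated_no_exclusions(self, clean_movie_100):
        spec, stack, truth, _ = clean_movie_100
        tracks = cfm.detect_beads(stack[0])
        cfm.apply_exclusions(tracks, stack[0])
        assert all(t.call is None for t in tracks)

    def test_blurred_bead_excluded_off_focus(self):
        positions = [(50.0, 50.0), (50.0, 150.0), (150.0, 50.0),
                     (150.0, 150.0), (100.0, 100.0), (200.0, 100.0),
                     (200.0, 200.0), (100.0, 200.0)]
        frame = render_frame(positions, SPEC, blur_idx=(4,))
        tracks = [
            cfm.BeadTrack(bead_id=i, center=p, radius=6.0)
            for i, p in enumerate(positions)
        ]
        cfm.apply_exclusions(tracks, frame, min_separation_px=10.0)
        assert tracks[4].call == Call("excluded", reason="off_focus")
        assert sum(t.call is None for t in tracks) == 7

    def test_edge_roi_excluded(self):
        frame = np.random.default_rng(0).normal(100, 8, (128, 128))
        t = cfm.BeadTrack(bead_id=0, center=(4.0, 64.0), radius=6.0)
        cfm.apply_exclusions([t], frame)
        assert t.call == Call("excluded", reason="edge")


class TestVarianceTrace:
    def _movie(self, true_time):
        truth = cfm.GroundTruth(
            pd.DataFrame(
                [[0, 128.0, 128.0, "normal", true_time, 1 if true_time > 1e8 else 0]],
                columns=["bead_id", "x_px", "y_px", "class", "true_time_s", "censored"],
            )
        )
        spec = cfm.MovieSpec(
            frame_shape=(256, 256), bead_radius_px=6, bead_contrast=50.0,
            noise_sd=8.0, frame_interval=5.0, n_frames=40,
        )
        return cfm.render_movie(spec, truth, seed=1)

    def test_present_bead_high_constant(self):
        stack = self._movie(1e9)
        t = cfm.BeadTrack(bead_id=0, center=(128.0, 128.0), radius=6.0)
        trace = cfm.variance_trace(stack, t)
        assert trace.min() > 5 * 8.0**2
        assert trace.std() / trace.mean() < 0.1

    def test_absent_bead_noise_floor(self):
        stack = self._movie(1e9)
        t = cfm.BeadTrack(bead_id=0, center=(40.0, 40.0), radius=6.0)
        trace = cfm.variance_trace(stack, t)
        assert trace.mean() == pytest.approx(8.0**2, rel=0.2)

    def test_vanishing_bead_sharp_drop(self):
        stack = self._movie(52.0)  # absent from frame ceil(52/5) = 11
        t = cfm.BeadTrack(bead_id=0, center=(128.0, 128.0), radius=6.0)
        trace = cfm.variance_trace(stack, t)
        assert trace[10] / trace[11] > 3

    def test_clipped_roi_raises(self):
        stack = self._movie(1e9)
        t = cfm.BeadTrack(bead_id=0, center=(3.0, 128.0), radius=6.0)
        with pytest.raises(ValueError):
            cfm.variance_trace(stack, t)


class TestCallDissociation:
    def test_step_trace_called_at_drop(self):
        call = cfm.call_dissociation(
            np.array([100.0, 100, 100, 5, 5, 5]),
            drop_fraction=0.5, persistence=2, frame_interval=5.0,
        )
        assert call == Call("dissociated", time=15.0)

    def test_constant_trace_censored(self):
        call = cfm.call_dissociation(np.full(50, 100.0), frame_interval=5.0)
        assert call.kind == "censored"

    def test_recovering_trace_excluded_multiple_drops(self):
        call = cfm.call_dissociation(
            np.array([100.0, 5, 5, 100, 100, 5, 5]),
            drop_fraction=0.5, persistence=2, frame_interval=5.0,
        )
        assert call == Call("excluded", reason="multiple_drops")

    def test_early_drop_called_via_first_frame_anchor(self):
        # dissociation inside the baseline window still callable because the
        # detection frame anchors the baseline
        trace = np.array([100.0, 4, 5, 4, 5, 4, 5, 4])
        call = cfm.call_dissociation(trace, frame_interval=5.0)
        assert call == Call("dissociated", time=5.0)

    def test_non_finite_trace_rejected(self):
        with pytest.raises(ValueError):
            cfm.call_dissociation(np.array([100.0, np.nan, 5, 5, 5]))

    @given(
        trace=st.lists(st.floats(1.0, 1000.0), min_size=6, max_size=40),
        theta_hi=st.floats(0.2, 0.9),
        delta=st.floats(0.01, 0.15),
    )
    def test_lower_threshold_never_calls_earlier(self, trace, theta_hi, delta):
        trace = np.asarray(trace)
        theta_lo = theta_hi - delta
        hi = cfm.call_dissociation(trace, drop_fraction=theta_hi, persistence=2)
        lo = cfm.call_dissociation(trace, drop_fraction=theta_lo, persistence=2)
        if hi.kind == "dissociated" and lo.kind == "dissociated":
            assert lo.time >= hi.time

    def test_below_runs_helper(self):
        assert _below_runs(np.array([0, 1, 1, 0, 1], bool)) == [(1, 2), (4, 1)]


class TestTrackExperiment:
    def test_end_to_end_matches_truth(self, clean_movie_100):
        spec, stack, truth, _ = clean_movie_100
        tracks = cfm.detect_beads(stack[0])
        tracks = cfm.apply_exclusions(tracks, stack[0])
        matched = match_tracks_to_truth(tracks, truth)
        frames_true = truth.dissociation_frame().to_numpy()
        for t, j in matched:
            if t.call is not None:
                continue
            trace = cfm.variance_trace(stack, t)
            call = cfm.call_dissociation(trace, frame_interval=spec.frame_interval)
            if frames_true[j] == -1:
                assert call.kind == "censored"
            else:
                assert call.kind == "dissociated"
                f_called = round(call.time / spec.frame_interval)
                assert abs(f_called - frames_true[j]) <= 1

    def test_stuck_movie_all_censored(self):
        model = cfm.TetherPopulationModel(
            n_tethers=12, off_rate=0.01, stuck_fraction=1.0, slow_fraction=0.0,
            slow_rate=0.001, duration=1e9, seed=4,
        )
        spec = cfm.MovieSpec(frame_shape=(256, 256), n_frames=30, noise_sd=8.0)
        stack, truth, _ = cfm.simulate_movie(model, spec)
        ds, log = cfm.track_experiment(stack, ACQ)
        assert log["n_detected"] == 12
        assert ds.n_events == 0
        assert ds.n_censored == log["n_detected"] - log["n_excluded"]

    def test_clustered_pair_reported_in_log(self):
        spec = cfm.MovieSpec(frame_shape=(256, 256), n_frames=30, noise_sd=8.0)
        rows = [[0, 60.0, 60.0, "normal", 50.0, 0],
                [1, 66.0, 60.0, "normal", 80.0, 0]]
        rows += [
            [2 + i, 40.0 + 45 * (i % 5), 120.0 + 45 * (i // 5), "normal",
             30.0 + 9 * i, 0]
            for i in range(10)
        ]
        truth = cfm.GroundTruth(
            pd.DataFrame(rows, columns=["bead_id", "x_px", "y_px", "class",
                                        "true_time_s", "censored"]),
            frame_interval=5.0,
        )
        stack = cfm.render_movie(spec, truth, seed=0)
        ds, log = cfm.track_experiment(stack, ACQ, min_separation_px=10.0)
        assert log["excluded_by_reason"].get("clustered", 0) == 2
        assert ds.n_total == log["n_detected"] - log["n_excluded"]
        assert ds.n_total == 10

    def test_determinism(self, clean_movie_100):
        _, stack, _, _ = clean_movie_100
        a, _ = cfm.track_experiment(stack, ACQ)
        b, _ = cfm.track_experiment(stack, ACQ)
        assert a.data.equals(b.data)

    def test_excluded_never_contribute_events(self, clean_movie_100):
        _, stack, _, _ = clean_movie_100
        ds, log = cfm.track_experiment(stack, ACQ)
        assert ds.n_total + log["n_excluded"] == log["n_detected"]
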