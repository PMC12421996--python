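"""Distance traces, episode calling (against a direct boolean scan), approach
times on constructed waveforms, and Pearson-correlation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisstrace import LiveSimConfig, simulate_intensity_exchange, simulate_tethered_trajectory
from kisstrace.detect import SpotRecord
from kisstrace.kissing import (
    DistanceTrace,
    InsufficientDataError,
    UndefinedCorrelationError,
    approach_times,
    call_kissing_episodes,
    compute_distance_trace,
    intensity_correlation,
)
from kisstrace.track import Track


def trace_from_distances(d, valid=None, interval=1.0):
    d = np.asarray(d, dtype=float)
    n = len(d)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return DistanceTrace(
        frames=np.arange(n),
        time_s=np.arange(n) * interval,
        distance_um=d,
        gag_intensity=np.ones(n),
        rna_intensity=np.ones(n),
        gag_area_um2=np.full(n, 0.15),
        valid=np.asarray(valid, dtype=bool),
    )


def track_from_positions(frames, positions, channel="gag"):
    tr = Track(object_id=0, channel=channel)
    for f, p in zip(frames, positions):
        tr.frames.append(int(f))
        tr.spots.append(
            SpotRecord(
                channel=channel, frame=int(f), center_um=np.asarray(p, dtype=float),
                sum_intensity=100.0, peak_intensity=10.0, label=0, area_um2=0.1,
            )
        )
    return tr


class TestDistanceTrace:
    def test_identical_tracks_zero_distance(self):
        pos = [(1.0, 2.0)] * 5
        a = track_from_positions(range(5), pos)
        b = track_from_positions(range(5), pos, channel="rna")
        trace = compute_distance_trace(a, b, 1.04)
        assert np.all(trace.distance_um == 0)
        assert np.allclose(trace.time_s, np.arange(5) * 1.04)

    def test_three_four_five_triangle(self):
        a = track_from_positions([0, 1], [(0.0, 0.0)] * 2)
        b = track_from_positions([0, 1], [(0.3, 0.4)] * 2, channel="rna")
        trace = compute_distance_trace(a, b, 1.0)
        assert np.allclose(trace.distance_um, 0.5)

    def test_no_overlap_raises(self):
        a = track_from_positions([0, 1], [(0, 0)] * 2)
        b = track_from_positions([5, 6], [(0, 0)] * 2)
        with pytest.raises(InsufficientDataError):
            compute_distance_trace(a, b, 1.0)

    def test_interpolated_frames_marked_invalid(self):
        a = track_from_positions([0, 1, 2], [(0, 0)] * 3)
        a.gap_frames = {1}
        b = track_from_positions([0, 1, 2], [(0, 0.1)] * 3, channel="rna")
        trace = compute_distance_trace(a, b, 1.0)
        assert list(trace.valid) == [True, False, True]

    def test_simulator_truth_distances_recovered(self):
        cfg = LiveSimConfig(n_frames=50, rng_seed=17)
        traj = simulate_tethered_trajectory(cfg)
        center = np.asarray(cfg.tether_center_um)
        a = track_from_positions(range(50), traj)
        b = track_from_positions(range(50), [center] * 50, channel="rna")
        trace = compute_distance_trace(a, b, cfg.frame_interval_s)
        d_true = np.linalg.norm(traj - center, axis=1)
        assert np.allclose(trace.distance_um, d_true, atol=1e-12)


class TestEpisodes:
    def test_hand_checked_runs(self):
        trace = trace_from_distances([0.4, 0.2, 0.2, 0.3, 0.1])
        eps = call_kissing_episodes(trace, 0.25)
        assert [(e.start_frame, e.end_frame) for e in eps] == [(1, 2), (4, 4)]
        assert eps[0].duration_s == 2.0 and eps[1].duration_s == 1.0
        assert eps[1].min_distance_um == pytest.approx(0.1)

    def test_all_above_threshold_empty(self):
        assert call_kissing_episodes(trace_from_distances([0.3, 0.4, 0.5])) == []

    def test_invalid_frames_break_episodes(self):
        trace = trace_from_distances([0.1, 0.1, 0.1], valid=[True, False, True])
        eps = call_kissing_episodes(trace)
        assert [(e.start_frame, e.end_frame) for e in eps] == [(0, 0), (2, 2)]

    def test_boundary_inclusive(self):
        eps = call_kissing_episodes(trace_from_distances([0.25]))
        assert len(eps) == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=0.6, allow_nan=False), min_size=1, max_size=40),
        st.floats(min_value=0.05, max_value=0.5),
    )
    def test_episode_frames_equal_direct_boolean_scan(self, distances, threshold):
        trace = trace_from_distances(distances)
        eps = call_kissing_episodes(trace, threshold)
        episode_frames = set()
        for e in eps:
            assert e.start_frame <= e.end_frame
            episode_frames.update(range(e.start_frame, e.end_frame + 1))
        scan = {i for i, d in enumerate(distances) if d <= threshold}
        assert episode_frames == scan

    def test_simulated_contact_schedule_recovered_exactly(self):
        cfg = LiveSimConfig(n_frames=300, rng_seed=23)
        traj = simulate_tethered_trajectory(cfg)
        _, _, truth = simulate_intensity_exchange(cfg, traj)
        center = np.asarray(cfg.tether_center_um)
        a = track_from_positions(range(300), traj)
        b = track_from_positions(range(300), [center] * 300, channel="rna")
        trace = compute_distance_trace(a, b, cfg.frame_interval_s)
        eps = call_kissing_episodes(trace, cfg.contact_threshold_um)
        assert [(e.start_frame, e.end_frame) for e in eps] == truth.contact_intervals


class TestApproachTimes:
    def test_monotone_descent_single_event(self):
        d = [0.6, 0.5, 0.4, 0.35, 0.3, 0.1]
        events = approach_times(trace_from_distances(d), 0.25)
        assert len(events) == 1
        assert events[0].peak_frame == 0 and events[0].valley_frame == 5
        assert events[0].transit_s == 5.0

    def test_never_below_threshold_no_events(self):
        assert approach_times(trace_from_distances([0.5, 0.6, 0.5]), 0.25) == []

    def test_triangle_wave_k_crossings(self):
        # three triangles: peak 0.5 descending to 0.1 over 2 frames
        d = [0.1, 0.5, 0.3, 0.1, 0.5, 0.3, 0.1, 0.5, 0.3, 0.1]
        events = approach_times(trace_from_distances(d), 0.25)
        assert len(events) == 3
        assert all(e.transit_s == 2.0 for e in events)
        assert [e.peak_frame for e in events] == [1, 4, 7]


class TestIntensityCorrelation:
    def test_perfect_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, n = intensity_correlation(a, -a)
        assert r == pytest.approx(-1.0)
        assert n == 4

    def test_null_distribution_small_r(self):
        small = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a, b = rng.standard_normal((2, 1000))
            r, _, _ = intensity_correlation(a, b)
            if abs(r) < 0.1:
                small += 1
        assert small >= 95

    def test_generative_sign_recovery(self):
        cfg = LiveSimConfig(
            n_frames=300, exchange_rate=0.02, intensity_noise_sd=20.0, rng_seed=31
        )
        traj = simulate_tethered_trajectory(cfg)
        rna, gag, _ = simulate_intensity_exchange(cfg, traj)
        r, _, _ = intensity_correlation(rna, gag)
        assert r < 0

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 50))
        r0, _, _ = intensity_correlation(a, b)
        r_pos, _, _ = intensity_correlation(2.5 * a + 7, b)
        r_neg, _, _ = intensity_correlation(-1.5 * a + 2, b)
        assert r_pos == pytest.approx(r0, abs=1e-12)
        assert r_neg == pytest.approx(-r0, abs=1e-12)
        assert -1.0 <= r0 <= 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            intensity_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            intensity_correlation([1.0, 2.0], [2.0, 1.0])


def test_mean_contact_fraction_recovered_over_many_movies():
    # parameter recovery: with the tether calibrated for 30% contact
    # occupancy, the mean detected contact fraction over 50 movies (from
    # true positions, i.e. noiseless detection) is within ±0.05 of 0.30
    from kisstrace.config import tether_sd_for_contact_fraction

    sd = tether_sd_for_contact_fraction(0.25, 0.30)
    fracs = []
    for seed in range(50):
        cfg = LiveSimConfig(n_frames=300, tether_sd_um=sd, rng_seed=seed)
        traj = simulate_tethered_trajectory(cfg)
        d = np.linalg.norm(traj - np.asarray(cfg.tether_center_um), axis=1)
        fracs.append(np.mean(d <= 0.25))
    assert abs(np.mean(fracs) - 0.30) <= 0.05
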