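"""Simulator contracts: OU tether moments, intensity-exchange arithmetic and
conservation, rendering mass/centroid fidelity, fixed-volume geometry truth,
and determinism of every generation path."""

import numpy as np
import pytest

from kisstrace import (
    FixedSimConfig,
    LiveSimConfig,
    ParameterError,
    simulate_fixed_cell_volume,
    simulate_intensity_exchange,
    simulate_live_movie,
    simulate_tethered_trajectory,
)
from kisstrace.simulate import (
    contact_intervals_from_distances,
    ellipsoid_boundary_distance,
    render_movie,
)

from conftest import brute_force_ellipsoid_distance


class TestTetheredTrajectory:
    def test_zero_noise_limit_stays_at_tether_center(self):
        cfg = LiveSimConfig(n_frames=20, tether_sd_um=0.0)
        traj = simulate_tethered_trajectory(cfg)
        assert np.array_equal(traj, np.tile(cfg.tether_center_um, (20, 1)))

    def test_stationary_sd_matches_configured_value(self):
        # long-run per-axis SD vs the closed-form stationary variance
        cfg = LiveSimConfig(
            n_frames=10_000, tether_sd_um=0.3, tether_relaxation_s=10.0, rng_seed=1
        )
        traj = simulate_tethered_trajectory(cfg)
        sd = traj.std(axis=0)
        assert np.all(np.abs(sd - 0.3) / 0.3 < 0.05)

    def test_same_seed_identical_trajectories(self):
        cfg = LiveSimConfig(n_frames=100, rng_seed=42)
        a = simulate_tethered_trajectory(cfg)
        b = simulate_tethered_trajectory(cfg)
        assert np.array_equal(a, b)

    def test_confined_within_one_micron(self):
        # emulates condensates that stay ≤1 µm from the burst throughout
        cfg = LiveSimConfig(n_frames=300, rng_seed=5)
        traj = simulate_tethered_trajectory(cfg)
        d = np.linalg.norm(traj - np.asarray(cfg.tether_center_um), axis=1)
        assert np.mean(d <= 1.0) > 0.99

    @pytest.mark.parametrize(
        "bad", [{"tether_relaxation_s": 0.0}, {"tether_relaxation_s": -1.0}, {"tether_sd_um": -0.1}]
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            LiveSimConfig(**bad)


class TestIntensityExchange:
    def test_no_exchange_no_noise_series_constant(self):
        cfg = LiveSimConfig(n_frames=50, exchange_rate=0.0, rng_seed=3)
        traj = simulate_tethered_trajectory(cfg)
        rna, gag, _ = simulate_intensity_exchange(cfg, traj)
        assert np.ptp(rna) == 0 and np.ptp(gag) == 0
        assert np.allclose(rna + gag, rna[0] + gag[0])

    def test_single_contact_frame_arithmetic(self):
        cfg = LiveSimConfig(
            n_frames=2,
            exchange_rate=0.1,
            burst_mean_intensity=1000.0,
            gag_mean_intensity=100.0,
            tether_sd_um=0.0,  # always in contact
        )
        traj = simulate_tethered_trajectory(cfg)
        rna, gag, _ = simulate_intensity_exchange(cfg, traj)
        assert rna[1] == pytest.approx(900.0)
        assert gag[1] == pytest.approx(200.0)

    def test_sum_conserved_without_fluctuation_noise(self):
        cfg = LiveSimConfig(n_frames=200, exchange_rate=0.05, rng_seed=9)
        traj = simulate_tethered_trajectory(cfg)
        rna, gag, _ = simulate_intensity_exchange(cfg, traj)
        assert np.allclose(rna + gag, rna[0] + gag[0])

    def test_exchange_produces_anticorrelated_series(self):
        # sign recovery across seeds: contact-gated exchange → negative r
        neg = 0
        for seed in range(100):
            cfg = LiveSimConfig(
                n_frames=300,
                exchange_rate=0.02,
                intensity_noise_sd=0.01 * 2000.0,
                rng_seed=seed,
            )
            traj = simulate_tethered_trajectory(cfg)
            rna, gag, truth = simulate_intensity_exchange(cfg, traj)
            if truth.contact_mask(cfg.n_frames).mean() < 0.05:
                neg += 1  # essentially no contacts: no signal to carry a sign
                continue
            if np.corrcoef(rna, gag)[0, 1] < 0:
                neg += 1
        assert neg >= 95

    def test_exchange_rate_validated(self):
        with pytest.raises(ParameterError):
            LiveSimConfig(exchange_rate=1.5)

    def test_contact_intervals_match_direct_thresholding(self):
        cfg = LiveSimConfig(n_frames=400, rng_seed=21)
        traj = simulate_tethered_trajectory(cfg)
        _, _, truth = simulate_intensity_exchange(cfg, traj)
        d = np.linalg.norm(traj - np.asarray(cfg.tether_center_um), axis=1)
        mask = d <= cfg.contact_threshold_um
        assert np.array_equal(truth.contact_mask(cfg.n_frames), mask)
        # intervals disjoint, sorted, maximal
        ivs = truth.contact_intervals
        assert all(a <= b for a, b in ivs)
        assert all(ivs[i][1] + 1 < ivs[i + 1][0] for i in range(len(ivs) - 1))


class TestRenderMovie:
    def test_zero_intensity_zero_noise_gives_blank_frames(self):
        cfg = LiveSimConfig(n_frames=3, tether_sd_um=0.0)
        traj = simulate_tethered_trajectory(cfg)
        stack = render_movie(traj, np.zeros(3), np.zeros(3), cfg)
        assert not np.any(stack.data)

    def test_rendered_mass_equals_frame_intensity(self):
        cfg = LiveSimConfig(n_frames=2, tether_sd_um=0.0)
        traj = simulate_tethered_trajectory(cfg)
        stack = render_movie(traj, np.full(2, 1234.0), np.full(2, 567.0), cfg)
        assert stack.data[0, 0].sum() == pytest.approx(1234.0, rel=0.01)
        assert stack.data[0, 1].sum() == pytest.approx(567.0, rel=0.01)

    def test_centroid_of_pixel_centered_object_is_exact(self):
        cfg = LiveSimConfig(n_frames=2, tether_sd_um=0.0, tether_center_um=(3.2, 3.2))
        traj = np.array([[3.2, 3.2]] * 2)  # exactly pixel 32 at 0.1 µm/px
        stack = render_movie(traj, np.array([1000.0] * 2), np.array([1000.0] * 2), cfg)
        img = stack.data[0, 1]
        yy, xx = np.indices(img.shape)
        cy = (yy * img).sum() / img.sum() * cfg.pixel_size_um
        cx = (xx * img).sum() / img.sum() * cfg.pixel_size_um
        assert abs(cy - 3.2) < 1e-6 and abs(cx - 3.2) < 1e-6

    def test_undersampled_psf_warns(self):
        cfg = LiveSimConfig(n_frames=2, psf_sigma_um=0.02, tether_sd_um=0.0)
        traj = simulate_tethered_trajectory(cfg)
        with pytest.warns(UserWarning, match="undersampled"):
            render_movie(traj, np.ones(2), np.ones(2), cfg)

    def test_full_movie_generation_deterministic(self):
        cfg = LiveSimConfig(n_frames=10, rng_seed=13, noise_gaussian_sd=2.0, noise_poisson=True)
        s1, t1 = simulate_live_movie(cfg)
        s2, t2 = simulate_live_movie(cfg)
        assert np.array_equal(s1.data, s2.data)
        assert t1.contact_intervals == t2.contact_intervals


class TestEllipsoidGeometry:
    def test_analytic_distance_matches_brute_force_surface_sampling(self):
        semi = np.array([4.2, 5.5, 5.5])
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(-0.6, 0.6, 3) * semi
            d = ellipsoid_boundary_distance(p, semi)
            d_oracle = brute_force_ellipsoid_distance(p, semi)
            assert abs(d - d_oracle) < 5e-3

    def test_sphere_center_distance_is_radius(self):
        assert ellipsoid_boundary_distance([0, 0, 0], [5.0, 5.0, 5.0]) == pytest.approx(5.0)


class TestFixedVolume:
    def test_focus_truth_distances_match_targets(self):
        cfg = FixedSimConfig(
            rng_seed=2,
            n_gag_foci=20,
            gag_rim_distance_sampler=lambda rng, n: np.full(n, 0.5),
        )
        _, truth = simulate_fixed_cell_volume(cfg)
        gag_d = [f["rim_distance_um"] for f in truth.foci if f["channel"] == "gag"]
        assert len(gag_d) == 20
        assert np.allclose(gag_d, 0.5, atol=0.15)  # half the largest voxel dim

    def test_exactly_one_true_burst_flagged(self):
        cfg = FixedSimConfig(rng_seed=4, n_bursts=2, n_gag_foci=0)
        _, truth = simulate_fixed_cell_volume(cfg)
        rna = [f for f in truth.foci if f["channel"] == "rna"]
        assert len(rna) == 2
        flags = [f["is_burst"] for f in rna]
        assert sum(flags) == 1
        burst = rna[flags.index(True)]
        assert burst["intensity"] == max(f["intensity"] for f in rna)

    def test_volume_generation_deterministic(self):
        cfg = FixedSimConfig(rng_seed=8, n_gag_foci=5, noise_poisson=True, noise_gaussian_sd=1.0)
        v1, t1 = simulate_fixed_cell_volume(cfg)
        v2, t2 = simulate_fixed_cell_volume(cfg)
        assert np.array_equal(v1.data, v2.data)
        assert t1.foci == t2.foci

    def test_infeasible_rim_distance_rejected(self):
        with pytest.raises(ParameterError):
            FixedSimConfig(burst_rim_distance_um=10.0)


def test_contact_interval_bookkeeping_roundtrip():
    d = np.array([0.4, 0.2, 0.2, 0.3, 0.1])
    assert contact_intervals_from_distances(d, 0.25) == [(1, 2), (4, 4)]
    assert contact_intervals_from_distances(np.full(5, 0.5), 0.25) == []
    assert contact_intervals_from_distances(np.zeros(3), 0.25) == [(0, 2)]
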