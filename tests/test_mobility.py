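"""Tests of mobility classification, MSD estimation and population stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ground_truth_classes, simulate_filtered_tracks
from sporetrack.mobility import (classify_mobility, compare_populations,
                                 compute_msd, estimate_D, population_table,
                                 summarize_population)
from sporetrack.tracking import Trajectory

PX = 0.16


def make_track(xy, dt=0.1, track_id=0):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(track_id, np.arange(len(xy)), xy, frame_interval=dt)


def brute_force_class(track, pixel_size=PX, window_s=1.2):
    """Independent oracle: direct max - min per axis over the window."""
    n_win = min(track.n_frames, int(np.floor(window_s / track.frame_interval
                                             + 1e-9)) + 1)
    w = track.xy[:n_win]
    sx = max(w[:, 0]) - min(w[:, 0])
    sy = max(w[:, 1]) - min(w[:, 1])
    return "immobile" if (sx < pixel_size and sy < pixel_size) else "mobile"


class TestClassifier:
    def test_static_track_is_immobile(self):
        t = make_track(np.tile([1.0, 2.0], (8, 1)))
        assert classify_mobility(t).mobility_class == "immobile"

    def test_steady_drift_is_mobile(self):
        xy = np.c_[1.0 + 0.05 * np.arange(10), np.full(10, 2.0)]
        call = classify_mobility(make_track(xy))
        assert call.mobility_class == "mobile"
        assert call.span_x == pytest.approx(0.45)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="classification minimum"):
            classify_mobility(make_track(np.zeros((3, 2))))

    def test_span_just_below_pixel_is_immobile(self):
        xy = np.array([[0.0, 0.0], [0.159, 0.159]] * 3)
        assert classify_mobility(make_track(xy)).mobility_class == "immobile"
        xy = np.array([[0.0, 0.0], [0.161, 0.0]] * 3)
        assert classify_mobility(make_track(xy)).mobility_class == "mobile"

    def test_mixed_state_track_counts_as_mobile(self):
        # bound segment followed by free excursion: box exceeds one pixel
        xy = np.r_[np.tile([1.0, 1.0], (6, 1)),
                   np.tile([1.5, 1.0], (6, 1))]
        assert classify_mobility(make_track(xy)).mobility_class == "mobile"

    def test_equivalence_with_brute_force_on_mixed_population(self):
        tracks, _ = ground_truth_classes(
            n_particles=10_000, immobile_fraction=0.4, d_mobile=2.62e-2,
            loc_noise_sd=0.015, track_length_frames=12, seed=33)
        for t in tracks:
            assert classify_mobility(t).mobility_class == brute_force_class(t)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(5, 30), st.floats(0.0, 0.3), st.integers(0, 2**16))
    def test_classifier_matches_oracle_property(self, n, scale, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, scale * PX, (n, 2)), axis=0)
        t = make_track(xy)
        assert classify_mobility(t).mobility_class == brute_force_class(t)


class TestMSD:
    def test_stationary_track_msd_is_zero(self):
        msd = compute_msd(make_track(np.tile([3.0, 4.0], (10, 1))))
        assert np.allclose(msd.msd, 0.0)

    def test_ballistic_track_closed_form(self):
        # x = v t with v = 0.1 um/frame: msd(k dt) = (0.1 k)^2
        n, v = 12, 0.1
        xy = np.c_[v * np.arange(n), np.zeros(n)]
        msd = compute_msd(make_track(xy))
        k = np.arange(1, n)
        assert np.allclose(msd.msd, (v * k) ** 2, atol=1e-12)

    def test_two_point_track_single_lag(self):
        msd = compute_msd(make_track([[0.0, 0.0], [0.3, 0.4]]))
        assert msd.lags.shape == (1,)
        assert msd.msd[0] == pytest.approx(0.25)

    def test_pair_counts_decrease_with_lag(self):
        msd = compute_msd(make_track(np.random.default_rng(0).normal(size=(9, 2))))
        assert (np.diff(msd.n_pairs) < 0).all()


class TestEstimateD:
    def test_exact_on_noiseless_linear_msd(self):
        D = 2.62e-2
        lags = np.array([0.1, 0.2, 0.3, 0.4])
        from sporetrack.mobility import MSDCurve
        msd = MSDCurve(lags=lags, msd=4 * D * lags, n_pairs=np.arange(8, 4, -1))
        assert estimate_D(msd).D == pytest.approx(D, abs=1e-15)

    def test_zero_msd_gives_zero_D(self):
        from sporetrack.mobility import MSDCurve
        msd = MSDCurve(lags=np.arange(1, 5) * 0.1, msd=np.zeros(4),
                       n_pairs=np.arange(8, 4, -1))
        assert estimate_D(msd).D == 0.0

    def test_free_intercept_removes_constant_offset(self):
        D, c = 2.62e-2, 0.001
        lags = np.arange(1, 5) * 0.1
        from sporetrack.mobility import MSDCurve
        msd = MSDCurve(lags=lags, msd=4 * D * lags + c,
                       n_pairs=np.arange(8, 4, -1))
        est = estimate_D(msd, fit_mode="free_intercept")
        assert est.D == pytest.approx(D, abs=1e-12)
        assert est.intercept == pytest.approx(c, abs=1e-12)

    def test_too_few_lags_raises(self):
        from sporetrack.mobility import MSDCurve
        msd = MSDCurve(lags=np.array([0.1, 0.2]), msd=np.zeros(2),
                       n_pairs=np.array([2, 1]))
        with pytest.raises(ValueError, match="lags"):
            estimate_D(msd, n_lags=4)


class TestEstimatorRecovery:
    def test_noiseless_recovery_and_noise_bias_structure(self):
        # (a) noiseless 12-frame tracks: through-origin mean D within 5%
        # (b) localization noise biases through-origin estimates upward
        # (c) the free-intercept fit removes that bias
        D = 2.62e-2
        clean = simulate_filtered_tracks(
            n_particles=1000, immobile_fraction=0.0, d_mobile=D,
            loc_noise_sd=0.0, track_length_frames=12, seed=101)
        noisy = simulate_filtered_tracks(
            n_particles=1000, immobile_fraction=0.0, d_mobile=D,
            loc_noise_sd=0.04, mobile_loc_noise=True,
            track_length_frames=12, seed=101)
        mean_clean = population_table(clean)["D_um2_s"].mean()
        assert mean_clean == pytest.approx(D, rel=0.05)
        mean_noisy = population_table(noisy)["D_um2_s"].mean()
        # expected inflation: sigma^2 * sum(lag)/sum(lag^2) = 3.33 sigma^2
        assert mean_noisy - mean_clean > 2.0e-3
        mean_free = population_table(noisy, fit_mode="free_intercept")["D_um2_s"].mean()
        assert abs(mean_free - D) < abs(mean_noisy - D)
        assert mean_free == pytest.approx(D, rel=0.10)

    def test_immobile_fraction_recovery_within_5_points(self):
        for frac, D in ((0.315, 1.80e-2), (0.102, 2.87e-2)):
            tracks, _ = ground_truth_classes(
                n_particles=2000, immobile_fraction=frac, d_mobile=D,
                loc_noise_sd=0.015, track_length_frames=12, seed=55)
            s = summarize_population(tracks, n_bootstrap=50, seed=1)
            assert abs(s.immobile_fraction_pct - 100 * frac) < 5.0

    def test_recovered_fraction_monotone_in_true_fraction(self):
        recovered = []
        for i, frac in enumerate(np.linspace(0.0, 1.0, 6)):
            tracks, _ = ground_truth_classes(
                n_particles=1500, immobile_fraction=float(frac),
                d_mobile=1.8e-2, loc_noise_sd=0.015,
                track_length_frames=12, seed=200 + i)
            s = summarize_population(tracks, n_bootstrap=10, seed=1)
            recovered.append(s.immobile_fraction_pct)
        assert all(b >= a for a, b in zip(recovered, recovered[1:]))


class TestPopulationSummary:
    def test_all_stationary_population(self):
        tracks = [make_track(np.tile([i, i], (8, 1)), track_id=i)
                  for i in range(5)]
        s = summarize_population(tracks, n_bootstrap=20, seed=0)
        assert s.immobile_fraction_pct == 100.0
        assert s.mean_D is None and s.bootstrap_sd_D is None

    def test_identical_mobile_tracks_have_zero_bootstrap_sd(self):
        xy = np.c_[0.05 * np.arange(10), np.zeros(10)]
        tracks = [make_track(xy, track_id=i) for i in range(6)]
        s = summarize_population(tracks, n_bootstrap=100, seed=0)
        assert s.bootstrap_sd_D == pytest.approx(0.0, abs=1e-12)

    def test_two_track_bootstrap_sd_matches_exhaustive_enumeration(self):
        # resamples of {a, b} are {aa, ab, ba, bb}, equally likely; the sd
        # of the resample means is |b - a| / (2 sqrt(2))
        xy_a = np.c_[0.04 * np.arange(10), np.zeros(10)]
        xy_b = np.c_[0.08 * np.arange(10), np.zeros(10)]
        tracks = [make_track(xy_a, track_id=0), make_track(xy_b, track_id=1)]
        s = summarize_population(tracks, n_bootstrap=4000, seed=3)
        d = population_table(tracks)["D_um2_s"].to_numpy()
        exact = abs(d[1] - d[0]) / (2 * np.sqrt(2))
        assert s.bootstrap_sd_D == pytest.approx(exact, rel=0.05)

    def test_immobile_fraction_identity(self):
        tracks, classes = ground_truth_classes(
            n_particles=400, immobile_fraction=0.3, d_mobile=2.62e-2,
            loc_noise_sd=0.015, track_length_frames=12, seed=77)
        s = summarize_population(tracks, n_bootstrap=10, seed=0)
        assert s.immobile_fraction_pct == 100.0 * s.n_immobile / s.n_total


class TestComparePopulations:
    def summarize(self, frac, D, seed, n=800):
        tracks, _ = ground_truth_classes(
            n_particles=n, immobile_fraction=frac, d_mobile=D,
            loc_noise_sd=0.015, track_length_frames=12, seed=seed)
        return summarize_population(tracks, n_bootstrap=1000, seed=seed + 1)

    def test_identical_datasets_not_significant(self):
        a = self.summarize(0.3, 2.62e-2, seed=9)
        b = self.summarize(0.3, 2.62e-2, seed=9)
        r = compare_populations(a, b)
        assert r["p_mean_D"] == 1.0
        assert not r["significant_mean_D"]

    def test_distinct_diffusion_populations_flagged_significant(self):
        a = self.summarize(0.3, 1.80e-2, seed=10)
        b = self.summarize(0.3, 2.62e-2, seed=11)
        r = compare_populations(a, b)
        assert r["p_mean_D"] < 0.005 and r["significant_mean_D"]
        assert r["delta_mean_D"] < 0

    def test_disjoint_replicates_bounded_tail(self):
        a = self.summarize(0.05, 2.87e-2, seed=12)
        b = self.summarize(0.60, 1.80e-2, seed=13)
        r = compare_populations(a, b)
        assert r["p_immobile"] <= 2.0 / 1000

    def test_missing_replicates_raise(self):
        a = self.summarize(0.3, 2.62e-2, seed=14)
        b = self.summarize(0.3, 2.62e-2, seed=15)
        b.replicates_immobile_pct = None
        with pytest.raises(ValueError, match="replicates"):
            compare_populations(a, b)
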