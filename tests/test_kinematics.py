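"""Kinematic operations against closed forms and brute-force oracles."""

import numpy as np
import pytest

from asymtrack import kinematics
from asymtrack.io_tracks import Fate, ValidationError, EndEvent
from asymtrack.synthetic import MotionModel, simulate_track
from conftest import make_track, random_piecewise_track


class TestMaxBasal:
    def test_simple_maximum(self):
        tr = make_track([2, 6, 11, 9])
        assert kinematics.max_basal_position(tr) == (11.0, 10.0)

    def test_constant_track_earliest_tie(self):
        tr = make_track([4, 4, 4])
        assert kinematics.max_basal_position(tr) == (4.0, 0.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            tr = random_piecewise_track(rng)
            mb, t_mb = kinematics.max_basal_position(tr)
            best = max(zip(tr.depth, tr.t), key=lambda p: (p[0], -p[1]))
            assert (mb, t_mb) == best


class TestVelocity:
    def test_single_step(self):
        v, mean = kinematics.instantaneous_velocity(make_track([0, 5]))
        np.testing.assert_allclose(v, [1.0])
        assert mean == 1.0

    def test_constant_track_zero(self):
        v, mean = kinematics.instantaneous_velocity(make_track([3, 3, 3, 3]))
        assert mean == 0.0 and np.all(v == 0)

    def test_recovers_simulated_drift(self, rng):
        # pure basal drift with weak noise: per-step |displacement|/dt
        # concentrates on the drift speed
        drift = 0.12
        model = MotionModel(drift=drift, step_sd=0.02, persistence=0.0, tissue_thickness=500.0)
        means = [
            kinematics.instantaneous_velocity(
                simulate_track(model, 200.0, 5.0, 10.0, rng, track_id=f"s{i}")
            )[1]
            for i in range(100)
        ]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - drift) < max(3 * se, 5e-3)

    def test_planar_uses_euclidean_displacement(self):
        tr = make_track([0, 3], t=[0, 5], x=[0, 4], y=[0, 0])
        _, mean_depth = kinematics.instantaneous_velocity(tr, use_planar=False)
        _, mean_planar = kinematics.instantaneous_velocity(tr, use_planar=True)
        assert mean_depth == pytest.approx(3 / 5)
        assert mean_planar == pytest.approx(5 / 5)


class TestMsd:
    def test_stationary_is_zero(self):
        curve = kinematics.msd(make_track(np.full(21, 8.0)), window=100)
        assert np.all(curve.msd == 0) and np.all(curve.n_pairs >= 2)

    def test_ballistic_closed_form(self):
        v = 1.0
        t = np.arange(0, 105, 5.0)
        curve = kinematics.msd(make_track(v * t, t=t), window=100)
        np.testing.assert_allclose(curve.msd, (v * curve.lags) ** 2, rtol=1e-12)

    def test_window_restricts_samples(self):
        t = np.arange(0, 300, 5.0)
        curve = kinematics.msd(make_track(t * 0.5, t=t), window=100)
        assert curve.lags.max() <= 100

    def test_random_walk_slope_recovery(self, rng):
        # unbiased 1-D walk, per-step sd sigma over dt: MSD(k dt) = k sigma^2,
        # so the slope vs lag in minutes is sigma^2/dt
        sigma, dt = 1.0, 5.0
        model = MotionModel(
            drift=0.0, step_sd=sigma / np.sqrt(dt), persistence=0.0, tissue_thickness=10000.0
        )
        curves = [
            kinematics.msd(
                simulate_track(model, 100.0, dt, 5000.0, rng, track_id=f"w{i}"), window=100
            )
            for i in range(200)
        ]
        lags = curves[0].lags
        mean_msd = np.mean([c.msd for c in curves], axis=0)
        slope = np.polyfit(lags, mean_msd, 1)[0]
        assert abs(slope - sigma**2 / dt) / (sigma**2 / dt) < 0.15

    def test_too_few_samples_in_window(self):
        tr = make_track([0, 1, 2], t=[0, 150, 300])
        with pytest.raises(ValidationError):
            kinematics.msd(tr, window=100)


class TestDirectionality:
    def test_monotone_path_is_one(self):
        curve = kinematics.directionality_ratio(make_track([0, 2, 5, 9]))
        np.testing.assert_allclose(curve.ratio, 1.0)

    def test_full_backtrack_ends_at_zero(self):
        curve = kinematics.directionality_ratio(make_track([0, 10, 0]))
        assert curve.ratio[-1] == 0.0

    def test_bounded_and_translation_invariant(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 25))
            t = np.arange(n) * 5.0
            x = rng.uniform(0, 50, n)
            y = rng.uniform(0, 50, n)
            d = rng.uniform(0, 50, n)
            tr = make_track(d, t=t, x=x, y=y)
            curve = kinematics.directionality_ratio(tr, use_planar=True)
            assert np.all((curve.ratio >= 0) & (curve.ratio <= 1 + 1e-12))
            dx, dy = rng.uniform(-30, 30, 2)
            shifted = make_track(d, t=t, x=x + dx, y=y + dy)
            curve2 = kinematics.directionality_ratio(shifted, use_planar=True)
            np.testing.assert_allclose(curve.ratio, curve2.ratio, atol=1e-12)

    def test_zero_path_defined_as_one(self):
        curve = kinematics.directionality_ratio(make_track([5, 5, 7]))
        assert curve.ratio[0] == 1.0


class TestIntegralMean:
    def test_constant_depth(self):
        d_hat, I, T = kinematics.integral_mean(make_track([7, 7, 7], t=[0, 10, 30]))
        assert (d_hat, I, T) == (7.0, 210.0, 30.0)

    def test_linear_ramp_is_half(self):
        d_hat, _, _ = kinematics.integral_mean(make_track([0, 20], t=[0, 50]))
        assert d_hat == pytest.approx(10.0)

    def test_against_riemann_oracle(self, rng):
        # midpoint Riemann sum on a fine grid, written independently of the
        # trapezoid implementation
        for _ in range(200):
            tr = random_piecewise_track(rng)
            d_hat, _, T = kinematics.integral_mean(tr)
            n_sub = 10_000
            h = T / n_sub
            mids = tr.t[0] + (np.arange(n_sub) + 0.5) * h
            oracle = np.sum(np.interp(mids, tr.t, tr.depth)) * h / T
            assert abs(d_hat - oracle) / abs(oracle) < 1e-6

    def test_bounded_by_depth_range(self, rng):
        for _ in range(50):
            tr = random_piecewise_track(rng)
            d_hat, _, _ = kinematics.integral_mean(tr)
            assert tr.depth.min() - 1e-12 <= d_hat <= tr.depth.max() + 1e-12

    def test_refinement_invariance(self, rng):
        # inserting interpolated samples must not change the integral mean
        tr = random_piecewise_track(rng)
        t_fine = np.unique(np.concatenate([tr.t, np.linspace(tr.t[0], tr.t[-1], 137)]))
        fine = make_track(np.interp(t_fine, tr.t, tr.depth), t=t_fine)
        a, _, _ = kinematics.integral_mean(tr)
        b, _, _ = kinematics.integral_mean(fine)
        assert a == pytest.approx(b, rel=1e-12)


class TestSummarize:
    def test_composition_matches_components(self, rng):
        for i in range(20):
            tr = random_piecewise_track(rng, track_id=f"c{i}")
            s = kinematics.summarize_track(tr, window=100)
            assert (s.max_basal, s.t_max_basal) == kinematics.max_basal_position(tr)
            assert s.mean_inst_velocity == kinematics.instantaneous_velocity(tr)[1]
            d_hat, I, T = kinematics.integral_mean(tr)
            assert (s.integral_mean, s.integral_area, s.duration) == (d_hat, I, T)
            np.testing.assert_array_equal(s.msd.msd, kinematics.msd(tr, window=100).msd)

    def test_censored_flag_propagates(self):
        tr = make_track(np.arange(21.0), end_event=EndEvent.CENSORED)
        s = kinematics.summarize_track(tr)
        assert s.censored and np.isfinite(s.integral_mean)

    def test_batch_matches_per_track(self, rng):
        tracks = [random_piecewise_track(rng, track_id=f"b{i}") for i in range(10)]
        scalar, _, _ = kinematics.summarize_tracks(tracks, window=100)
        for tr, (_, row) in zip(tracks, scalar.iterrows()):
            s = kinematics.summarize_track(tr, window=100)
            assert row["max_basal_um"] == s.max_basal
            assert row["integral_mean_um"] == s.integral_mean
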