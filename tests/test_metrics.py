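import numpy as np
import pytest

import anemotax as ax
from anemotax.angles import wrap_deg
from conftest import make_track, rotate_trackset


def static_trackset(cfg, positions, n_frames=60, headings=None, schedule=None):
    """TrackSet of stationary flies at given (x, y) positions."""
    tracks = []
    for i, (x, y) in enumerate(positions):
        h = 0.0 if headings is None else headings[i]
        tracks.append(
            make_track([x] * n_frames, [y] * n_frames, [h] * n_frames, fly_id=f"f{i}")
        )
    return ax.TrackSet(tracks=tracks, cfg=cfg, schedule=schedule or ax.EpochSchedule())


def brute_force_return(track, k0, window_frames, away_mm, back_mm):
    """Literal per-frame transcription of the revisit definition."""
    x0, y0 = track.x_mm[k0], track.y_mm[k0]
    went_away = False
    for k in range(k0 + 1, min(k0 + 1 + window_frames, len(track))):
        d = np.hypot(track.x_mm[k] - x0, track.y_mm[k] - y0)
        if went_away and d <= back_mm:
            return True
        if d > away_mm:
            went_away = True
    return False


class TestUpwindDisplacement:
    def test_stationary_flies_give_zero(self, cfg, led_schedule):
        ts = static_trackset(cfg, [(10, 0), (0, 20)], n_frames=900, schedule=led_schedule)
        t, delta, end = ax.upwind_displacement(ts, led_schedule.first, at_s=5.0)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)
        assert end == pytest.approx([0.0])

    def test_center_to_wall_is_plus_one(self, cfg, led_schedule):
        # every fly walks from r=0 at onset to r=R by onset + 10 s
        fps, onset = cfg.frame_rate_hz, led_schedule.first.effective_onset_s
        n = int(31 * fps)
        t = np.arange(n) / fps
        r = np.clip((t - onset) / 10.0, 0.0, 1.0) * cfg.radius_mm
        tracks = [
            make_track(r * np.cos(a), r * np.sin(a), np.zeros(n), fly_id=f"f{i}")
            for i, a in enumerate([0.3, 2.0])
        ]
        ts = ax.TrackSet(tracks=tracks, cfg=cfg, schedule=led_schedule)
        _, _, end = ax.upwind_displacement(ts, led_schedule.first, at_s=10.0)
        assert end == pytest.approx([1.0])

    def test_positive_gain_drives_positive_displacement(self, cfg, led_schedule):
        wins = 0
        for seed in range(10):
            p = ax.SimParams(n_flies=20, upwind_turn_gain=3.0, seed=seed)
            ts = ax.simulate(p, cfg, led_schedule)
            _, _, end = ax.upwind_displacement(ts, led_schedule.first, at_s=10.0)
            wins += end[0] > 0
        assert wins >= 9

    def test_no_valid_flies_at_onset_errors(self, cfg, led_schedule):
        ts = static_trackset(cfg, [(10, 0)], n_frames=900, schedule=led_schedule)
        ts.tracks[0].valid[:] = False
        with pytest.raises(ValueError, match="onset"):
            ax.upwind_displacement(ts, led_schedule.first)


class TestMeanCosUpwind:
    def test_all_facing_upwind(self, cfg, led_schedule):
        # heading = outward bearing at each position
        ts = static_trackset(
            cfg, [(10, 0), (0, 20)], headings=[0.0, 90.0], schedule=led_schedule
        )
        _, series = ax.mean_cos_upwind(ts, led_schedule.first)
        np.testing.assert_allclose(series, 1.0, atol=1e-12)

    def test_all_facing_center(self, cfg, led_schedule):
        ts = static_trackset(
            cfg, [(10, 0), (0, 20)], headings=[180.0, -90.0], schedule=led_schedule
        )
        _, series = ax.mean_cos_upwind(ts, led_schedule.first)
        np.testing.assert_allclose(series, -1.0, atol=1e-12)

    def test_uniform_headings_average_near_zero(self, cfg):
        rng = np.random.default_rng(0)
        n = 2000
        pos = ax.uniform_positions(n, cfg, seed=1)
        ts = static_trackset(
            cfg, pos, n_frames=2, headings=rng.uniform(-180, 180, n)
        )
        _, series = ax.mean_cos_upwind(ts)
        assert abs(series.mean()) < 3 / np.sqrt(2 * n)

    def test_wind_off_not_available(self, cfg):
        import dataclasses

        off = dataclasses.replace(cfg, wind_mode="off")
        ts = static_trackset(off, [(10, 0)])
        with pytest.raises(ValueError, match="wind"):
            ax.mean_cos_upwind(ts)


class TestCumulativeTurn:
    def _spiral(self, alpha0, step_deg, x=10.0, y=0.0, n=15):
        # fly at (x, y): upwind bearing 0 deg; heading chosen to give alpha0
        h0 = wrap_deg(-alpha0)
        headings = wrap_deg(h0 + step_deg * np.arange(n))
        return make_track([x] * n, [y] * n, headings)

    def test_turn_toward_upwind_from_negative_alpha(self, cfg):
        tr = self._spiral(alpha0=-120.0, step_deg=-10.0)
        rec = ax.cumulative_turn(tr, 0.0, cfg)
        assert rec["signed_deg"] == pytest.approx(-100.0)
        assert rec["toward_upwind_deg"] == pytest.approx(100.0)

    def test_turn_away_from_positive_alpha(self, cfg):
        tr = self._spiral(alpha0=120.0, step_deg=-10.0)
        rec = ax.cumulative_turn(tr, 0.0, cfg)
        assert rec["signed_deg"] == pytest.approx(-100.0)
        assert rec["toward_upwind_deg"] == pytest.approx(-100.0)

    def test_constant_heading_is_zero(self, cfg):
        tr = self._spiral(alpha0=-120.0, step_deg=0.0)
        rec = ax.cumulative_turn(tr, 0.0, cfg)
        assert rec["signed_deg"] == 0.0 and rec["toward_upwind_deg"] == 0.0

    def test_facing_upwind_folds_to_zero(self, cfg):
        tr = self._spiral(alpha0=0.0, step_deg=-10.0)
        assert ax.cumulative_turn(tr, 0.0, cfg)["toward_upwind_deg"] == 0.0

    def test_insufficient_frames_rejected(self, cfg):
        tr = self._spiral(alpha0=-120.0, step_deg=0.0, n=5)
        with pytest.raises(ValueError, match="valid frames"):
            ax.cumulative_turn(tr, 0.0, cfg)


class TestBinnedOnsetResponse:
    def test_constant_metric_gives_flat_curve(self):
        recs = [{"alpha0_deg": a, "signed_deg": 7.5} for a in np.linspace(-170, 170, 35)]
        curve = ax.binned_onset_response(recs)
        assert np.nanmax(curve.metric_mean) == pytest.approx(7.5)
        assert np.nanmin(curve.metric_mean) == pytest.approx(7.5)

    def test_single_fly_defined_only_near_its_angle(self):
        curve = ax.binned_onset_response([{"alpha0_deg": 0.0, "signed_deg": 3.0}])
        near = np.abs(curve.initial_angle_grid_deg) <= 30
        assert np.all(curve.metric_mean[near] == 3.0)
        assert np.all(np.isnan(curve.metric_mean[~near]))
        assert curve.n_per_bin[~near].sum() == 0

    def test_sinusoidal_response_recovered(self, cfg, led_schedule):
        from scipy.optimize import curve_fit

        gain, recs = 3.0, []
        for seed in range(20):
            p = ax.SimParams(n_flies=20, upwind_turn_gain=gain, startle_gain_deg=0.0, seed=seed)
            ts = ax.simulate(p, cfg, led_schedule, movie_id=f"m{seed}")
            recs += ax.onset_turn_metrics(ts, ts.schedule.first)
        assert len(recs) >= 300
        curve = ax.binned_onset_response(recs, "signed_deg")
        ok = ~np.isnan(curve.metric_mean)
        (amp,), _ = curve_fit(
            lambda a, A: A * np.sin(a),
            np.deg2rad(curve.initial_angle_grid_deg[ok]),
            curve.metric_mean[ok],
        )
        assert amp == pytest.approx(gain * 10, rel=0.10)


class TestReturnProbability:
    def _one(self, cfg, x, schedule=None):
        tr = make_track(x, np.zeros(len(x)), np.zeros(len(x)))
        return ax.TrackSet(tracks=[tr], cfg=cfg, schedule=schedule or ax.EpochSchedule())

    def test_excursion_and_return_inside_window(self, cfg):
        fps = int(cfg.frame_rate_hz)
        x = np.zeros(20 * fps)
        x[5 * fps] = 12.0  # out to 12 mm at +5 s
        # back near 0 afterwards -> return at time0=0
        profile = ax.return_probability(self._one(cfg, x))
        assert profile.p_return[0] == 1.0

    def test_return_outside_window_misses(self, cfg):
        fps = int(cfg.frame_rate_hz)
        x = np.full(40 * fps, 12.0)
        x[0] = 0.0
        x[16 * fps :] = 2.0  # comes back only at +16 s
        profile = ax.return_probability(self._one(cfg, x))
        assert profile.p_return[0] == 0.0

    def test_never_leaving_is_not_a_return(self, cfg):
        fps = int(cfg.frame_rate_hz)
        x = 9.0 * np.abs(np.sin(np.arange(20 * fps) / fps))
        profile = ax.return_probability(self._one(cfg, x))
        np.testing.assert_array_equal(profile.p_return, 0.0)

    def test_time0_grid_spans_0_to_45s_for_60s_movie(self, cfg, null_trackset):
        profile = ax.return_probability(null_trackset)
        assert profile.time0_s[0] == 0.0
        assert profile.time0_s[-1] == pytest.approx(45.0, abs=1 / cfg.frame_rate_hz)

    def test_window_longer_than_movie_rejected(self, cfg):
        ts = self._one(cfg, np.zeros(30))
        with pytest.raises(ValueError, match="longer"):
            ax.return_probability(ts)

    def test_monotone_in_window_and_away_threshold(self, cfg, led_schedule):
        p = ax.SimParams(n_flies=20, duration_s=40.0, return_gain=4.0, seed=21)
        ts = ax.simulate(p, cfg, led_schedule)
        grids = {
            w: ax.return_probability(ts, window_s=w, grid_step_frames=15).p_return
            for w in (5.0, 10.0, 15.0)
        }
        n = len(grids[15.0])
        assert np.all(grids[5.0][:n] <= grids[10.0][:n] + 1e-12)
        assert np.all(grids[10.0][:n] <= grids[15.0][:n] + 1e-12)
        p_strict = ax.return_probability(ts, away_mm=14.0, grid_step_frames=15).p_return
        p_loose = ax.return_probability(ts, away_mm=10.0, grid_step_frames=15).p_return
        assert np.all(p_strict <= p_loose + 1e-12)

    def test_matches_brute_force_on_synthetic_tracks(self, cfg, led_schedule):
        p = ax.SimParams(n_flies=25, duration_s=12.0, return_gain=3.0, seed=8)
        ts = ax.simulate(p, cfg, led_schedule)
        away, back, window = 6.0, 3.0, 2.0
        wf = int(round(window * cfg.frame_rate_hz))
        profile = ax.return_probability(
            ts, away_mm=away, back_mm=back, window_s=window, grid_step_frames=7
        )
        k0s = np.round(profile.time0_s * cfg.frame_rate_hz).astype(int)
        for j, k0 in enumerate(k0s):
            expected = np.mean(
                [brute_force_return(tr, k0, wf, away, back) for tr in ts]
            )
            assert profile.p_return[j] == pytest.approx(expected)


class TestPreferenceIndex:
    def test_balanced_quadrants_give_zero(self, cfg):
        ts = static_trackset(cfg, [(10, 0), (0, 10), (-10, 0), (0, -10)])
        assert ax.preference_index(ts).pi == pytest.approx(0.0)

    def test_all_in_odor_one_quadrants(self, cfg):
        ts = static_trackset(cfg, [(10, 0), (-10, 0), (12, 2)])
        assert ax.preference_index(ts).pi == pytest.approx(1.0)

    def test_fifteen_vs_five_split_is_half(self, cfg):
        pos = [(10, 0)] * 8 + [(-10, 0)] * 7 + [(0, 10)] * 3 + [(0, -10)] * 2
        assert ax.preference_index(static_trackset(cfg, pos)).pi == pytest.approx(0.5)

    def test_antisymmetric_under_quadrant_swap(self, cfg, null_trackset):
        pi_a = ax.preference_index(null_trackset, odor_one_quadrants=(0, 2))
        pi_b = ax.preference_index(null_trackset, odor_one_quadrants=(1, 3))
        assert pi_a.pi == pytest.approx(-pi_b.pi)

    def test_non_diagonal_pair_rejected(self, cfg, null_trackset):
        with pytest.raises(ValueError, match="diagonal"):
            ax.preference_index(null_trackset, odor_one_quadrants=(0, 1))

    def test_uniform_placement_expects_zero(self, cfg):
        pis = []
        for seed in range(30):
            pos = ax.uniform_positions(20, cfg, seed=seed)
            pis.append(ax.preference_index(static_trackset(cfg, pos)).pi)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis)) < 3 * max(se, 1e-3)


class TestReciprocalAverage:
    def _pref(self, pi, window=(30.0, 60.0)):
        return ax.PreferenceResult(pi=pi, window_s=window)

    def test_aligned_mean_toward_cs_plus(self):
        # reciprocal run reported +0.2 toward CS+, i.e. -0.2 toward the
        # fixed odor-one quadrant pair
        res = ax.reciprocal_average(self._pref(0.4), self._pref(-0.2))
        assert res.reciprocal_mean == pytest.approx(0.3)

    def test_pure_position_bias_cancels(self, cfg):
        rng = np.random.default_rng(5)
        means = []
        for _ in range(25):
            # both reciprocal runs share the same spatial bias, no learning
            theta = np.where(rng.random(20) < 0.65, rng.uniform(-np.pi / 4, np.pi / 4, 20),
                             rng.uniform(-np.pi, np.pi, 20))
            r = 40 * np.sqrt(rng.random(20))
            pos_a = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            theta = np.where(rng.random(20) < 0.65, rng.uniform(-np.pi / 4, np.pi / 4, 20),
                             rng.uniform(-np.pi, np.pi, 20))
            pos_b = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            pi_a = ax.preference_index(static_trackset(cfg, pos_a))
            pi_b = ax.preference_index(static_trackset(cfg, pos_b))
            means.append(ax.reciprocal_average(pi_a, pi_b).reciprocal_mean)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se

    def test_zero_inputs_give_zero(self):
        assert ax.reciprocal_average(self._pref(0.0), self._pref(0.0)).reciprocal_mean == 0.0

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ax.reciprocal_average(self._pref(0.1), self._pref(0.1, window=(0.0, 30.0)))


class TestLearningRate:
    @pytest.mark.parametrize("a, b, expected", [(0.05, 0.20, 0.25), (0.2, 0.2, 1.0), (0, 0.2, 0.0)])
    def test_ratio(self, a, b, expected):
        assert ax.learning_rate(a, b) == pytest.approx(expected)

    def test_zero_peak_flagged(self):
        with pytest.raises(ZeroDivisionError):
            ax.learning_rate(0.1, 0.0)


class TestRotationInvariance:
    def test_population_metrics_unchanged_by_arena_rotation(self, cfg, upwind_trackset):
        epoch = upwind_trackset.schedule.first
        rotated = rotate_trackset(upwind_trackset, -141.0)
        t0, d0 = ax.upwind_displacement(upwind_trackset, epoch)
        _, d1 = ax.upwind_displacement(rotated, epoch)
        np.testing.assert_allclose(d1, d0, atol=1e-9)
        _, c0 = ax.mean_cos_upwind(upwind_trackset, epoch)
        _, c1 = ax.mean_cos_upwind(rotated, epoch)
        np.testing.assert_allclose(c1, c0, atol=1e-9)
        p0 = ax.return_probability(upwind_trackset, grid_step_frames=30)
        p1 = ax.return_probability(rotated, grid_step_frames=30)
        np.testing.assert_allclose(p1.p_return, p0.p_return, atol=1e-12)
        r0 = ax.onset_turn_metrics(upwind_trackset, epoch)
        r1 = ax.onset_turn_metrics(rotated, epoch)
        assert len(r0) == len(r1)
        for a, b in zip(r0, r1):
            assert b["signed_deg"] == pytest.approx(a["signed_deg"], abs=1e-9)
            assert b["toward_upwind_deg"] == pytest.approx(a["toward_upwind_deg"], abs=1e-9)
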