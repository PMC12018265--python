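"""Group inference: event-locked averages, cluster and latency tests,
behavior regressions, route adherence."""

import numpy as np
import pytest

from thetanav import stats
from thetanav.synth import make_route_template


class TestTurnAlignedAverage:
    def test_pulse_at_each_event_peaks_at_zero_lag(self):
        fs = 50.0
        x = np.zeros(int(100 * fs))
        events = np.arange(5.0, 95.0, 5.0)
        for e in events:
            x[int(e * fs)] = 1.0
        lags, avg = stats.turn_aligned_average(x, fs, events, window_s=1.0)
        assert lags[np.argmax(avg)] == pytest.approx(0.0)

    def test_random_events_flat(self):
        fs = 50.0
        rng = np.random.default_rng(0)
        x = 1.0 + 0.3 * np.sin(np.arange(int(400 * fs)) / 17)
        events = rng.uniform(5, 395, 200)
        _, avg = stats.turn_aligned_average(x, fs, events, window_s=1.5)
        assert avg.max() / avg.min() < 1.5

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            stats.turn_aligned_average(np.zeros(100), 50.0, np.array([]), 1.0)


class TestClusterSignflip:
    def test_reduces_to_pointwise_when_p_cluster_one(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((10, 60))
        res = stats.cluster_signflip_test(maps, n_perm=200, p_cluster=1.0, seed=0)
        np.testing.assert_array_equal(res.mask, res.primary_mask)

    def test_common_deflection_one_big_cluster(self):
        rng = np.random.default_rng(2)
        maps = 0.3 * rng.standard_normal((12, 80))
        maps[:, 30:50] += 2.0
        res = stats.cluster_signflip_test(maps, n_perm=200, seed=1)
        assert res.mask[30:50].all()
        big = int(np.argmax(res.cluster_sizes))
        assert res.cluster_p[big] == pytest.approx(1 / 201)

    def test_single_channel_effect_usually_not_significant(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            maps = rng.standard_normal((18, 60))
            maps[0, 20:40] += 3.0
            res = stats.cluster_signflip_test(maps, n_perm=150, seed=s)
            hits += res.mask[20:40].any()
        assert hits <= 3

    def test_2d_maps_supported(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((10, 12, 30))
        maps[:, 4:8, 10:20] += 2.5
        res = stats.cluster_signflip_test(maps, n_perm=150, seed=0)
        assert res.mask[5, 15]


class TestPeakLatency:
    def _series_with_offset(self, offset_s, fs=50.0, n_channels=10):
        x = np.zeros((n_channels, int(300 * fs)))
        turns = np.arange(10.0, 290.0, 10.0)
        for c in range(n_channels):
            for t in turns:
                i = int((t + offset_s[c]) * fs)
                x[c, i - 8:i + 9] += np.hanning(17)   # odd: peak exactly on-grid
        return x, turns

    def test_bouts_at_turns_no_latency_effect(self):
        x, turns = self._series_with_offset(np.zeros(10))
        parts = np.repeat(np.arange(5), 2)
        res = stats.peak_latency_test(x, 50.0, turns, 2.0, parts,
                                      n_perm=400, seed=0)
        assert abs(res.observed) < 0.05
        assert res.p > 0.05

    def test_early_bouts_detected(self):
        x, turns = self._series_with_offset(np.full(10, -0.9))
        parts = np.repeat(np.arange(5), 2)
        res = stats.peak_latency_test(x, 50.0, turns, 2.0, parts,
                                      n_perm=400, seed=0)
        assert res.observed == pytest.approx(-0.9, abs=0.05)
        assert res.p < 0.05

    def test_mixed_offsets_cancel(self):
        off = np.array([-0.9, 0.9] * 5)
        x, turns = self._series_with_offset(off)
        parts = np.repeat(np.arange(5), 2)
        res = stats.peak_latency_test(x, 50.0, turns, 2.0, parts,
                                      n_perm=400, seed=0)
        assert res.p > 0.05


class TestBehaviorTheta:
    def test_shifted_copy_peaks_at_negative_lag(self):
        """theta leading behavior by 0.5 s puts the lag-profile peak at -0.5."""
        fs = 50.0
        rng = np.random.default_rng(4)
        T = int(20 * fs)
        theta = np.empty((1, 6, T))
        beh = np.empty((6, T))
        for k in range(6):
            base = np.convolve(rng.standard_normal(T + 100),
                               np.hanning(25), "same")[:T]
            theta[0, k] = base
            beh[k] = np.roll(base, int(0.5 * fs))
        out = stats.behavior_theta_analysis(theta, {"speed": beh}, fs,
                                            participants=np.array([0]),
                                            max_lag_s=2.0, n_perm=50, seed=0)
        prof = out["lag_profiles"]["speed"][0]
        peak_lag = out["lags_s"][np.argmax(prof)]
        assert peak_lag == pytest.approx(-0.5, abs=0.1)

    def test_constant_variable_dropped(self):
        fs = 50.0
        theta = np.random.default_rng(5).standard_normal((2, 4, 200))
        with pytest.warns(UserWarning):
            out = stats.behavior_theta_analysis(
                theta, {"flat": np.ones((4, 200)),
                        "ok": np.random.default_rng(6).standard_normal((4, 200))},
                fs, participants=np.array([0, 0]), n_perm=50, seed=0)
        assert out["coefficient_names"] == ["ok"]

    def test_independent_noise_coefficients_null(self):
        fs = 50.0
        ps = []
        for s in range(15):
            rng = np.random.default_rng(s)
            theta = rng.standard_normal((6, 5, 150))
            beh = {"speed": rng.standard_normal((5, 150)),
                   "yaw": rng.standard_normal((5, 150))}
            out = stats.behavior_theta_analysis(
                theta, beh, fs, participants=np.array([0, 0, 1, 1, 2, 2]),
                n_perm=100, seed=s)
            ps.extend(out["p_corrected"].values())
        assert np.mean(np.array(ps) <= 0.05) < 0.2


class TestRouteRmse:
    def test_on_polyline_zero(self):
        route = make_route_template(4, "left", 1)
        assert stats.route_rmse(route.vertices, route) == 0.0

    def test_uniform_lateral_offset(self):
        route = make_route_template(1, "left", 0)
        # points offset perpendicular to the first (axis-aligned) segment
        seg_dir = route.vertices[1] - route.vertices[0]
        normal = np.array([-seg_dir[1], seg_dir[0]])
        normal /= np.linalg.norm(normal)
        mid = route.vertices[0] + 0.3 * seg_dir
        pts = mid[None, :] + 0.5 * normal[None, :]
        assert stats.route_rmse(pts, route) == pytest.approx(0.5, abs=1e-9)

    def test_empty_rejected(self):
        route = make_route_template(4, "left", 1)
        with pytest.raises(ValueError):
            stats.route_rmse(np.zeros((0, 2)), route)

    def test_rmse_increases_with_jitter(self):
        from thetanav.synth import SynthConfig, simulate_trajectory
        route = make_route_template(4, "left", 2)
        vals = []
        for j in (0.0, 0.1, 0.3):
            cfg = SynthConfig(pos_jitter=j).resolve()
            tr = simulate_trajectory(route, cfg, trial_seed=1)
            vals.append(stats.route_rmse(tr.xy, route))
        assert vals[0] < vals[1] < vals[2]


class TestDeterminism:
    def test_permutation_engines_honor_seed(self):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((8, 40))
        a = stats.cluster_signflip_test(maps, n_perm=100, seed=5)
        b = stats.cluster_signflip_test(maps, n_perm=100, seed=5)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.cluster_p == b.cluster_p


class TestPhaseSelectiveRegression:
    def test_phase_coefficient_found_speed_not(self):
        """When amplitude depends only on route phase, the joint regression
        flags the phase regressor and not the kinematic ones."""
        fs = 50.0
        rng = np.random.default_rng(11)
        T = 500
        phi = np.tile(np.linspace(0, 2 * np.pi, 100, endpoint=False), 5)
        n_trials, C = 8, 6
        theta = np.empty((C, n_trials, T))
        beh = {"est_phase": np.empty((n_trials, T)),
               "speed": rng.standard_normal((n_trials, T)),
               "hip_yaw_vel": rng.standard_normal((n_trials, T))}
        for k in range(n_trials):
            beh["est_phase"][k] = -np.sin(phi)
            for c in range(C):
                theta[c, k] = -np.sin(phi) + 0.5 * rng.standard_normal(T)
        out = stats.behavior_theta_analysis(
            theta, beh, fs, participants=np.array([0, 0, 1, 1, 2, 2]),
            max_lag_s=1.0, n_perm=300, seed=0)
        assert out["p_corrected"]["est_phase"] <= 0.05
        assert out["p_corrected"]["speed"] > 0.05
        assert out["p_corrected"]["hip_yaw_vel"] > 0.05
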