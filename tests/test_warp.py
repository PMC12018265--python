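"""Time-warping: DTW paths, piecewise-linear warps, segment normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetanav import warp
from thetanav.synth import SynthConfig, make_route_template, simulate_trajectory


class TestDtwCore:
    def test_identical_sequences_identity_path(self):
        x = np.random.default_rng(0).standard_normal((50, 2))
        d, pi, pj = warp.dtw_path(x, x)
        assert d < 1e-12
        np.testing.assert_array_equal(pi, pj)

    def test_path_monotone_and_pinned(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((40, 2)), rng.standard_normal((55, 2))
        _, pi, pj = warp.dtw_path(a, b)
        assert pi[0] == 0 and pj[0] == 0
        assert pi[-1] == 39 and pj[-1] == 54
        assert np.all(np.diff(pi) >= 0) and np.all(np.diff(pj) >= 0)

    def test_banded_equals_unbanded_when_band_wide(self):
        rng = np.random.default_rng(2)
        a = np.cumsum(rng.standard_normal(60))
        b = np.mod(a + 0.2, 2 * np.pi)
        a = np.mod(a, 2 * np.pi)
        d1, *_ = warp.dtw_path(a, b, metric="sq_circular", band=100)
        d2, *_ = warp.dtw_path(a, b, metric="sq_circular", band=-1)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestTrajectoryAlignment:
    def test_identical_trials_equal_anchors(self):
        cfg = SynthConfig(pos_jitter=0.0).resolve()
        route = make_route_template(4, "left", seed=2)
        tr = simulate_trajectory(route, cfg, trial_seed=0)
        anchors, medoid = warp.dtw_align_trajectories([tr, tr, tr], route)
        for a in anchors[1:]:
            np.testing.assert_allclose(a, anchors[0], atol=1e-9)

    def test_uniformly_slower_trial_scales_anchors(self):
        cfg = SynthConfig(pos_jitter=0.0).resolve()
        route = make_route_template(4, "left", seed=2)
        tr = simulate_trajectory(route, cfg, trial_seed=0)

        class _Slow:
            t = tr.t * 1.1
            xy = tr.xy
            duration = tr.duration * 1.1
        anchors, _ = warp.dtw_align_trajectories([tr, tr, _Slow()], route)
        ratio = anchors[2][1:-1] / anchors[0][1:-1]
        np.testing.assert_allclose(ratio, 1.1, atol=0.03)

    def test_short_trial_dropped(self):
        cfg = SynthConfig().resolve()
        route = make_route_template(4, "left", seed=2)
        tr = simulate_trajectory(route, cfg, trial_seed=0)

        class _Stub:
            t = tr.t[:len(tr.t) // 4]
            xy = tr.xy[:len(tr.t) // 4]
            duration = tr.duration / 4
        with pytest.warns(UserWarning):
            anchors, _ = warp.dtw_align_trajectories([tr, tr, _Stub()], route)
        assert anchors[2] is None

    def test_known_distortion_recovered(self):
        cfg = SynthConfig(rng_seed=3, seg_length_range=(3.0, 4.0)).resolve()
        route = make_route_template(4, "left", 3)
        trajs = [simulate_trajectory(route, cfg, trial_seed=i) for i in range(10)]
        anchors, _ = warp.dtw_align_trajectories(trajs, route)
        errs = [np.abs(a[1:-1] - tr.turn_times).mean()
                for a, tr in zip(anchors, trajs)]
        assert np.mean(errs) < 0.1


class TestPiecewiseLinearWarp:
    def test_identity(self):
        t = np.arange(100) / 10
        x = np.sin(t)
        a = np.array([0.0, 4.0, 9.9])
        out = warp.piecewise_linear_warp(x, t, a, a, t_out=t)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_uniform_stretch_halves_slope(self):
        t = np.arange(101) / 10.0
        ramp = 2.0 * t
        out = warp.piecewise_linear_warp(ramp, t, np.array([0.0, 10.0]),
                                         np.array([0.0, 20.0]))
        t2 = np.arange(0, 20.05, 0.1)
        np.testing.assert_allclose(out, t2, atol=1e-9)

    def test_round_trip(self):
        t = np.arange(400) / 40.0
        x = np.sin(2 * np.pi * 0.4 * t) + 0.5 * np.cos(2 * np.pi * 0.9 * t)
        src = np.array([0.0, 3.0, 6.5, 9.975])
        dst = np.array([0.0, 4.0, 5.5, 9.975])
        fwd = warp.piecewise_linear_warp(x, t, src, dst, t_out=t)
        back = warp.piecewise_linear_warp(fwd, t, dst, src, t_out=t)
        core = slice(5, -5)
        assert np.max(np.abs(back[core] - x[core])) < 0.15

    def test_non_monotone_anchors_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            warp.piecewise_linear_warp(t, t, np.array([0.0, 5.0, 4.0]),
                                       np.array([0.0, 3.0, 6.0]))

    def test_mean_preserved_for_smooth_input(self):
        t = np.arange(500) / 50.0
        x = np.sin(2 * np.pi * 0.3 * t) + 2.0
        src = np.array([0.0, 4.0, 9.98])
        dst = np.array([0.0, 5.0, 9.98])
        out = warp.piecewise_linear_warp(x, t, src, dst)
        assert abs(out.mean() - x.mean()) / abs(x.mean()) < 0.05


class TestSegmentNormalization:
    def test_equal_spans_pure_resampling(self):
        t = np.arange(200) / 20.0
        x = np.sin(t)
        out = warp.normalize_segment_lengths(x, t, np.array([0.0, 5.0, 9.95]),
                                             samples_per_segment=50)
        assert out.shape == (100,)
        np.testing.assert_allclose(out[:50], np.interp(np.arange(50) / 10, t, x),
                                   atol=1e-9)

    def test_cosine_phase_series_is_periodic(self):
        fs = 50.0
        anchors = np.array([0.0, 2.0, 5.0, 6.5])   # unequal spans
        t = np.arange(int(6.5 * fs) + 1) / fs
        seg = np.clip(np.searchsorted(anchors, t, side="right") - 1, 0, 2)
        frac = (t - anchors[seg]) / (anchors[seg + 1] - anchors[seg])
        series = np.cos(2 * np.pi * frac)
        out = warp.normalize_segment_lengths(series, t, anchors, 80)
        seg0, seg1, seg2 = out[:80], out[80:160], out[160:240]
        np.testing.assert_allclose(seg0, seg1, atol=0.02)
        np.testing.assert_allclose(seg1, seg2, atol=0.02)

    def test_zero_duration_span_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            warp.normalize_segment_lengths(t, t, np.array([0.0, 3.0, 3.0, 9.0]))


class TestCappedDtw:
    def _phase(self, fs=50.0, seg=5.0, total=25.0):
        t = np.arange(int(total * fs)) / fs
        return t, (t % seg) / seg * 2 * np.pi

    def test_aligned_series_identity(self):
        t, phi = self._phase()
        p = warp.capped_dtw_align(phi, phi, cap_s=2.0, fs=50.0)
        assert abs(p.mean_offset_s) < 0.02
        assert p.edge_pinned_fraction < 0.05

    @pytest.mark.parametrize("shift", [0.5, 1.5])
    def test_constant_shift_recovered(self, shift):
        t, phi = self._phase()
        est = np.interp(t - shift, t, phi)
        p = warp.capped_dtw_align(est, phi, cap_s=2.0, fs=50.0)
        assert abs(p.mean_offset_s - shift) < 0.25

    def test_beyond_cap_saturates(self):
        t, phi = self._phase()
        est = np.interp(t - 2.4, t, phi)
        p = warp.capped_dtw_align(est, phi, cap_s=2.0, fs=50.0)
        assert abs(p.mean_offset_s) <= 2.0 + 1e-6
        assert p.edge_pinned_fraction > 0.5

    def test_cap_below_one_sample_rejected(self):
        t, phi = self._phase()
        with pytest.raises(ValueError):
            warp.capped_dtw_align(phi, phi, cap_s=0.001, fs=50.0)

    def test_warp_path_invariants(self):
        with pytest.raises(ValueError):
            warp.WarpPath(src_times=np.array([0.0, 2.0, 1.0]),
                          dst_times=np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            warp.WarpPath(src_times=np.array([0.0, 5.0]),
                          dst_times=np.array([0.0, 1.0]), max_shift_s=2.0)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=0.1, max_value=3.0), min_size=2, max_size=6))
def test_warp_inverse_composition_property(spans):
    """Warping through anchors and back is the identity within one sample."""
    src = np.concatenate([[0.0], np.cumsum(spans)])
    rng = np.random.default_rng(0)
    jitter = rng.uniform(0.8, 1.2, len(spans))
    dst = np.concatenate([[0.0], np.cumsum(np.array(spans) * jitter)])
    t = np.linspace(0, src[-1], 300)
    x = np.sin(t * 2.0)
    fwd = warp.piecewise_linear_warp(x, t, src, dst)
    t2 = np.linspace(0, dst[-1], len(fwd))
    back = warp.piecewise_linear_warp(fwd, t2, dst, src, t_out=t)
    assert np.max(np.abs(back[3:-3] - x[3:-3])) < 0.1
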