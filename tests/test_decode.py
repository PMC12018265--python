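"""Circular position decoder: task structure, CV hygiene, reconstruction."""

import numpy as np
import pytest

from thetanav import decode
from thetanav._circular import TWO_PI, wrap
from thetanav.decode import (build_task_structure, circular_shift_null,
                             crosscorrelogram_route, decode_imagined,
                             fit_decoder, fit_weights, predict_phase,
                             reconstruction_report)

FS = 50.0


def _structure(n_segments=5, spseg=100):
    return build_task_structure(np.arange(n_segments + 1) * spseg,
                                n_segments * spseg, fs=FS)


def _synthetic_theta(structure, n_trials, n_channels, snr, seed=0,
                     prefs=None):
    """Channels a + b*cos(phi - pref_c) plus white envelope noise."""
    rng = np.random.default_rng(seed)
    if prefs is None:
        prefs = np.arange(n_channels) * TWO_PI / n_channels
    T = len(structure.phi)
    X = np.empty((n_trials, n_channels, T))
    for k in range(n_trials):
        for c in range(n_channels):
            clean = snr * np.cos(structure.phi - prefs[c])
            X[k, c] = clean + rng.standard_normal(T)
    return X


class TestTaskStructure:
    def test_closed_form_positions(self):
        s = _structure()
        mid = 50                      # midpoint of first segment
        assert s.phi[mid] == pytest.approx(np.pi)
        assert s.responses[mid, 0] == pytest.approx(-1.0)
        assert abs(s.responses[mid, 1]) < 1e-12
        q3 = 75                       # three quarters through: pre-turn peak
        assert s.responses[q3, 1] == pytest.approx(1.0)
        assert s.phi[0] == 0.0        # at a turn/segment entry: cos = +1
        assert s.responses[0, 0] == pytest.approx(1.0)

    def test_unit_circle_invariant(self):
        s = _structure()
        np.testing.assert_allclose((s.responses ** 2).sum(axis=1), 1.0)

    def test_invalid_anchors(self):
        with pytest.raises(ValueError):
            build_task_structure(np.array([0]), 100)
        with pytest.raises(ValueError):
            build_task_structure(np.array([0, 50, 50, 100]), 100)


class TestPredictPhase:
    @pytest.mark.parametrize("pred, expected", [
        ((1.0, 0.0), 0.0),
        ((0.0, -1.0), np.pi / 2),
        ((0.0, 1.0), 3 * np.pi / 2),
        ((-1.0, 0.0), np.pi),
    ])
    def test_quadrants(self, pred, expected):
        assert predict_phase(np.array(pred)) == pytest.approx(expected)

    def test_zero_vector_undefined(self):
        assert np.isnan(predict_phase(np.array([0.0, 0.0])))


class TestFitDecoder:
    def test_exact_features_identifiable(self):
        s = _structure(3, 60)
        X = np.tile(s.responses.T, (6, 1, 1))   # channels = exact responses
        model = fit_decoder(X, s, n_folds=3, n_repeats=1, seed=0)
        phi_hat = predict_phase(model.oof_pred[0])
        err = wrap(phi_hat - s.phi[None, :])
        assert np.max(np.abs(err)) < 1e-6

    def test_pure_noise_error_near_90deg(self):
        s = _structure(4, 80)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 6, len(s.phi)))
        model = fit_decoder(X, s, n_folds=5, n_repeats=2, seed=0)
        phi_hat = predict_phase(model.oof_pred).reshape(-1)
        phi = np.tile(s.phi, 2 * 20)
        res = reconstruction_report(phi_hat, phi)
        assert 80.0 < res.mean_abs_error_deg < 100.0

    def test_snr2_recovery_below_45deg(self):
        s = _structure(5, 100)
        X = _synthetic_theta(s, 24, 18, snr=2.0, seed=1)
        model = fit_decoder(X, s, n_folds=10, n_repeats=2, seed=0)
        phi_hat = predict_phase(model.oof_pred).reshape(-1)
        res = reconstruction_report(phi_hat, np.tile(s.phi, 2 * 24))
        assert res.mean_abs_error_deg < 45.0

    def test_fold_hygiene(self):
        """Folds partition trials exactly in every repeat."""
        s = _structure(3, 50)
        X = _synthetic_theta(s, 17, 4, snr=1.0)
        model = fit_decoder(X, s, n_folds=5, n_repeats=3, seed=0)
        for r in range(3):
            counts = np.bincount(model.folds[r], minlength=5)
            assert counts.sum() == 17 and counts.max() - counts.min() <= 1

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 9))
        Y = rng.standard_normal((200, 2))
        W, used = fit_weights(X, Y)
        D = np.column_stack([np.ones(200), X])
        W_ref = np.linalg.solve(D.T @ D, D.T @ Y)
        assert not used
        np.testing.assert_allclose(W, W_ref, atol=1e-8)

    def test_rank_deficient_falls_back_to_ridge(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        X[:, 3] = X[:, 0]             # exact collinearity
        with pytest.warns(UserWarning):
            W, used = fit_weights(X, rng.standard_normal((50, 2)))
        assert used
        assert np.all(np.isfinite(W))

    def test_noise_scaling_monotonicity(self):
        """Mean |error| never improves as envelope noise grows."""
        s = _structure(4, 60)
        errs = []
        for snr in (8.0, 2.0, 0.5):
            X = _synthetic_theta(s, 10, 8, snr=snr, seed=4)
            model = fit_decoder(X, s, n_folds=5, n_repeats=1, seed=0)
            phi_hat = predict_phase(model.oof_pred).reshape(-1)
            errs.append(reconstruction_report(
                phi_hat, np.tile(s.phi, 10)).mean_abs_error_deg)
        assert errs[0] < errs[1] < errs[2]


class TestReconstructionReport:
    def test_perfect_reconstruction(self):
        phi = np.random.default_rng(0).uniform(0, TWO_PI, 4000)
        res = reconstruction_report(phi, phi, n_bins=12)
        assert res.mean_abs_error_deg == 0.0
        off_diag = res.density - np.diag(np.diag(res.density))
        assert np.all(off_diag == 0)
        assert res.diagonal_mass > 1.0

    def test_uniform_independent_density_near_one(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(0, TWO_PI, 60000)
        phi_hat = rng.uniform(0, TWO_PI, 60000)
        res = reconstruction_report(phi_hat, phi, n_bins=8)
        assert abs(res.density.mean() - 1.0) < 1e-9
        assert np.max(np.abs(res.density - 1.0)) < 0.25

    def test_constant_shift_shows_in_errors(self):
        phi = np.random.default_rng(2).uniform(0, TWO_PI, 3000)
        res = reconstruction_report(phi + np.pi / 2, phi)
        assert res.mean_error_deg == pytest.approx(90.0, abs=1.0)

    def test_errors_wrapped_and_hist_sums_to_one(self):
        rng = np.random.default_rng(3)
        res = reconstruction_report(rng.uniform(-10, 10, 500),
                                    rng.uniform(-10, 10, 500))
        assert np.all(res.errors > -np.pi) and np.all(res.errors <= np.pi)
        assert res.error_hist.sum() == pytest.approx(1.0)

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            reconstruction_report(np.zeros(10), np.zeros(10), n_bins=3)


class TestShiftNull:
    def test_perfect_match_floor_p(self):
        phi = np.random.default_rng(0).uniform(0, TWO_PI, 300)
        res = circular_shift_null(phi, phi, n_shifts=99, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_independent_series_calibrated(self):
        ps = []
        for s in range(40):
            rng = np.random.default_rng(s)
            ps.append(circular_shift_null(rng.uniform(0, TWO_PI, 200),
                                          rng.uniform(0, TWO_PI, 200),
                                          n_shifts=99, seed=s).p)
        assert np.mean(np.array(ps) <= 0.05) < 0.2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            circular_shift_null(np.zeros(5), np.zeros(5))


class TestCrossCorrelogram:
    def test_nsin_autostructure(self):
        s = _structure(5, 80)
        lags, r = crosscorrelogram_route(s.responses[:, 1], s)
        i0 = len(r) // 2
        assert r[i0] == pytest.approx(1.0)
        assert r[i0 + 80] > 0.8 and r[i0 - 80] > 0.8

    def test_white_noise_stays_low(self):
        s = _structure(5, 80)
        rng = np.random.default_rng(0)
        vals = [np.abs(crosscorrelogram_route(
            rng.standard_normal(len(s.phi)), s)[1]).max() for _ in range(10)]
        assert np.mean(vals) < 0.2


class TestDecodeImagined:
    def test_zero_distortion_reduces_to_plain_decoding(self):
        s = _structure(5, 100)
        X = _synthetic_theta(s, 12, 12, snr=2.0, seed=5)
        Xall = X.transpose(0, 2, 1).reshape(-1, 12)
        W, _ = fit_weights(Xall, np.tile(s.responses, (12, 1)))
        groups = np.repeat(np.arange(3), 4)
        res_aligned = decode_imagined(W, X, s, groups=groups, n_repeats=2, seed=0)
        res_plain = decode_imagined(W, X, s, groups=groups, n_repeats=2,
                                    seed=0, align=False)
        assert abs(res_aligned.mean_abs_error_deg
                   - res_plain.mean_abs_error_deg) < 10.0
        assert res_aligned.mean_abs_error_deg < 45.0
        assert not res_aligned.alignment_flagged

    def test_shared_shift_corrected_by_alignment(self):
        s = _structure(5, 100)
        X = _synthetic_theta(s, 12, 12, snr=2.0, seed=6)
        # all trials share a 1.2 s timing delay
        shift = int(1.2 * FS)
        Xs = np.roll(X, shift, axis=2)
        Xall = X.transpose(0, 2, 1).reshape(-1, 12)
        W, _ = fit_weights(Xall, np.tile(s.responses, (12, 1)))
        res_plain = decode_imagined(W, Xs, s, n_repeats=2, seed=0, align=False)
        res_align = decode_imagined(W, Xs, s, n_repeats=2, seed=0, align=True)
        assert res_align.mean_abs_error_deg < res_plain.mean_abs_error_deg - 10.0
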