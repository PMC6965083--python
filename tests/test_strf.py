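"""Separable STRF estimation, prediction, and tuning-parameter extraction."""

import numpy as np
import pytest

import lnadapt as ln
from lnadapt.strf import (
    SeparableSTRF,
    SeparableSTRFModel,
    compare_combined_vs_split,
    extract_strf_params,
    predict_linear,
)


def _truth_strf(n_freqs=25, n_history=10, center=12.0):
    f = np.arange(n_freqs)
    k_f = np.exp(-0.5 * ((f - center) / 2.0) ** 2)
    h = np.arange(n_history)
    k_h = np.exp(-h / 2.0) - np.exp(-h / 0.7)
    k_h[0] = 0.5 * k_h[1]
    return SeparableSTRF(k_f, k_h, bias=0.3).canonical()


def _drc_levels(grid, n=1600, seed=0, width=40.0):
    return ln.generate_drc(grid, ln.ContrastRegime("x", 40.0, width), n, seed=seed).levels


class TestPredictLinear:
    def test_identity_kernel_returns_channel_track(self, grid):
        levels = _drc_levels(grid, 50)
        k_f = np.zeros(25)
        k_f[7] = 1.0
        strf = SeparableSTRF(k_f, np.array([1.0]), bias=0.0)
        assert np.allclose(predict_linear(strf, levels), levels[:, 7])

    def test_linearity_in_kernel_scale(self, grid):
        levels = _drc_levels(grid, 100)
        strf = _truth_strf()
        doubled = SeparableSTRF(2 * strf.k_f, strf.k_h, strf.bias)
        z1 = predict_linear(strf, levels) - strf.bias
        z2 = predict_linear(doubled, levels) - strf.bias
        assert np.allclose(z2, 2 * z1)

    def test_matches_bruteforce_convolution(self, grid):
        levels = _drc_levels(grid, 60, seed=3)
        strf = _truth_strf()
        z = predict_linear(strf, levels)
        # naive double loop with first-chord padding for t-h < 0
        n, nf = levels.shape
        expect = np.full(n, strf.bias)
        for t in range(n):
            for h, w in enumerate(strf.k_h):
                row = levels[max(t - h, 0)] if t - h < 0 else levels[t - h]
                expect[t] += w * float(strf.k_f @ row)
        assert np.allclose(z, expect)

    def test_grid_mismatch_rejected(self, grid):
        strf = SeparableSTRF(np.ones(10), np.ones(2), 0.0)
        with pytest.raises(ValueError, match="channels"):
            predict_linear(strf, _drc_levels(grid, 10))


class TestCanonicalForm:
    def test_idempotent_and_scale_invariant_predictions(self, grid):
        levels = _drc_levels(grid, 80)
        strf = SeparableSTRF(np.random.default_rng(0).normal(size=25), -3.0 * np.ones(5), 1.0)
        canon = strf.canonical()
        again = canon.canonical()
        assert np.allclose(canon.k_f, again.k_f) and np.allclose(canon.k_h, again.k_h)
        assert np.linalg.norm(canon.k_h) == pytest.approx(1.0)
        assert canon.k_h[np.argmax(np.abs(canon.k_h))] >= 0
        assert np.allclose(predict_linear(strf, levels), predict_linear(canon, levels))


class TestFitting:
    def test_noiseless_rank1_recovery(self, grid):
        truth = _truth_strf()
        levels = _drc_levels(grid, 1600, seed=1)
        y = predict_linear(truth, levels)
        fit = SeparableSTRFModel(y, levels).fit().strf
        assert abs(np.corrcoef(fit.k_f, truth.k_f)[0, 1]) > 0.999
        assert abs(np.corrcoef(fit.k_h, truth.k_h)[0, 1]) > 0.999

    def test_all_zero_psth_gives_zero_kernels(self, grid):
        levels = _drc_levels(grid, 200)
        res = SeparableSTRFModel(np.zeros(200), levels).fit()
        assert np.all(res.strf.k_f == 0) and res.strf.bias == 0.0

    def test_poisson_recovery_from_forty_seconds(self, grid, high_regime):
        unit = ln.make_population(1, 100.0, 100.0, seed=2)[0]
        stim = ln.generate_drc(grid, high_regime, 1600, seed=6)
        resp = ln.exclude_onset(ln.simulate_unit_response(unit, stim, 20, seed=7), 500.0)
        fit = SeparableSTRFModel(resp.psth(), resp.stimulus.levels).fit().strf
        truth = unit.strf.canonical()
        assert abs(np.corrcoef(fit.k_f, truth.k_f)[0, 1]) >= 0.9
        assert abs(np.corrcoef(fit.k_h, truth.k_h)[0, 1]) >= 0.9

    def test_training_error_never_increases_with_iterations(self, grid):
        unit = ln.make_population(1, 100.0, 100.0, seed=3)[0]
        stim = ln.generate_drc(grid, ln.ContrastRegime("x", 40.0, 40.0), 800, seed=8)
        resp = ln.simulate_unit_response(unit, stim, 10, seed=9)
        mses = [
            SeparableSTRFModel(resp.psth(), stim.levels).fit(max_iter=k).train_mse
            for k in (1, 2, 4, 8, 50)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(mses, mses[1:]))


class TestParams:
    def test_gaussian_spectral_fwhm(self, grid):
        # FWHM of a sigma=2-channel Gaussian on a 1/4-octave grid
        strf = _truth_strf(center=12.0)
        strf.k_h = np.zeros(10)
        strf.k_h[1] = 1.0
        p = extract_strf_params(strf, grid)
        assert p.best_frequency == grid.frequencies[12]
        assert p.freq_bandwidth == pytest.approx(2.355 * 2.0 * 0.25, rel=0.02)

    def test_single_bin_temporal_kernel_floors_at_25ms(self, grid):
        strf = _truth_strf()
        strf.k_h = np.zeros(10)
        strf.k_h[0] = 1.0
        assert extract_strf_params(strf, grid).temporal_bandwidth == 25.0

    def test_scale_equivariance(self, grid):
        strf = _truth_strf()
        scaled = SeparableSTRF(3.0 * strf.k_f, strf.k_h, strf.bias)
        a = extract_strf_params(strf, grid)
        b = extract_strf_params(scaled, grid)
        assert b.best_frequency == a.best_frequency
        assert b.freq_bandwidth == pytest.approx(a.freq_bandwidth)
        assert b.temporal_bandwidth == pytest.approx(a.temporal_bandwidth)
        assert b.max_weight == pytest.approx(3.0 * a.max_weight)

    def test_negative_peak_flagged(self, grid):
        strf = SeparableSTRF(-np.ones(25), np.ones(3) / np.sqrt(3), 0.0)
        p = extract_strf_params(strf, grid)
        assert "non_positive_peak" in p.flags
        assert np.isnan(p.best_frequency)

    def test_truncated_fwhm_flagged(self, grid):
        strf = SeparableSTRF(np.linspace(0.5, 1.0, 25), np.array([1.0]), 0.0)
        p = extract_strf_params(strf, grid)
        assert any("truncated" in f for f in p.flags)

    def test_bf_recovery_within_one_grid_step(self, grid, high_regime):
        errors = []
        units = ln.make_population(8, 100.0, 100.0, seed=4)
        stim = ln.generate_drc(grid, high_regime, 1600, seed=10)
        for i, unit in enumerate(units):
            resp = ln.exclude_onset(ln.simulate_unit_response(unit, stim, 10, seed=20 + i), 500.0)
            fit = SeparableSTRFModel(resp.psth(), resp.stimulus.levels).fit().strf
            bf_true = extract_strf_params(unit.strf, grid).best_frequency
            bf_est = extract_strf_params(fit, grid).best_frequency
            errors.append(abs(np.log2(bf_est / bf_true)) / grid.octave_step)
        assert np.median(errors) <= 1.0


class TestCombinedVsSplit:
    def test_shared_truth_favors_combined(self, grid, mouse_drcs):
        unit = ln.make_population(1, 0.0, 100.0, seed=5)[0]
        data = {}
        for lbl in ("low", "high"):
            resp = ln.exclude_onset(
                ln.simulate_unit_response(unit, mouse_drcs[lbl], 10, seed=30), 500.0
            )
            data[lbl] = (resp.stimulus.levels, resp.psth())
        out = compare_combined_vs_split(data)
        assert out["mean_difference"] > -0.02  # combined at least as good, up to cv noise

    def test_distinct_kernels_favor_split(self, grid, mouse_drcs):
        # different spectral kernels per condition: a single STRF cannot serve both
        u1 = ln.make_population(3, 0.0, 100.0, seed=6)[0]
        u2 = ln.make_population(3, 0.0, 100.0, seed=6)[2]
        r1 = ln.exclude_onset(ln.simulate_unit_response(u1, mouse_drcs["low"], 10, seed=31), 500.0)
        r2 = ln.exclude_onset(ln.simulate_unit_response(u2, mouse_drcs["high"], 10, seed=32), 500.0)
        out = compare_combined_vs_split(
            {"low": (r1.stimulus.levels, r1.psth()), "high": (r2.stimulus.levels, r2.psth())}
        )
        assert out["mean_difference"] < 0

    def test_single_condition_rejected(self, grid, mouse_drcs):
        with pytest.raises(ValueError):
            compare_combined_vs_split({"low": (mouse_drcs["low"].levels, np.zeros(1600))})
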