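"""Adaptation dynamics: the exponential contrast filter and tau estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lnadapt as ln
from lnadapt.dynamics import (
    AdaptiveLN,
    AdaptiveLNModel,
    adaptive_predict,
    contrast_filter,
    steady_state_bins,
)
from lnadapt.sigmoid import SigmoidParams, sigmoid
from lnadapt.strf import predict_linear


class TestContrastFilter:
    def test_constant_high_stays_at_one(self):
        s = contrast_filter(np.ones(50), 200.0)
        assert np.allclose(s, 1.0)

    def test_tiny_tau_is_instantaneous(self):
        C = np.array([0.0, 1, 1, 0, 1, 0, 0, 1])
        assert np.array_equal(contrast_filter(C, 1.0), C)

    def test_step_reaches_632pct_after_tau(self):
        # tau = 100 ms = 4 bins: 1 - e^-1 of the step ~4 bins after the switch
        C = np.concatenate([np.zeros(40), np.ones(40)])
        s = contrast_filter(C, 100.0)
        assert s[43] == pytest.approx(1 - np.exp(-1), abs=0.001)

    @given(tau=st.floats(1.0, 700.0), seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_bounded_in_unit_interval(self, tau, seed):
        C = np.random.default_rng(seed).integers(0, 2, 120).astype(float)
        s = contrast_filter(C, tau)
        assert np.all(s >= 0.0) and np.all(s <= 1.0 + 1e-12)

    def test_monotone_convergence_under_constant_contrast(self):
        C = np.concatenate([np.ones(10), np.zeros(60)])
        s = contrast_filter(C, 300.0)
        tail = s[10:]
        assert np.all(np.diff(tail) <= 1e-12)


class TestAdaptivePredict:
    def _model(self, tau=150.0, same=False, seed=0):
        u = ln.make_population(1, 0.0 if same else 100.0, tau, seed=seed)[0]
        return AdaptiveLN(u.strf, u.params_low, u.params_low if same else u.params_high, tau)

    def test_equal_params_make_tau_irrelevant(self, switching_drc):
        m1 = self._model(tau=10.0, same=True)
        m2 = AdaptiveLN(m1.strf, m1.params_low, m1.params_high, 650.0)
        assert np.allclose(adaptive_predict(m1, switching_drc), adaptive_predict(m2, switching_drc))

    def test_constant_contrast_matches_static_prediction(self, grid, high_regime):
        m = self._model()
        stim = ln.generate_drc(grid, high_regime, 200, seed=1)
        z = predict_linear(m.strf, stim.levels)
        assert np.allclose(adaptive_predict(m, stim), sigmoid(z, m.params_high))

    def test_matches_per_bin_hand_evaluation(self, switching_drc):
        m = self._model(tau=120.0)
        rate = adaptive_predict(m, switching_drc)
        z = predict_linear(m.strf, switching_drc.levels)
        s = contrast_filter(switching_drc.binary_contrast_track(), m.tau_ms)
        lo, hi = m.params_low.as_array(), m.params_high.as_array()
        expect = np.empty_like(z)
        for t in range(len(z)):
            a, b, c, d = lo + (hi - lo) * s[t]
            expect[t] = a + b / (1 + np.exp(-(z[t] - c) / d))
        assert np.allclose(rate, expect)

    def test_tau_to_zero_limit_equals_instantaneous_two_state(self, switching_drc):
        m = self._model(tau=1.0)
        rate = adaptive_predict(m, switching_drc)
        z = predict_linear(m.strf, switching_drc.levels)
        C = switching_drc.binary_contrast_track()
        inst = np.where(C == 1.0, sigmoid(z, m.params_high), sigmoid(z, m.params_low))
        assert np.max(np.abs(rate - inst)) < 1e-9


class TestSteadyStateBins:
    def test_last_second_of_two_second_epochs(self):
        C = np.array([0.0] * 80 + [1.0] * 80)
        mask = steady_state_bins(C)
        assert mask.sum() == 80
        assert mask[40:80].all() and not mask[:40].any()
        assert mask[120:].all() and not mask[80:120].any()


class TestAdaptiveFit:
    def _fit(self, tau_true, seed=0, n_repeats=40):
        u = ln.make_population(1, 100.0, tau_true, seed=seed)[0]
        sw = ln.generate_switching_drc(ln.mouse_grid(), total_s=40.0, seed=10 + seed)
        resp = ln.exclude_onset(ln.simulate_unit_response(u, sw, n_repeats, seed=20 + seed), 500.0)
        return ln.fit_adaptive_ln(resp.stimulus, resp.psth()), u

    def test_tau_recovery_within_30pct(self):
        res, u = self._fit(150.0)
        assert res.tau_ms == pytest.approx(150.0, rel=0.30)

    def test_tau_beyond_cap_returns_cap(self):
        res, _ = self._fit(2000.0)
        assert res.tau_ms == pytest.approx(700.0)
        assert res.tau_at_cap

    def test_degenerate_unit_flagged(self, switching_drc):
        u = ln.make_population(1, 0.0, 150.0, seed=1)[0]
        u.params_high = u.params_low  # no contrast dependence: tau unidentifiable
        resp = ln.exclude_onset(ln.simulate_unit_response(u, switching_drc, 40, seed=2), 500.0)
        res = ln.fit_adaptive_ln(resp.stimulus, resp.psth())
        assert "tau_unidentifiable" in res.fitted.flags

    def test_recovery_error_shrinks_with_repeats(self):
        errs = {}
        for n_rep in (10, 40):
            errors = []
            for seed in (3, 4, 5):
                res, u = self._fit(150.0, seed=seed, n_repeats=n_rep)
                errors.append(abs(res.tau_ms - 150.0))
            errs[n_rep] = np.mean(errors)
        assert errs[40] <= errs[10]

    def test_summary_reports_tau(self):
        res, _ = self._fit(150.0, seed=6)
        assert "tau" in res.summary()


class TestModelSelection:
    def _selection(self, unit, seed):
        sw = ln.generate_switching_drc(ln.mouse_grid(), total_s=40.0, seed=100 + seed)
        resp = ln.exclude_onset(ln.simulate_unit_response(unit, sw, 20, seed=200 + seed), 500.0)
        return ln.model_selection(resp.stimulus, resp.psth())

    def test_specificity_on_non_adapting_truth(self):
        flags = []
        for i in range(6):
            u = ln.make_population(1, 100.0, 150.0, seed=i)[0]
            u.params_high = u.params_low
            flags.append(self._selection(u, i)["contrast_dependent_better"])
        assert sum(flags) <= 1  # contrast dependence claimed in at most 1/6 units

    def test_sensitivity_to_slow_adaptation(self):
        flags = []
        for i in range(3):
            u = ln.make_population(1, 100.0, 400.0, seed=i)[0]
            flags.append(self._selection(u, 10 + i)["tau_improves"])
        assert sum(flags) >= 2  # tau helps in the majority of slowly adapting units

    def test_sub_chord_adaptation_rarely_needs_tau(self):
        # adaptation completing within one 25-ms chord: the instantaneous
        # two-state model already captures it
        flags = []
        for i in range(3):
            u = ln.make_population(1, 100.0, 8.0, seed=i)[0]
            flags.append(self._selection(u, 20 + i)["tau_improves"])
        assert sum(flags) <= 1
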