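"""Psychometric fitting, JND estimation, and the neurometric decision model."""

import numpy as np
import pytest
from scipy.stats import norm

import lnadapt as ln
from lnadapt.behavior import (
    NeurometricConfig,
    fit_psychometric,
    predict_perceptual_adaptation,
    predict_psychometric,
    simulate_neurometric_trial,
)
from lnadapt.simulate import JND_PER_SIGMA
from lnadapt.sigmoid import SigmoidParams
from lnadapt.strf import SeparableSTRF


def _gaussian_counts(sigma, levels, n, ref=60.0, seed=0):
    rng = np.random.default_rng(seed)
    p = norm.cdf((np.asarray(levels) - ref) / sigma)
    return rng.binomial(n, p)


class TestPsychometric:
    def test_jnd_of_cumulative_gaussian(self):
        levels = np.arange(56.0, 65.0, 1.0)
        k = _gaussian_counts(1.0, levels, 10000)
        fit = fit_psychometric(levels, k, 10000)
        assert fit.jnd == pytest.approx(JND_PER_SIGMA, abs=0.05)

    def test_doubling_sigma_doubles_jnd(self):
        levels = np.arange(52.0, 69.0, 2.0)
        j = []
        for sigma in (1.5, 3.0):
            k = _gaussian_counts(sigma, levels, 10000, seed=1)
            j.append(fit_psychometric(levels, k, 10000).jnd)
        assert j[1] == pytest.approx(2 * j[0], rel=0.05)

    def test_symmetric_data_centres_on_reference(self):
        levels = np.arange(52.0, 69.0, 2.0)
        k = _gaussian_counts(2.0, levels, 10000, seed=2)
        fit = fit_psychometric(levels, k, 10000)
        assert fit.location == pytest.approx(60.0, abs=0.1)
        assert fit.predict([60.0])[0] == pytest.approx(0.5, abs=0.01)

    def test_jnd_consistency_improves_with_trials(self):
        levels = np.arange(52.0, 69.0, 2.0)
        errs = []
        for n in (100, 1000, 10000):
            jnds = [
                fit_psychometric(levels, _gaussian_counts(2.0, levels, n, seed=s), n).jnd
                for s in range(8)
            ]
            errs.append(np.mean(np.abs(np.array(jnds) - 2.0 * JND_PER_SIGMA)))
        assert errs[2] < errs[0]

    def test_all_one_responses_flagged(self):
        levels = np.arange(52.0, 69.0, 2.0)
        fit = fit_psychometric(levels, np.full(len(levels), 50), 50)
        assert "responses_at_bound" in fit.flags

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric([1.0, 2.0, 3.0], [0, 1, 2], 5)


class TestBehavioralCompensation:
    def test_jnd_doubling_under_contrast_doubling_is_100(self):
        assert ln.behavioral_compensation(2.0, 4.0, 20.0, 40.0) == pytest.approx(100.0)

    def test_equal_jnds_is_0(self):
        assert ln.behavioral_compensation(3.0, 3.0, 20.0, 40.0) == 0.0

    def test_participant_table_round_trip(self):
        levels = np.arange(52.0, 69.0, 2.0)
        frames = [
            ln.simulate_observer_session(3.0, 4.5, levels, 2000, participant=f"p{i}", seed=i)
            for i in range(3)
        ]
        import pandas as pd

        table = ln.participant_jnd_table(pd.concat(frames))
        assert len(table) == 3
        assert table.jnd_low.mean() == pytest.approx(3.0, abs=0.3)
        assert table.jnd_high.mean() == pytest.approx(4.5, abs=0.4)
        expected_change = (4.5 / 3.0 - 1.0) * 100.0
        assert table.jnd_change_pct.mean() == pytest.approx(expected_change, abs=8.0)


def _steep_probe_unit(n_freqs=25):
    """Single unit with a steeply increasing response to probe level."""
    k_f = np.ones(n_freqs) / np.sqrt(n_freqs)
    strf = SeparableSTRF(k_f, np.array([1.0]), 0.0)
    sum_k = k_f.sum()
    c = (70.0 - 10 * np.log10(n_freqs)) * sum_k
    p = SigmoidParams(0.1, 5.0, c, 1.0 * sum_k)
    return ln.GroundTruthUnit(strf, p, p, 100.0)


class TestNeurometricTrial:
    def test_equal_levels_give_half_louder(self, grid, low_regime):
        units = ln.make_population(5, 100.0, 100.0, seed=0, operating_point="probe")
        n = 400
        louder = 0
        for i in range(n):
            trial = ln.assemble_trial(low_regime, 70.0, 70.0, grid, seed=1000 + i)
            louder += simulate_neurometric_trial(units, trial, seed=i) == "louder"
        assert abs(louder / n - 0.5) < 2.6 * 0.5 / np.sqrt(n)

    def test_steep_unit_detects_plus_8db(self, grid, low_regime):
        unit = _steep_probe_unit()
        hits = 0
        for i in range(60):
            trial = ln.assemble_trial(low_regime, 70.0, 78.0, grid, seed=2000 + i)
            hits += simulate_neurometric_trial([unit], trial, seed=i) == "louder"
        assert hits / 60 > 0.9

    def test_empty_population_rejected(self, grid, low_regime):
        trial = ln.assemble_trial(low_regime, 70.0, 70.0, grid, seed=0)
        with pytest.raises(ValueError):
            simulate_neurometric_trial([], trial, seed=0)


class TestNeurometricPopulation:
    def test_level_insensitive_population_is_flat(self, grid, low_regime):
        # b = 0: no level information anywhere; fair tie-breaking pins P at 0.5
        units = ln.make_population(5, 100.0, 100.0, seed=0, operating_point="probe")
        for u in units:
            u.params_low = SigmoidParams(u.params_low.a, 0.0, u.params_low.c, u.params_low.d)
            u.params_high = u.params_low
        cfg = NeurometricConfig(n_trials_per_level=400)
        fit = predict_psychometric(units, low_regime, cfg, np.random.default_rng(0), grid)
        frac = fit.model.k / fit.model.n
        assert np.all(np.abs(frac - 0.5) < 3.3 * 0.5 / np.sqrt(400))

    def test_full_compensation_predicts_about_100pct(self):
        units = ln.make_population(20, 100.0, 100.0, seed=0, operating_point="probe")
        cfg = NeurometricConfig(n_trials_per_level=1000, n_runs=6, seed=0)
        out = predict_perceptual_adaptation(units, cfg)
        assert out["mean_compensation"] == pytest.approx(100.0, abs=10.0)

    def test_zero_compensation_predicts_about_0pct(self):
        units = ln.make_population(20, 0.0, 100.0, seed=0, operating_point="probe")
        cfg = NeurometricConfig(n_trials_per_level=500, n_runs=4, seed=0)
        out = predict_perceptual_adaptation(units, cfg)
        assert out["mean_compensation"] == pytest.approx(0.0, abs=6.0)

    def test_predicted_compensation_monotone_in_gain_ratio(self):
        means = []
        for target in (0.0, 50.0, 100.0):
            units = ln.make_population(12, target, 100.0, seed=1, operating_point="probe")
            cfg = NeurometricConfig(n_trials_per_level=400, n_runs=3, seed=2)
            means.append(predict_perceptual_adaptation(units, cfg)["mean_compensation"])
        assert means[0] < means[1] < means[2]

    def test_mouse_paradigm_defaults(self):
        cfg = NeurometricConfig()
        assert cfg.reference_level == 70.0
        assert min(cfg.target_levels) == 62.0 and max(cfg.target_levels) == 78.0
        assert cfg.n_trials_per_level == 500 and cfg.n_runs == 25
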