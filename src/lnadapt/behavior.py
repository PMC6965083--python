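"""2-AFC psychophysics and the neurometric behavioural prediction model.

Psychometric side: the probability of reporting the target noise probe as
"louder" than the reference is fitted with a maximum-likelihood sigmoid curve
(cumulative-Gaussian core by default, with small estimated guess/lapse
rates), and the just noticeable difference (JND) is the dB separation between
the 25% and 75% points of the fitted curve.
Because discrimination sensitivity is inversely proportional to JND, the
effective gain of the level-discrimination process is taken as G = 1/JND and
perceptual contrast adaptation is quantified with the same percentage
compensation formula used for neuronal gain.

Neurometric side: populations of fitted contrast-dependent LN units are shown
the same 2-AFC trials (noise probes embedded in DRC of a given contrast).
Each unit's predicted rate in a decision window around each probe is
discretised as a Poisson process, counts are summed across units, and the
probe with more spikes is reported "louder" (ties broken by a fair coin).
Repeating this over levels and trials yields a predicted psychometric curve
per contrast, hence a predicted perceptual compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import lfilter
from scipy.stats import norm

from .sigmoid import percent_compensation, sigmoid
from .stimuli import ContrastRegime, FrequencyGrid, TrialStimulus, assemble_trial, mouse_grid
from .strf import predict_linear


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _logit_ppf(q):
    return np.log(q / (1.0 - q))


# ---------------------------------------------------------------------------
# psychometric fitting


class PsychometricModel:
    """Maximum-likelihood 2-AFC psychometric curve.

    P(louder | level x) = guess + (1 - guess - lapse) * F((x - m)/s)

    where the core F is the cumulative Gaussian (``family="probit"``, default)
    or the logistic (``family="logit"``).  The probit core matches the
    ideal-observer model underlying both the synthetic observers and the
    Poisson-count decision rule; a logit core fitted to probit-shaped data
    systematically narrows the estimated 25-75% width (it steepens to chase
    the lighter Gaussian tails), so probit is the default.  The guess and
    lapse rates are estimated within [0, max_asymptote] (default cap 0.05)
    alongside location and width; pass ``fix_asymptotes=True`` to pin them at
    their initial values instead.

    Parameters
    ----------
    levels : array of target levels, dB
    k_louder : array of "louder" response counts per level
    n_trials : int or array, trials per level
    guess, lapse : float
        Initial (or fixed) lower/upper asymptote offsets, default 0.01 each.
    """

    def __init__(
        self,
        levels,
        k_louder,
        n_trials,
        guess: float = 0.01,
        lapse: float = 0.01,
        family: str = "probit",
        fix_asymptotes: bool = False,
        max_asymptote: float = 0.05,
    ):
        self.levels = np.asarray(levels, float)
        self.k = np.asarray(k_louder, float)
        self.n = np.broadcast_to(np.asarray(n_trials, float), self.k.shape).copy()
        if len(set(map(len, (self.levels, self.k, self.n)))) != 1:
            raise ValueError("levels, k_louder and n_trials must align")
        if len(np.unique(self.levels)) < 4:
            raise ValueError("need at least 4 distinct levels")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("response counts must lie in [0, n_trials]")
        self.guess = guess
        self.lapse = lapse
        if family not in ("probit", "logit"):
            raise ValueError("family must be 'probit' or 'logit'")
        self.family = family
        self._core = norm.cdf if family == "probit" else _logistic
        self._core_ppf = norm.ppf if family == "probit" else _logit_ppf
        self.fix_asymptotes = fix_asymptotes
        self.max_asymptote = max_asymptote

    def _nll(self, theta):
        m, log_s, g, l = theta
        p = g + (1 - g - l) * self._core((self.levels - m) / np.exp(log_s))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(self.k * np.log(p) + (self.n - self.k) * np.log(1 - p)))

    def fit(self) -> "PsychometricResults":
        flags: list[str] = []
        frac = self.k / self.n
        span = float(self.levels.max() - self.levels.min())
        if np.all(frac == 0) or np.all(frac == 1):
            flags.append("responses_at_bound")
        # location init: level whose response fraction is nearest 0.5
        m0 = float(self.levels[np.argmin(np.abs(frac - 0.5))])
        cap = self.max_asymptote
        if self.fix_asymptotes:
            bounds = [(None, None), (None, None), (self.guess, self.guess), (self.lapse, self.lapse)]
        else:
            bounds = [(None, None), (None, None), (0.0, cap), (0.0, cap)]
        best = None
        for s0 in (span / 20, span / 8, span / 3):
            x0 = np.array([m0, np.log(s0), self.guess, self.lapse])
            sol = minimize(
                self._nll, x0, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
            if best is None or sol.fun < best[0]:
                best = (float(sol.fun), sol.x)
        nll, x = best
        m, s = float(x[0]), float(np.exp(x[1]))
        return PsychometricResults(
            self, location=m, width=s, guess=float(x[2]), lapse=float(x[3]),
            nll=float(nll), flags=tuple(flags),
        )


@dataclass
class PsychometricResults:
    """Fitted psychometric curve; JND is the 25-75% width of the fitted curve."""

    model: PsychometricModel
    location: float  # dB, curve midpoint
    width: float  # dB, logistic scale parameter
    guess: float
    lapse: float
    nll: float
    flags: tuple[str, ...] = ()

    def predict(self, levels) -> np.ndarray:
        g, l = self.guess, self.lapse
        x = (np.asarray(levels, float) - self.location) / self.width
        return g + (1 - g - l) * self.model._core(x)

    def level_at(self, p: float) -> float:
        """Target level at which the fitted curve crosses probability ``p``."""
        g, l = self.guess, self.lapse
        q = (p - g) / (1 - g - l)
        if not 0 < q < 1:
            raise ValueError(f"probability {p} outside the fitted curve's range")
        return self.location + self.width * float(self.model._core_ppf(q))

    @property
    def jnd(self) -> float:
        return self.level_at(0.75) - self.level_at(0.25)

    def summary(self) -> str:
        return (
            f"Psychometric fit (ML {self.model.family} core, estimated guess/lapse "
            f"{self.guess:.3f}/{self.lapse:.3f})\n"
            f"  location: {self.location:.2f} dB  width: {self.width:.3f} dB\n"
            f"  JND (25-75%): {self.jnd:.3f} dB\n"
            f"  -log likelihood: {self.nll:.2f}"
            + (f"\n  flags: {', '.join(self.flags)}" if self.flags else "")
        )


def fit_psychometric(levels, k_louder, n_trials, guess: float = 0.01, lapse: float = 0.01, **kw) -> PsychometricResults:
    """Functional wrapper around :class:`PsychometricModel`."""
    return PsychometricModel(levels, k_louder, n_trials, guess, lapse, **kw).fit()


def behavioral_compensation(jnd_low: float, jnd_high: float, c_low: float, c_high: float) -> float:
    """Perceptual % compensation, treating G = 1/JND as the effective gain."""
    if jnd_low <= 0 or jnd_high <= 0:
        raise ValueError("JNDs must be positive")
    return percent_compensation(1.0 / jnd_low, 1.0 / jnd_high, c_low, c_high)


def participant_jnd_table(responses: pd.DataFrame, contrast_widths: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-participant JNDs and contrast adaptation from a 2-AFC response table.

    Accepts either aggregated rows (columns participant, contrast,
    target_level_db, n_trials, n_louder) or raw per-trial rows (participant,
    contrast, target_level_db, response with response in {0, 1}).  Returns one
    row per participant with jnd_low, jnd_high, % JND change and %
    compensation (widths default to the 10/30 dB human regimes).
    """
    cw = contrast_widths or {"low": 10.0, "high": 30.0}
    df = responses.copy()
    if "n_louder" not in df.columns:
        grouped = df.groupby(["participant", "contrast", "target_level_db"])["response"]
        df = grouped.agg(n_louder="sum", n_trials="count").reset_index()
    rows = []
    for participant, sub in df.groupby("participant"):
        jnds = {}
        for contrast, cond in sub.groupby("contrast"):
            fit = fit_psychometric(cond["target_level_db"], cond["n_louder"], cond["n_trials"])
            jnds[contrast] = fit.jnd
        rows.append(
            {
                "participant": participant,
                "jnd_low": jnds["low"],
                "jnd_high": jnds["high"],
                "jnd_change_pct": (jnds["high"] - jnds["low"]) / jnds["low"] * 100.0,
                "compensation_pct": behavioral_compensation(jnds["low"], jnds["high"], cw["low"], cw["high"]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neurometric simulation


@dataclass
class NeurometricConfig:
    """Trial layout and sampling plan for the neurometric prediction model."""

    reference_level: float = 70.0
    target_levels: tuple = tuple(np.arange(62.0, 79.0, 2.0))  # 62-78 dB
    n_trials_per_level: int = 500
    n_runs: int = 25
    contrast_widths: dict = field(default_factory=lambda: {"low": 20.0, "high": 40.0})
    mean_level: float = 40.0
    #: decision window = probe bins + this many following bins; None derives it
    #: from the population's temporal-kernel peak lag (the probe-evoked
    #: response of a causal kernel peaking at lag 1 spills one bin past the
    #: probe; an instantaneous kernel has nothing to collect there)
    latency_bins: int | None = None
    seed: int = 0


def _decision_window(probe_bins: np.ndarray, n_bins: int, latency_bins: int) -> np.ndarray:
    extra = np.arange(probe_bins[-1] + 1, min(probe_bins[-1] + 1 + latency_bins, n_bins))
    return np.concatenate([probe_bins, extra])


def _resolve_latency(units, latency_bins: int | None) -> int:
    if latency_bins is not None:
        return latency_bins
    return int(max(int(np.argmax(np.abs(u.strf.k_h))) for u in units))


def _unit_params(unit, contrast_label: str):
    return unit.params_high if contrast_label == "high" else unit.params_low


def simulate_neurometric_trial(units, trial: TrialStimulus, seed: int | np.random.Generator = 0) -> str:
    """Decide one 2-AFC trial from Poisson counts of a population of LN units.

    Each unit's rate in the decision windows (probe bins plus one latency bin)
    comes from the contrast-appropriate sigmoid applied to its STRF drive;
    Poisson counts are summed across units and windows, and the probe with the
    larger total wins ("louder" if the target wins; ties by fair coin).
    """
    if not units:
        raise ValueError("need at least one unit")
    rng = np.random.default_rng(seed)
    n_bins = trial.spectrogram.shape[0]
    latency = _resolve_latency(units, None)
    win_ref = _decision_window(trial.reference_bins, n_bins, latency)
    win_tgt = _decision_window(trial.target_bins, n_bins, latency)
    count_ref = count_tgt = 0
    for unit in units:
        z = predict_linear(unit.strf, trial.spectrogram)
        rate = np.maximum(sigmoid(z, _unit_params(unit, trial.contrast.label)), 0.0)
        count_ref += int(rng.poisson(rate[win_ref]).sum())
        count_tgt += int(rng.poisson(rate[win_tgt]).sum())
    if count_tgt > count_ref:
        return "louder"
    if count_tgt < count_ref:
        return "quieter"
    return "louder" if rng.random() < 0.5 else "quieter"


def _batch_trial_spectrograms(
    n_trials: int,
    contrast: ContrastRegime,
    reference_level: float,
    target_level: float,
    grid: FrequencyGrid,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fresh trial spectrograms, stacked (n_trials, n_bins, n_freqs)."""
    template = assemble_trial(contrast, reference_level, target_level, grid, seed=rng)
    n_bins, n_freqs = template.spectrogram.shape
    spect = np.empty((n_trials, n_bins, n_freqs))
    drc_mask = np.ones(n_bins, dtype=bool)
    drc_mask[template.reference_bins] = False
    drc_mask[template.target_bins] = False
    n_drc = int(drc_mask.sum())
    spect[:, ~drc_mask, :] = template.spectrogram[~drc_mask]
    spect[:, drc_mask, :] = contrast.lo + rng.random((n_trials, n_drc, n_freqs)) * (contrast.hi - contrast.lo)
    return spect, template.reference_bins, template.target_bins


def _population_window_rates(units, spect: np.ndarray, contrast_label: str, windows) -> list[np.ndarray]:
    """Summed population rate per trial in each decision window.

    The spectral projection and the causal temporal filtering are batched over
    trials; pre-trial history is padded with each trial's first chord, as in
    :func:`lnadapt.strf.predict_linear`.
    """
    n_trials, n_bins, _ = spect.shape
    totals = [np.zeros(n_trials) for _ in windows]
    for unit in units:
        strf = unit.strf
        proj = spect @ strf.k_f  # (n_trials, n_bins)
        H = strf.n_history
        padded = np.concatenate([np.repeat(proj[:, :1], H - 1, axis=1), proj], axis=1) if H > 1 else proj
        z = lfilter(strf.k_h, [1.0], padded, axis=1)[:, H - 1 :] if H > 1 else strf.k_h[0] * proj
        z = z + strf.bias
        params = _unit_params(unit, contrast_label)
        for i, win in enumerate(windows):
            rate = np.maximum(sigmoid(z[:, win], params), 0.0)
            totals[i] += rate.sum(axis=1)
    return totals


def predict_psychometric(
    units,
    contrast: ContrastRegime,
    config: NeurometricConfig,
    rng: np.random.Generator,
    grid: FrequencyGrid | None = None,
) -> PsychometricResults:
    """One simulated psychometric curve for a population in one contrast regime.

    For each target level, ``n_trials_per_level`` fresh trials are simulated.
    Summed Poisson counts across units and window bins are drawn as a single
    Poisson variate of the summed rate (the sum of independent Poisson counts
    is Poisson in their summed rate), which is statistically identical to
    per-unit draws and much faster.
    """
    grid = grid or mouse_grid()
    levels = np.asarray(config.target_levels, float)
    k_louder = np.zeros(len(levels), dtype=int)
    for i, lvl in enumerate(levels):
        spect, ref_bins, tgt_bins = _batch_trial_spectrograms(
            config.n_trials_per_level, contrast, config.reference_level, lvl, grid, rng
        )
        n_bins = spect.shape[1]
        latency = _resolve_latency(units, config.latency_bins)
        wins = [
            _decision_window(ref_bins, n_bins, latency),
            _decision_window(tgt_bins, n_bins, latency),
        ]
        lam_ref, lam_tgt = _population_window_rates(units, spect, contrast.label, wins)
        c_ref = rng.poisson(lam_ref)
        c_tgt = rng.poisson(lam_tgt)
        louder = c_tgt > c_ref
        ties = c_tgt == c_ref
        louder |= ties & (rng.random(len(ties)) < 0.5)
        k_louder[i] = int(louder.sum())
    return fit_psychometric(levels, k_louder, config.n_trials_per_level)


def predict_perceptual_adaptation(
    units,
    config: NeurometricConfig | None = None,
    grid: FrequencyGrid | None = None,
) -> dict:
    """Predicted perceptual contrast adaptation from a population of LN units.

    For each of ``n_runs`` runs: simulate full psychometric curves in the low-
    and high-contrast regimes, fit each, and convert the JND pair to a %
    compensation.  Returns the per-run values with their mean and a 95%
    confidence interval around the mean; runs whose psychometric fit pins at a
    response bound are flagged and excluded from the summary.
    """
    config = config or NeurometricConfig()
    rng = np.random.default_rng(config.seed)
    cw = config.contrast_widths
    low = ContrastRegime("low", config.mean_level, cw["low"])
    high = ContrastRegime("high", config.mean_level, cw["high"])
    comps, jnds_low, jnds_high, flagged = [], [], [], 0
    for _ in range(config.n_runs):
        fit_low = predict_psychometric(units, low, config, rng, grid)
        fit_high = predict_psychometric(units, high, config, rng, grid)
        if fit_low.flags or fit_high.flags:
            flagged += 1
            continue
        jnds_low.append(fit_low.jnd)
        jnds_high.append(fit_high.jnd)
        comps.append(behavioral_compensation(fit_low.jnd, fit_high.jnd, cw["low"], cw["high"]))
    comps_arr = np.asarray(comps)
    mean = float(comps_arr.mean()) if len(comps_arr) else float("nan")
    if len(comps_arr) > 1:
        half = 1.96 * comps_arr.std(ddof=1) / np.sqrt(len(comps_arr))
        ci = (mean - half, mean + half)
    else:
        ci = (float("nan"), float("nan"))
    return {
        "compensation_runs": comps,
        "mean_compensation": mean,
        "ci95": ci,
        "jnd_low_runs": jnds_low,
        "jnd_high_runs": jnds_high,
        "n_flagged_runs": flagged,
    }
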