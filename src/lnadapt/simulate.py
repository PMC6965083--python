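"""Ground-truth synthetic units, populations, and 2-AFC observers.

Real recordings behind the contrast-gain-control analyses are not publicly
archived, so every downstream stage of this package is validated against
simulated data with known truth: linear-nonlinear (LN) neurons with separable
STRFs, contrast-dependent sigmoid output nonlinearities, a known adaptation
time constant, and Poisson spiking in 25-ms bins; and cumulative-Gaussian
2-AFC observers with known JNDs.

Default population parameters follow the mouse study conditions: DRC regimes
of 20-dB (low) and 40-dB (high) width around a 40 dB SPL mean, quarter-octave
frequency grid from 1 to 64 kHz, sigmoid ranges of a few spikes per 25-ms bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dynamics import contrast_filter
from .sigmoid import SigmoidParams
from .stimuli import CHORD_MS, DRCStimulus, FrequencyGrid, mouse_grid
from .strf import SeparableSTRF, predict_linear

#: Phi^-1(0.75) - Phi^-1(0.25): JND of a cumulative Gaussian is 1.349 sigma
JND_PER_SIGMA = float(norm.ppf(0.75) - norm.ppf(0.25))


@dataclass
class GroundTruthUnit:
    """LN neuron with known kernels, per-contrast sigmoids and adaptation tau."""

    strf: SeparableSTRF
    params_low: SigmoidParams
    params_high: SigmoidParams
    tau_ms: float
    unit_id: int = 0

    def rate(self, stimulus: DRCStimulus) -> np.ndarray:
        """Noise-free firing rate (spikes/bin), clamped at zero for Poisson use."""
        z = predict_linear(self.strf, stimulus.levels)
        s = contrast_filter(stimulus.binary_contrast_track(), self.tau_ms)
        lo = self.params_low.as_array()
        hi = self.params_high.as_array()
        p = lo[None, :] + (hi - lo)[None, :] * s[:, None]
        x = np.clip((z - p[:, 2]) / p[:, 3], -500, 500)
        rate = p[:, 0] + p[:, 1] / (1.0 + np.exp(-x))
        return np.maximum(rate, 0.0)

    @property
    def compensation(self) -> float:
        """Ground-truth % compensation for the 20->40 dB contrast doubling."""
        g_l, g_h = self.params_low.gain, self.params_high.gain
        return (g_l - g_h) / g_h * 100.0


@dataclass
class UnitResponse:
    """Per-repeat spike counts in 25-ms bins aligned 1:1 with stimulus chords."""

    counts: np.ndarray  # (n_repeats, n_bins) non-negative ints
    bin_ms: float = CHORD_MS
    condition: str | None = None
    cortex_state: str | None = None
    stimulus: DRCStimulus | None = None
    unit_id: int = 0

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def psth(self) -> np.ndarray:
        """Trial-averaged rate, spikes/bin."""
        return self.counts.mean(axis=0)


def simulate_unit_response(
    unit: GroundTruthUnit,
    stimulus: DRCStimulus,
    n_repeats: int = 20,
    seed: int | np.random.Generator = 0,
    condition: str | None = None,
    cortex_state: str | None = None,
) -> UnitResponse:
    """Poisson spike counts of a ground-truth unit responding to a DRC."""
    if stimulus.levels.shape[1] != len(unit.strf.k_f):
        raise ValueError("stimulus frequency grid does not match the unit's STRF")
    rng = np.random.default_rng(seed)
    rate = unit.rate(stimulus)
    counts = rng.poisson(rate, size=(n_repeats, len(rate)))
    return UnitResponse(
        counts=counts,
        condition=condition,
        cortex_state=cortex_state,
        stimulus=stimulus,
        unit_id=unit.unit_id,
    )


def _temporal_kernel(n_history: int, rise_bins: float = 0.7, decay_bins: float = 2.0) -> np.ndarray:
    """Difference-of-exponentials temporal kernel, peak near lag 1."""
    h = np.arange(n_history)
    k = np.exp(-h / decay_bins) - np.exp(-h / rise_bins)
    k[0] = 0.6 * k[1] if n_history > 1 else 1.0  # partial response within the driving chord
    return k


def _spectral_kernel(n_freqs: int, center: float, sigma_channels: float = 2.0) -> np.ndarray:
    f = np.arange(n_freqs)
    return np.exp(-0.5 * ((f - center) / sigma_channels) ** 2)


def _draw_tau(tau_distribution, rng: np.random.Generator) -> float:
    if np.isscalar(tau_distribution):
        return float(tau_distribution)
    kind = tau_distribution[0]
    if kind == "uniform":
        return float(rng.uniform(tau_distribution[1], tau_distribution[2]))
    if kind == "lognormal":
        median, sigma = tau_distribution[1], tau_distribution[2]
        return float(median * np.exp(rng.normal(0.0, sigma)))
    raise ValueError(f"unknown tau distribution {tau_distribution!r}")


def make_population(
    n_units: int,
    compensation_target: float = 100.0,
    tau_distribution=("lognormal", 100.0, 0.4),
    seed: int | np.random.Generator = 0,
    grid: FrequencyGrid | None = None,
    contrast_widths: tuple[float, float] = (20.0, 40.0),
    mean_level: float = 40.0,
    jitter: float = 0.0,
    n_history: int = 10,
    y_offset: float = 0.25,
    y_range: float = 2.5,
    operating_point: str = "drc",
    probe_reference_level: float = 70.0,
) -> list[GroundTruthUnit]:
    """Construct ground-truth units whose gain change realises a compensation target.

    Gains are set through the sigmoid width d (G = b/(4d), with the y-range b
    shared between conditions): the high-contrast width is
    ``d_high = d_low * (1 + target * (C_high - C_low) / (100 * C_low))``, which
    inverts the compensation formula exactly (target 100% with a contrast
    doubling gives d_high = 2 d_low, i.e. a halving of gain; target 0% gives
    identical gains).  Best frequencies tile the interior of the grid.

    ``operating_point`` places the sigmoid midpoint c: ``"drc"`` centres it on
    the mean DRC drive (physiology fixtures, parameter recovery), ``"probe"``
    on the drive of a flat broadband-noise probe at ``probe_reference_level``
    (neurometric fixtures, where level sensitivity around the reference level
    is what matters).  Probe-point units additionally use a single-bin
    (instantaneous) temporal kernel so their drive during a noise probe is a
    monotone function of probe level alone — without this, bins whose history
    mixes probe and flanking DRC break the proportionality between neuronal
    gain and probe-level sensitivity.
    """
    if not 0.0 <= compensation_target <= 150.0:
        raise ValueError("compensation target must lie in [0, 150] %")
    rng = np.random.default_rng(seed)
    grid = grid or mouse_grid()
    n_freqs = len(grid)
    c_low_w, c_high_w = contrast_widths
    centers = np.linspace(2, n_freqs - 3, n_units) if n_units > 1 else [n_freqs // 2]

    units = []
    for i in range(n_units):
        # probe-point units integrate instantaneously and broadly: their probe
        # response is then monotone in probe level, and the flanking DRC sits
        # many drive-SDs below the sigmoid midpoint instead of spiking through
        k_h = np.ones(1) if operating_point == "probe" else _temporal_kernel(n_history)
        sigma_ch = 6.0 if operating_point == "probe" else 2.0
        k_f = _spectral_kernel(n_freqs, centers[i], sigma_ch)
        strf = SeparableSTRF(k_f, k_h, bias=0.0).canonical()
        strf.k_f /= np.linalg.norm(strf.k_f)  # unit-energy kernel

        sum_k = float(np.sum(strf.k_f) * np.sum(strf.k_h))
        if operating_point == "drc":
            c = mean_level * sum_k
            # drive SD under the low regime: tone levels i.i.d. uniform(width)
            d_low = (c_low_w / np.sqrt(12.0)) * float(
                np.linalg.norm(strf.k_f) * np.linalg.norm(strf.k_h)
            )
        elif operating_point == "probe":
            c = (probe_reference_level - 10.0 * np.log10(n_freqs)) * sum_k
            # 5 dB of probe level per sigmoid width unit: population JNDs then
            # land at a few dB, resolvable on a 2-dB target grid, while the
            # 62-78 dB span still covers the sigmoid's dynamic range
            d_low = 5.0 * sum_k
        else:
            raise ValueError("operating_point must be 'drc' or 'probe'")

        target_i = compensation_target + (rng.normal(0.0, jitter) if jitter else 0.0)
        target_i = max(target_i, 0.0)
        ratio = 1.0 + target_i * (c_high_w - c_low_w) / (100.0 * c_low_w)
        d_high = d_low * ratio

        params_low = SigmoidParams(y_offset, y_range, c, d_low)
        params_high = SigmoidParams(y_offset, y_range, c, d_high)
        tau = min(_draw_tau(tau_distribution, rng), 2000.0)
        units.append(GroundTruthUnit(strf, params_low, params_high, tau, unit_id=i))
    return units


def simulate_observer_session(
    jnd_low: float,
    jnd_high: float,
    levels,
    n_trials: int = 100,
    reference_level: float = 60.0,
    participant: str = "sim",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulated 2-AFC responses of a cumulative-Gaussian observer.

    P("louder") = Phi((target - reference)/sigma) with sigma = JND/1.349, so
    the 25-75% width of the generating curve equals the stated JND in each
    contrast condition.  Returns a tidy response table (participant, contrast,
    target_level_db, n_trials, n_louder).
    """
    if jnd_low <= 0 or jnd_high <= 0:
        raise ValueError("JNDs must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for contrast, jnd in (("low", jnd_low), ("high", jnd_high)):
        sigma = jnd / JND_PER_SIGMA
        for lvl in levels:
            p = norm.cdf((lvl - reference_level) / sigma)
            k = int(rng.binomial(n_trials, p))
            rows.append(
                {
                    "participant": participant,
                    "contrast": contrast,
                    "target_level_db": float(lvl),
                    "n_trials": n_trials,
                    "n_louder": k,
                }
            )
    return pd.DataFrame(rows)
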