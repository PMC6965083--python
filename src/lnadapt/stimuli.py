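"""Dynamic random chord (DRC) stimulus construction.

A DRC is a sequence of 25-ms chords; each chord superposes pure tones on a
logarithmic frequency grid, with each tone's level drawn independently from a
uniform distribution in dB SPL.  The *contrast* of the stimulus is the full
width of that uniform distribution (e.g. 20 dB low / 40 dB high for the mouse
stimuli; 10 dB / 30 dB for the human psychophysics variant); the mean level is
held fixed, so only the spread of levels changes between regimes.

All analysis operates on the dB-level matrix (chords x frequencies); optional
waveform rendering exists purely for export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: duration of one chord / analysis bin, ms
CHORD_MS = 25.0
#: on/off ramp inside each chord, ms (rendering only)
RAMP_MS = 5.0

MOUSE_LOW = ("low", 40.0, 20.0)
MOUSE_HIGH = ("high", 40.0, 40.0)
HUMAN_LOW = ("low", 40.0, 10.0)
HUMAN_HIGH = ("high", 40.0, 30.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmically spaced tone frequencies (Hz)."""

    f_min: float
    f_max: float
    steps_per_octave: int
    frequencies: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def octave_step(self) -> float:
        """Grid spacing in octaves."""
        return 1.0 / self.steps_per_octave


@dataclass(frozen=True)
class ContrastRegime:
    """Uniform dB-level distribution: mean level and full width ("contrast")."""

    label: str
    mean_level: float  # dB SPL
    width: float  # dB, full range of the uniform

    def __post_init__(self):
        if self.width < 0:
            raise ValueError("contrast width must be non-negative")

    @property
    def lo(self) -> float:
        return self.mean_level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.mean_level + self.width / 2.0


@dataclass
class DRCStimulus:
    """Chords x frequencies matrix of tone levels plus timing metadata.

    ``contrast_track`` carries the per-chord regime label; the binary
    high-contrast indicator used by the adaptive LN model is available via
    :meth:`binary_contrast_track`.
    """

    levels: np.ndarray  # (n_chords, n_freqs) dB SPL
    grid: FrequencyGrid
    regimes: dict[str, ContrastRegime]
    contrast_track: np.ndarray  # (n_chords,) of regime labels
    chord_ms: float = CHORD_MS
    ramp_ms: float = RAMP_MS

    @property
    def n_chords(self) -> int:
        return self.levels.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_chords * self.chord_ms

    def binary_contrast_track(self, high_label: str = "high") -> np.ndarray:
        """1 where the chord belongs to the high-contrast regime, else 0."""
        return (self.contrast_track == high_label).astype(float)

    def chord_total_levels(self) -> np.ndarray:
        """Per-chord total level, 10*log10 of summed tone power (dB)."""
        return 10.0 * np.log10(np.sum(10.0 ** (self.levels / 10.0), axis=1))

    def sliced(self, start: int, stop: int | None = None) -> "DRCStimulus":
        return replace(
            self,
            levels=self.levels[start:stop],
            contrast_track=self.contrast_track[start:stop],
        )


def make_frequency_grid(f_min: float, f_max: float, steps_per_octave: int) -> FrequencyGrid:
    """Inclusive log-spaced grid from ``f_min`` to ``f_max``.

    The octave span must be an integral number of steps: e.g. 1-64 kHz at 4
    steps/octave spans 6 octaves = 24 steps = 25 frequencies.
    """
    if f_min > f_max:
        raise ValueError("f_min must not exceed f_max")
    if steps_per_octave < 1:
        raise ValueError("steps_per_octave must be >= 1")
    span_steps = np.log2(f_max / f_min) * steps_per_octave
    n_steps = round(span_steps)
    if abs(span_steps - n_steps) > 1e-9:
        raise ValueError(
            f"octave span {np.log2(f_max / f_min):.6f} is not an integral "
            f"multiple of 1/{steps_per_octave} octave"
        )
    freqs = f_min * 2.0 ** (np.arange(n_steps + 1) / steps_per_octave)
    if n_steps:
        freqs[-1] = f_max  # exact endpoint, no roundoff drift
    return FrequencyGrid(f_min, f_max, steps_per_octave, freqs)


def mouse_grid() -> FrequencyGrid:
    """25 frequencies, 1-64 kHz at quarter-octave spacing."""
    return make_frequency_grid(1000.0, 64000.0, 4)


def human_grid() -> FrequencyGrid:
    """29 frequencies, 150 Hz-19.2 kHz at quarter-octave spacing."""
    return make_frequency_grid(150.0, 19200.0, 4)


def _regime_map(regime_track) -> tuple[dict[str, ContrastRegime], np.ndarray]:
    regimes: dict[str, ContrastRegime] = {}
    labels = []
    for r in regime_track:
        if isinstance(r, tuple):
            r = ContrastRegime(*r)
        regimes[r.label] = r
        labels.append(r.label)
    return regimes, np.asarray(labels)


def generate_drc(
    grid: FrequencyGrid,
    regime_track,
    n_chords: int | None = None,
    seed: int | np.random.Generator = 0,
) -> DRCStimulus:
    """Draw a DRC level matrix: each tone i.i.d. uniform within its chord's regime.

    ``regime_track`` is either a single :class:`ContrastRegime` (constant
    contrast, requires ``n_chords``) or a per-chord sequence of regimes.
    """
    if isinstance(regime_track, (ContrastRegime, tuple)):
        if n_chords is None:
            raise ValueError("n_chords required for a constant regime")
        if isinstance(regime_track, tuple):
            regime_track = ContrastRegime(*regime_track)
        regime_track = [regime_track] * n_chords
    regime_track = list(regime_track)
    if n_chords is not None and n_chords != len(regime_track):
        raise ValueError("n_chords disagrees with regime_track length")
    if len(regime_track) < 1:
        raise ValueError("need at least one chord")
    regimes, labels = _regime_map(regime_track)
    rng = np.random.default_rng(seed)
    lo = np.array([r.lo if not isinstance(r, tuple) else ContrastRegime(*r).lo for r in regime_track])
    hi = np.array([r.hi if not isinstance(r, tuple) else ContrastRegime(*r).hi for r in regime_track])
    u = rng.random((len(regime_track), len(grid)))
    levels = lo[:, None] + u * (hi - lo)[:, None]
    return DRCStimulus(levels=levels, grid=grid, regimes=regimes, contrast_track=labels)


def generate_switching_drc(
    grid: FrequencyGrid,
    width_low: float = 20.0,
    width_high: float = 40.0,
    epoch_s: float = 2.0,
    total_s: float = 40.0,
    mean_level: float = 40.0,
    start_high: bool = False,
    seed: int | np.random.Generator = 0,
) -> DRCStimulus:
    """DRC whose contrast alternates between low and high every ``epoch_s``."""
    chords_per_epoch = epoch_s * 1000.0 / CHORD_MS
    if abs(chords_per_epoch - round(chords_per_epoch)) > 1e-9:
        raise ValueError("epoch duration must be a whole number of chords")
    chords_per_epoch = int(round(chords_per_epoch))
    n_epochs = int(round(total_s / epoch_s))
    low = ContrastRegime("low", mean_level, width_low)
    high = ContrastRegime("high", mean_level, width_high)
    order = (high, low) if start_high else (low, high)
    track = []
    for e in range(n_epochs):
        track.extend([order[e % 2]] * chords_per_epoch)
    return generate_drc(grid, track, seed=seed)


def generate_level_matched_drc(
    grid: FrequencyGrid,
    regime_track,
    n_chords: int | None = None,
    seed: int | np.random.Generator = 0,
) -> DRCStimulus:
    """DRC with per-chord total acoustic power equalised across regimes.

    After the usual uniform draw, every chord is rescaled (a common dB shift of
    all its tones) so that its summed tone power matches the power of a chord
    whose tones all sit at the regime mean level.  This removes the small
    overall-level difference between high- and low-contrast DRCs at the
    expense of the marginal uniformity of individual tone levels.
    """
    stim = generate_drc(grid, regime_track, n_chords, seed)
    n_freqs = len(grid)
    mean_level = next(iter(stim.regimes.values())).mean_level
    target_db = mean_level + 10.0 * np.log10(n_freqs)
    total_db = stim.chord_total_levels()
    stim.levels = stim.levels + (target_db - total_db)[:, None]
    return stim


def expected_total_level_difference(regime_a: ContrastRegime, regime_b: ContrastRegime, n_freqs: int) -> float:
    """Analytic expected per-chord total-level difference (dB), regime_a - regime_b.

    The expected power of a uniform-dB tone is E[10^(L/10)]; on the log scale a
    wider uniform has a higher mean power, which is the origin of the few-dB
    overall-level difference between unmatched high- and low-contrast DRCs.
    """

    def mean_power(r: ContrastRegime) -> float:
        if r.width == 0:
            return 10.0 ** (r.mean_level / 10.0)
        k = np.log(10.0) / 10.0
        return (10.0 ** (r.hi / 10.0) - 10.0 ** (r.lo / 10.0)) / (k * r.width)

    pa, pb = n_freqs * mean_power(regime_a), n_freqs * mean_power(regime_b)
    return 10.0 * np.log10(pa / pb)


def noise_to_spectrogram(level: float, duration_ms: float, grid: FrequencyGrid) -> np.ndarray:
    """Flat spectrogram block for a broadband noise probe.

    Every channel is set to ``level - 10*log10(n_channels)`` so the channel
    powers sum to the stated total level.
    """
    n_bins = duration_ms / CHORD_MS
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("duration must be a multiple of the chord duration")
    n_bins = int(round(n_bins))
    n_freqs = len(grid)
    per_channel = level - 10.0 * np.log10(n_freqs)
    return np.full((n_bins, n_freqs), per_channel)


@dataclass
class TrialStimulus:
    """One 2-AFC level-discrimination trial: DRC flanks two noise probes.

    Layout: DRC(1000 ms) + noise(100 ms, reference) + DRC(250 ms) +
    noise(100 ms, target) + DRC(500 ms) = 1950 ms.
    """

    spectrogram: np.ndarray  # (n_bins, n_freqs) dB
    grid: FrequencyGrid
    contrast: ContrastRegime
    reference_level: float
    target_level: float
    segments: list[tuple[str, float, float | None]]  # (kind, duration ms, noise level)
    reference_bins: np.ndarray  # bin indices of the reference probe
    target_bins: np.ndarray

    @property
    def duration_ms(self) -> float:
        return self.spectrogram.shape[0] * CHORD_MS


def assemble_trial(
    contrast: ContrastRegime,
    reference_level: float = 70.0,
    target_level: float = 70.0,
    grid: FrequencyGrid | None = None,
    seed: int | np.random.Generator = 0,
    drc_ms: tuple[float, float, float] = (1000.0, 250.0, 500.0),
    noise_ms: float = 100.0,
) -> TrialStimulus:
    """Assemble a single 2-AFC trial spectrogram (defaults: the 1950-ms layout)."""
    if grid is None:
        grid = mouse_grid()
    rng = np.random.default_rng(seed)
    segs = []
    blocks = []
    probes: list[np.ndarray] = []
    cursor = 0
    plan = [
        ("drc", drc_ms[0], None),
        ("noise", noise_ms, reference_level),
        ("drc", drc_ms[1], None),
        ("noise", noise_ms, target_level),
        ("drc", drc_ms[2], None),
    ]
    for kind, dur, lvl in plan:
        n_bins = int(round(dur / CHORD_MS))
        if kind == "drc":
            block = generate_drc(grid, contrast, n_bins, rng).levels
        else:
            block = noise_to_spectrogram(lvl, dur, grid)
            probes.append(np.arange(cursor, cursor + n_bins))
        blocks.append(block)
        segs.append((kind, dur, lvl))
        cursor += n_bins
    spect = np.vstack(blocks)
    return TrialStimulus(
        spectrogram=spect,
        grid=grid,
        contrast=contrast,
        reference_level=reference_level,
        target_level=target_level,
        segments=segs,
        reference_bins=probes[0],
        target_bins=probes[1],
    )


def render_waveform(stim: DRCStimulus, sample_rate: int = 192000, seed: int = 0) -> np.ndarray:
    """Render a DRC to a pressure waveform (tones with cosine ramps, random phase).

    Export convenience only; the analysis pipeline never consumes audio.
    Levels are interpreted re an arbitrary full-scale reference (dB -> linear
    amplitude 10^(L/20)).
    """
    rng = np.random.default_rng(seed)
    n_samp_chord = int(round(stim.chord_ms * sample_rate / 1000.0))
    n_ramp = int(round(stim.ramp_ms * sample_rate / 1000.0))
    t = np.arange(n_samp_chord) / sample_rate
    env = np.ones(n_samp_chord)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    phases = rng.uniform(0, 2 * np.pi, size=len(stim.grid))
    out = np.zeros(stim.n_chords * n_samp_chord)
    for i in range(stim.n_chords):
        amps = 10.0 ** (stim.levels[i] / 20.0)
        chord = (amps[:, None] * np.sin(2 * np.pi * stim.grid.frequencies[:, None] * t + phases[:, None])).sum(axis=0)
        out[i * n_samp_chord : (i + 1) * n_samp_chord] = chord * env
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out / peak * 0.95
    return out


def save_waveform(path, waveform: np.ndarray, sample_rate: int = 192000) -> None:
    """Write a rendered stimulus waveform to a 16-bit WAV file."""
    from scipy.io import wavfile

    data = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, sample_rate, (data * 32767).astype(np.int16))
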