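"""PSTH binning, onset exclusion, and response-reliability screening.

Units are screened by how reliably they respond to repeated DRC presentations,
using the signal-power / noise-power decomposition of repeated responses:
signal power (SP) is the stimulus-locked part of the response power, noise
power (NP) the trial-to-trial remainder.  Units with NP/SP > 60 (unreliable)
or with a cross-validated linear prediction correlation below 0.1 are
excluded from the contrast-adaptation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np
import pandas as pd

from .simulate import UnitResponse
from .stimuli import CHORD_MS, DRCStimulus


def bin_psth(spike_times, stimulus: DRCStimulus, bin_ms: float = CHORD_MS, **meta) -> UnitResponse:
    """Bin spike times (ms) into per-repeat counts aligned with stimulus chords.

    ``spike_times`` is a sequence of arrays, one per repeat.  Bins are
    half-open, 0-based: a spike at exactly t = 25.0 ms falls in bin 1.  Empty
    trains are allowed (all-zero rows); spikes outside the stimulus span are
    rejected.
    """
    n_bins = int(round(stimulus.duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    rows = []
    for train in spike_times:
        train = np.asarray(train, dtype=float)
        if train.size and (train.min() < 0 or train.max() >= stimulus.duration_ms):
            raise ValueError("spike times must lie within the stimulus span")
        counts, _ = np.histogram(train, bins=edges)
        rows.append(counts)
    return UnitResponse(counts=np.asarray(rows, dtype=int), bin_ms=bin_ms, stimulus=stimulus, **meta)


def exclude_onset(response: UnitResponse, exclude_ms: float = 500.0) -> UnitResponse:
    """Drop the first ``exclude_ms`` of the response and its paired stimulus.

    Transient onset responses are not well described by the steady-state LN
    model, so the opening 500 ms of every stimulus presentation is excluded
    before any fitting.
    """
    n_drop = int(round(exclude_ms / response.bin_ms))
    if n_drop >= response.n_bins:
        raise ValueError("exclusion window must be shorter than the response")
    stim = response.stimulus.sliced(n_drop) if response.stimulus is not None else None
    return UnitResponse(
        counts=response.counts[:, n_drop:],
        bin_ms=response.bin_ms,
        condition=response.condition,
        cortex_state=response.cortex_state,
        stimulus=stim,
        unit_id=response.unit_id,
    )


@dataclass
class ReliabilityStats:
    """Signal/noise power of repeated responses plus prediction quality."""

    signal_power: float  # (spikes/bin)^2
    noise_power: float  # (spikes/bin)^2
    cc_pred: float = float("nan")
    unit_id: int = 0

    @property
    def np_sp_ratio(self) -> float:
        return self.noise_power / self.signal_power if self.signal_power > 0 else float("inf")


def signal_noise_power(response: UnitResponse | np.ndarray, cc_pred: float = float("nan"), unit_id: int = 0) -> ReliabilityStats:
    """Signal-power / noise-power decomposition of repeated responses.

    With N repeats and P(.) the variance of a response across time bins
    (population variance, divided by n_bins),

        SP = (N * P(mean over repeats) - mean_n P(trial_n)) / (N - 1)
        NP = mean_n P(trial_n) - SP

    SP is an unbiased estimate of the power of the underlying stimulus-locked
    rate: averaging N trials shrinks the noise contribution by 1/N, and the
    two-point extrapolation above removes it entirely.  By construction
    SP + NP equals the mean per-trial response power exactly.  Individual SP
    estimates can be slightly negative for unresponsive units; they are
    preserved (not clamped) so the NP/SP screen can act on them.
    """
    counts = response.counts if isinstance(response, UnitResponse) else np.asarray(response, float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need at least 2 repeats to separate signal from noise")
    n = counts.shape[0]
    power = lambda x: float(np.var(x))  # noqa: E731  variance across bins
    p_mean = power(counts.mean(axis=0))
    p_trials = float(np.mean([power(row) for row in counts]))
    sp = (n * p_mean - p_trials) / (n - 1)
    np_ = p_trials - sp
    uid = response.unit_id if isinstance(response, UnitResponse) else unit_id
    return ReliabilityStats(signal_power=sp, noise_power=np_, cc_pred=cc_pred, unit_id=uid)


def screen_units(
    stats: list[ReliabilityStats],
    np_sp_max: float = 60.0,
    cc_min: float = 0.1,
) -> pd.DataFrame:
    """Inclusion flags per unit: retain iff NP/SP <= np_sp_max and cc_pred >= cc_min.

    The boundary is inclusive (the stated exclusion rules are strict
    NP/SP > 60 and cc_pred < 0.1).  Units with non-positive signal power are
    excluded with their own reason code; a missing cc_pred only fails the
    screen if a cc threshold is in force.
    """
    rows = []
    for s in stats:
        reasons = []
        if s.signal_power <= 0:
            reasons.append("nonpositive_sp")
        elif s.np_sp_ratio > np_sp_max:
            reasons.append("np_sp_above_max")
        if cc_min is not None:
            if isnan(s.cc_pred) or s.cc_pred < cc_min:
                reasons.append("cc_pred_below_min")
        rows.append(
            {
                "unit_id": s.unit_id,
                "signal_power": s.signal_power,
                "noise_power": s.noise_power,
                "np_sp_ratio": s.np_sp_ratio,
                "cc_pred": s.cc_pred,
                "include": not reasons,
                "reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)
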