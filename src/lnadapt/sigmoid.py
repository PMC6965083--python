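"""Contrast-dependent sigmoid output nonlinearities and gain-control metrics.

For each contrast condition the observed firing rate y_t is regressed onto the
shared linear drive z_t through a 4-parameter sigmoid

    yhat_t = a + b / (1 + exp(-(z_t - c) / d))

with a the y-offset (baseline), b the y-range, c the x-offset and b/(4d) the
gain (the slope at the inflection point).  Contrast gain control is quantified
as percentage compensation for a contrast change: 100% compensation means the
gain halves when the contrast (the dB width of the stimulus level
distribution) doubles,

    % compensation = C_low (G_low - G_high) / (G_high (C_high - C_low)) * 100,

and other quantities (e.g. the y-offset a) are compared between conditions as
plain percentage change relative to the low-contrast value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class SigmoidParams:
    """Sigmoid parameters: y-offset a, y-range b, x-offset c, width d."""

    a: float
    b: float
    c: float
    d: float
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("sigmoid width d must be positive")
        if self.b < 0:
            raise ValueError("sigmoid range b must be non-negative")

    @property
    def gain(self) -> float:
        """Slope at the inflection point, b/(4d), spikes/bin per drive unit."""
        return self.b / (4.0 * self.d)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


def sigmoid(z, params: SigmoidParams | np.ndarray):
    """Evaluate the sigmoid; overflow-safe for large |z|."""
    if isinstance(params, SigmoidParams):
        a, b, c, d = params.a, params.b, params.c, params.d
    else:
        a, b, c, d = params
    x = -(np.asarray(z, dtype=float) - c) / d
    # scipy.special.expit is equivalent; inline keeps this dependency-light
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return a + b * out


def percent_compensation(g_low: float, g_high: float, c_low: float, c_high: float) -> float:
    """Percentage compensation of gain for a contrast change.

    100% = the gain exactly halves when the contrast doubles; 0% = no gain
    change.  ``c_low``/``c_high`` are the uniform-distribution dB widths of
    the two regimes.
    """
    if g_high <= 0:
        raise ValueError("high-contrast gain must be positive")
    if c_high == c_low:
        raise ValueError("contrast widths must differ")
    return c_low * (g_low - g_high) / (g_high * (c_high - c_low)) * 100.0


def percent_change(v_high: float, v_low: float) -> float:
    """Percentage change of a value from the low- to the high-contrast condition."""
    if v_low == 0:
        raise ValueError("low-condition value must be nonzero")
    return (v_high - v_low) / v_low * 100.0


def fit_sigmoid(z, y, seed: int = 0, n_quantiles: int = 9) -> SigmoidParams:
    """Least-squares sigmoid fit with a deterministic multi-start.

    The x-offset c is initialised over the 0.1..0.9 quantiles of the drive and
    the width d over decades around the drive's standard deviation; the best
    of all starts (trust-region reflective, b >= 0, d > 0) is returned.
    Degenerate (constant) responses yield b ~ 0 with a flag.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    if len(z) != len(y):
        raise ValueError("z and y must have equal length")
    if len(z) < 50:
        raise ValueError("need at least 50 bins to fit a sigmoid")
    if np.std(z) == 0:
        raise ValueError("drive is constant; sigmoid unidentifiable")
    flags: list[str] = []
    y_lo, y_hi = np.quantile(y, [0.02, 0.98])
    if np.std(y) == 0 or y_hi == y_lo:
        return SigmoidParams(float(np.mean(y)), 0.0, float(np.mean(z)), float(np.std(z)) or 1.0, ("constant_response",))

    sd = float(np.std(z))
    z_lo, z_hi = float(np.min(z)), float(np.max(z))
    d_min = max(sd * 1e-4, 1e-9)

    def resid(theta):
        return sigmoid(z, theta) - y

    def jac(theta):
        _, b, c, d = theta
        u = 1.0 / (1.0 + np.exp(np.clip(-(z - c) / d, -500, 500)))
        du = u * (1.0 - u)
        return np.column_stack([np.ones_like(z), u, -b * du / d, -b * du * (z - c) / d**2])

    # coarse screen of all starts by initial cost, then refine the best few
    starts = []
    c_inits = np.quantile(z, np.linspace(0.1, 0.9, n_quantiles))
    d_inits = [sd * s for s in (0.1, 1.0, 10.0)]
    for c0 in c_inits:
        for d0 in d_inits:
            theta0 = np.array([y_lo, max(y_hi - y_lo, 1e-6), c0, d0])
            r = resid(theta0)
            starts.append((float(r @ r), theta0))
    starts.sort(key=lambda t: t[0])
    best = None
    for _, theta0 in starts[:4]:
        try:
            sol = least_squares(
                resid,
                theta0,
                jac=jac,
                bounds=([-np.inf, 0.0, z_lo - 10 * sd, d_min], [np.inf, np.inf, z_hi + 10 * sd, np.inf]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("sigmoid fit failed from every start")
    a, b, c, d = best.x
    if b < 1e-8 * max(abs(a), 1.0):
        flags.append("near_constant_fit")
    return SigmoidParams(float(a), float(b), float(c), float(max(d, d_min)), tuple(flags))


@dataclass
class ConditionFit:
    """Sigmoid fitted to the bins of one condition on the shared drive."""

    condition: str
    params: SigmoidParams
    goodness: float  # held-out correlation between yhat and y
    n_bins: int


class ContrastLNModel:
    """Per-condition output nonlinearities on a shared linear drive.

    Parameters
    ----------
    drive : array (n_bins,)
        Linear prediction z_t from a single overall STRF fitted across all
        conditions.
    response : array (n_bins,)
        Observed rate y_t, spikes/bin.
    conditions : array (n_bins,) of labels
        Condition membership of each bin, e.g. ``("low", "high")`` contrasts
        or four contrast-by-cortex-state combinations.
    contrast_widths : dict label -> dB width
        Needed for compensation; labels must include the conditions compared.
    """

    def __init__(self, drive, response, conditions, contrast_widths: dict[str, float] | None = None):
        self.drive = np.asarray(drive, float)
        self.response = np.asarray(response, float)
        self.conditions = np.asarray(conditions)
        if not (len(self.drive) == len(self.response) == len(self.conditions)):
            raise ValueError("drive, response and conditions must align")
        self.labels = list(dict.fromkeys(self.conditions.tolist()))
        if len(self.labels) < 2:
            raise ValueError("need at least two conditions")
        self.contrast_widths = contrast_widths or {}

    def fit(self, seed: int = 0, test_frac: float = 0.1, min_bins: int = 50) -> "ContrastLNResults":
        fits: dict[str, ConditionFit] = {}
        excluded: list[str] = []
        for label in self.labels:
            mask = self.conditions == label
            z, y = self.drive[mask], self.response[mask]
            if len(z) < min_bins:
                excluded.append(label)
                continue
            n_test = max(1, int(round(len(z) * test_frac)))
            z_tr, y_tr = z[:-n_test], y[:-n_test]
            z_te, y_te = z[-n_test:], y[-n_test:]
            params = fit_sigmoid(z_tr, y_tr, seed=seed)
            yhat = sigmoid(z_te, params)
            if np.std(yhat) > 0 and np.std(y_te) > 0:
                goodness = float(np.corrcoef(y_te, yhat)[0, 1])
            else:
                goodness = 0.0
            fits[label] = ConditionFit(str(label), params, goodness, len(z))
        return ContrastLNResults(self, fits, tuple(excluded))


@dataclass
class ContrastLNResults:
    """Per-condition sigmoids plus gain/compensation/y-offset comparisons."""

    model: ContrastLNModel
    fits: dict[str, ConditionFit]
    excluded: tuple[str, ...] = ()

    def params(self, label: str) -> SigmoidParams:
        return self.fits[label].params

    def gain(self, label: str) -> float:
        return self.fits[label].params.gain

    def compensation(self, low: str = "low", high: str = "high") -> float:
        """Percentage gain compensation between two contrast conditions."""
        cw = self.model.contrast_widths
        return percent_compensation(self.gain(low), self.gain(high), cw[low], cw[high])

    def y_offset_change(self, low: str = "low", high: str = "high") -> float:
        """Percentage change of the baseline (y-offset a), high vs low contrast."""
        return percent_change(self.params(high).a, self.params(low).a)

    def gain_change(self, low: str = "low", high: str = "high") -> float:
        return percent_change(self.gain(high), self.gain(low))

    def silencing_effect(
        self,
        low_on: str = "low_on",
        high_on: str = "high_on",
        low_off: str = "low_off",
        high_off: str = "high_off",
        metric: str = "gain",
    ) -> float:
        """Cortical-silencing effect on contrast adaptation.

        Percentage change of the metric (gain or y-offset) across contrast
        with cortex silenced, minus the same change with cortex intact; 0
        means silencing leaves the contrast adaptation untouched.
        """
        if metric == "gain":
            change_on = percent_change(self.gain(high_on), self.gain(low_on))
            change_off = percent_change(self.gain(high_off), self.gain(low_off))
        elif metric == "y_offset":
            change_on = percent_change(self.params(high_on).a, self.params(low_on).a)
            change_off = percent_change(self.params(high_off).a, self.params(low_off).a)
        else:
            raise ValueError("metric must be 'gain' or 'y_offset'")
        return change_off - change_on

    def summary(self) -> str:
        lines = ["Contrast-dependent LN output nonlinearities", "  cond        a        b        c        d     gain    cc  n_bins"]
        for label, f in self.fits.items():
            p = f.params
            lines.append(
                f"  {label:<8} {p.a:8.4f} {p.b:8.4f} {p.c:8.3f} {p.d:8.3f} {p.gain:8.4f} {f.goodness:5.2f} {f.n_bins:6d}"
            )
        cw = self.model.contrast_widths
        if {"low", "high"} <= set(self.fits) and {"low", "high"} <= set(cw):
            lines.append(f"  % compensation (low->high): {self.compensation():.1f}")
            a_low = self.params('low').a
            if a_low != 0:
                lines.append(f"  % y-offset change: {self.y_offset_change():.1f}")
        if self.excluded:
            lines.append(f"  excluded (too few bins): {', '.join(self.excluded)}")
        return "\n".join(lines)


def fit_conditions(drive, response, conditions, contrast_widths=None, seed: int = 0) -> ContrastLNResults:
    """Functional wrapper: per-condition sigmoid fits on a shared drive."""
    return ContrastLNModel(drive, response, conditions, contrast_widths).fit(seed=seed)
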