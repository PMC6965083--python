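"""End-to-end orchestration: simulate -> screen -> fit -> dynamics -> neurometric.

The pipeline exercises every stage of the contrast-adaptation analysis on a
synthetic population with known truth and writes versioned outputs plus a
machine-readable summary (median compensation with a bootstrapped CI, median
adaptation time constant, fraction of units whose prediction improves with a
time constant, and the predicted perceptual compensation).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .behavior import NeurometricConfig, predict_perceptual_adaptation
from .dynamics import model_selection
from .preprocess import exclude_onset, screen_units, signal_noise_power
from .sigmoid import ContrastLNModel
from .simulate import make_population, simulate_unit_response
from .stimuli import ContrastRegime, generate_drc, generate_switching_drc, mouse_grid
from .strf import SeparableSTRFModel, cc_pred, predict_linear

logger = logging.getLogger("lnadapt")

STAGES = ("stimuli", "units", "responses", "screen", "ln", "dynamics", "neurometric")


@dataclass
class RunConfig:
    """Everything a full synthetic run needs; round-trips through YAML."""

    seed: int = 0
    output_dir: str = "lnadapt_run"
    # population
    n_units: int = 50
    compensation_target: float = 100.0
    compensation_jitter: float = 0.0
    tau_distribution: tuple = ("lognormal", 100.0, 0.4)
    # stimuli (mouse regimes)
    mean_level: float = 40.0
    contrast_widths: dict = field(default_factory=lambda: {"low": 20.0, "high": 40.0})
    duration_s: float = 40.0
    n_repeats: int = 20
    onset_exclude_ms: float = 500.0
    # screening
    np_sp_max: float = 60.0
    cc_min: float = 0.1
    # STRF / LN
    n_history: int = 10
    ridge: float = 1e-3
    # dynamics (switching-contrast paradigm)
    epoch_s: float = 2.0
    switching_total_s: float = 40.0
    dynamics_n_units: int = 12
    tau_bounds_ms: tuple = (1.0, 700.0)
    # neurometric (desk-scale defaults; the full paradigm is 500 trials x 25 runs)
    neurometric_n_units: int = 30
    neurometric_n_runs: int = 5
    neurometric_n_trials: int = 100
    reference_level: float = 70.0
    target_levels: tuple = tuple(np.arange(62.0, 79.0, 2.0))
    # summary
    bootstrap_n: int = 10000

    def to_dict(self) -> dict:
        d = asdict(self)
        td = self.tau_distribution
        if isinstance(td, (list, tuple)):
            d["tau_distribution"] = [str(td[0])] + [float(x) for x in td[1:]]
        else:
            d["tau_distribution"] = float(td)
        d["tau_bounds_ms"] = [float(v) for v in self.tau_bounds_ms]
        d["target_levels"] = [float(v) for v in self.target_levels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tau_distribution" in d and isinstance(d["tau_distribution"], list):
            td = d["tau_distribution"]
            d["tau_distribution"] = tuple(td)
        for key in ("tau_bounds_ms", "target_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path):
        lio.write_config(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(lio.read_config(path))


def bootstrap_median_ci(values, n_boot: int = 10000, seed: int = 0, alpha: float = 0.05):
    """Non-parametric bootstrap CI around the median (percentile method)."""
    values = np.asarray(values, float)
    if len(values) == 0:
        return float("nan"), (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.quantile(medians, [alpha / 2, 1 - alpha / 2])
    return float(np.median(values)), (float(lo), float(hi))


def run_pipeline(config: RunConfig, stages=None, write: bool = True) -> dict:
    """Execute the synthetic end-to-end analysis; returns the summary dict.

    ``stages`` restricts which stage *outputs* are written; prerequisite
    computations always run (they are cheap and deterministic under the
    config seeds).  Any stage failure leaves earlier outputs on disk and
    re-raises.
    """
    t0 = time.time()
    stages = set(stages or STAGES)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(STAGES, ss.spawn(len(STAGES)))}

    grid = mouse_grid()
    cw = config.contrast_widths
    regimes = {
        "low": ContrastRegime("low", config.mean_level, cw["low"]),
        "high": ContrastRegime("high", config.mean_level, cw["high"]),
    }
    n_chords = int(round(config.duration_s * 1000 / 25.0))
    stim_rng = np.random.default_rng(seeds["stimuli"])
    stimuli = {
        lbl: generate_drc(grid, regimes[lbl], n_chords, stim_rng) for lbl in ("low", "high")
    }
    switching = generate_switching_drc(
        grid,
        cw["low"],
        cw["high"],
        epoch_s=config.epoch_s,
        total_s=config.switching_total_s,
        mean_level=config.mean_level,
        seed=stim_rng,
    )
    if write and "stimuli" in stages:
        for lbl, stim in stimuli.items():
            lio.write_stimulus(stim, out / f"stimulus_{lbl}.npz")
        lio.write_stimulus(switching, out / "stimulus_switching.npz")
    logger.info("stimuli: %d chords per condition, switching %g s", n_chords, config.switching_total_s)

    units = make_population(
        config.n_units,
        compensation_target=config.compensation_target,
        tau_distribution=config.tau_distribution,
        seed=seeds["units"],
        grid=grid,
        contrast_widths=(cw["low"], cw["high"]),
        mean_level=config.mean_level,
        jitter=config.compensation_jitter,
        n_history=config.n_history,
    )
    logger.info("population: %d units, target compensation %.0f%%", len(units), config.compensation_target)

    # responses + onset exclusion; PSTHs concatenated low-then-high per unit
    resp_rng = np.random.default_rng(seeds["responses"])
    onset = config.onset_exclude_ms
    per_unit = []
    for u in units:
        resps = {
            lbl: exclude_onset(
                simulate_unit_response(u, stimuli[lbl], config.n_repeats, resp_rng, condition=lbl),
                onset,
            )
            for lbl in ("low", "high")
        }
        per_unit.append(resps)
    if write and "responses" in stages:
        for u, resps in zip(units, per_unit):
            for lbl, r in resps.items():
                lio.write_response(r, out / f"response_unit{u.unit_id:03d}_{lbl}.npz")

    # screening: SP/NP on pooled conditions, cc_pred from a held-out STRF fit
    stats = []
    fits = {}
    for u, resps in zip(units, per_unit):
        counts = np.hstack([resps["low"].counts, resps["high"].counts])
        levels = np.vstack([resps["low"].stimulus.levels, resps["high"].stimulus.levels])
        conditions = np.array(
            ["low"] * resps["low"].n_bins + ["high"] * resps["high"].n_bins
        )
        psth = counts.mean(axis=0)
        n_test = max(1, int(round(len(psth) * 0.1)))
        strf = SeparableSTRFModel(
            psth[:-n_test], levels[:-n_test], config.n_history, config.ridge
        ).fit().strf
        cc = cc_pred(psth[-n_test:], predict_linear(strf, levels[-n_test:]))
        stats.append(signal_noise_power(counts, cc_pred=cc, unit_id=u.unit_id))
        fits[u.unit_id] = (psth, levels, conditions)
    screen = screen_units(stats, np_sp_max=config.np_sp_max, cc_min=config.cc_min)
    retained = screen[screen.include].unit_id.tolist()
    if write and "screen" in stages:
        screen.to_csv(out / "screening.csv", index=False)
    logger.info("screening: %d/%d units retained", len(retained), len(units))

    # combined STRF + per-condition sigmoids -> compensation per unit
    ln_rows = []
    for uid in retained:
        psth, levels, conditions = fits[uid]
        strf = SeparableSTRFModel(psth, levels, config.n_history, config.ridge).fit().strf
        drive = predict_linear(strf, levels)
        res = ContrastLNModel(drive, psth, conditions, {"low": cw["low"], "high": cw["high"]}).fit()
        if not {"low", "high"} <= set(res.fits):
            continue
        row = {"unit_id": uid, "compensation_pct": res.compensation()}
        for lbl in ("low", "high"):
            p = res.params(lbl)
            row.update({f"{k}_{lbl}": v for k, v in zip("abcd", p.as_array())})
            row[f"gain_{lbl}"] = p.gain
            row[f"cc_{lbl}"] = res.fits[lbl].goodness
        try:
            row["y_offset_change_pct"] = res.y_offset_change()
        except ValueError:
            row["y_offset_change_pct"] = float("nan")
        ln_rows.append(row)
    ln_table = pd.DataFrame(ln_rows)
    if write and "ln" in stages:
        ln_table.to_csv(out / "contrast_ln.csv", index=False)

    # adaptation dynamics on the switching stimulus (subset of retained units)
    dyn_rows = []
    dyn_rng = np.random.default_rng(seeds["dynamics"])
    dyn_units = [u for u in units if u.unit_id in retained][: config.dynamics_n_units]
    for u in dyn_units:
        resp = exclude_onset(
            simulate_unit_response(u, switching, config.n_repeats, dyn_rng), onset
        )
        sel = model_selection(resp.stimulus, resp.psth())
        sel.update({"unit_id": u.unit_id, "tau_true_ms": u.tau_ms})
        dyn_rows.append(sel)
    dyn_table = pd.DataFrame(dyn_rows)
    if write and "dynamics" in stages:
        dyn_table.to_csv(out / "dynamics.csv", index=False)

    # neurometric prediction from a probe-operating-point population with the
    # same compensation target (probe-level sensitivity is what the 2-AFC
    # decision reads out; see docs/methods.md)
    neuro_units = make_population(
        config.neurometric_n_units,
        compensation_target=config.compensation_target,
        tau_distribution=config.tau_distribution,
        seed=seeds["units"],
        grid=grid,
        contrast_widths=(cw["low"], cw["high"]),
        mean_level=config.mean_level,
        jitter=config.compensation_jitter,
        operating_point="probe",
        probe_reference_level=config.reference_level,
    )
    ncfg = NeurometricConfig(
        reference_level=config.reference_level,
        target_levels=config.target_levels,
        n_trials_per_level=config.neurometric_n_trials,
        n_runs=config.neurometric_n_runs,
        contrast_widths=dict(cw),
        mean_level=config.mean_level,
        seed=int(seeds["neurometric"].generate_state(1)[0] % (2**31)),
    )
    neuro = predict_perceptual_adaptation(neuro_units, ncfg, grid)
    if write and "neurometric" in stages:
        pd.DataFrame({"run": range(len(neuro["compensation_runs"])), "compensation_pct": neuro["compensation_runs"]}).to_csv(
            out / "neurometric_runs.csv", index=False
        )

    boot_seed = int(ss.generate_state(1)[0] % (2**31))
    med_comp, comp_ci = bootstrap_median_ci(
        ln_table["compensation_pct"] if len(ln_table) else [], config.bootstrap_n, boot_seed
    )
    tau_vals = dyn_table[dyn_table.contrast_dependent_better]["tau_ms"] if len(dyn_table) else []
    med_tau, tau_ci = bootstrap_median_ci(tau_vals, config.bootstrap_n, boot_seed + 1)
    summary = {
        "n_units": len(units),
        "n_retained": len(retained),
        "median_compensation_pct": med_comp,
        "compensation_ci95": list(comp_ci),
        "median_y_offset_change_pct": float(np.median(ln_table["y_offset_change_pct"])) if len(ln_table) else float("nan"),
        "median_tau_ms": med_tau,
        "tau_ci95": list(tau_ci),
        "fraction_tau_improves": float(np.mean(dyn_table["tau_improves"])) if len(dyn_table) else float("nan"),
        "predicted_perceptual_compensation_pct": neuro["mean_compensation"],
        "predicted_perceptual_ci95": list(neuro["ci95"]),
        "elapsed_s": round(time.time() - t0, 2),
    }
    if write:
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        config.save(out / "config.yaml")
        (out / "run.log").write_text(
            "\n".join(
                [
                    f"lnadapt pipeline run (seed {config.seed})",
                    f"retained {len(retained)}/{len(units)} units",
                    f"median compensation {med_comp:.1f}% CI {comp_ci}",
                    f"median tau {med_tau:.1f} ms",
                    f"fraction tau_improves {summary['fraction_tau_improves']}",
                    f"predicted perceptual compensation {neuro['mean_compensation']:.1f}%",
                    f"elapsed {summary['elapsed_s']} s",
                ]
            )
        )
    return summary
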