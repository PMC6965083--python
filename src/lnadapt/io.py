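"""File formats: spike tables (CSV), stimulus/response archives, configs (YAML/JSON).

All tabular data travel as CSV with a schema-version comment header; matrix
data (stimulus level matrices, spike-count arrays) are stored as ``.npz``
archives with an embedded JSON metadata string.  Write -> read round-trips
are identity on all fields; a version mismatch raises an explicit error.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SPIKE_TABLE_VERSION = 1
ARCHIVE_VERSION = 1
CONFIG_VERSION = 1

SPIKE_COLUMNS = ["unit_id", "trial_id", "condition", "time_ms"]


class SchemaVersionError(ValueError):
    pass


def _check_version(found: int, expected: int, what: str):
    if int(found) != expected:
        raise SchemaVersionError(f"{what} schema v{found}, this build reads v{expected}")


# ---------------------------------------------------------------------------
# spike tables


def write_spike_table(df: pd.DataFrame, path) -> None:
    """CSV with columns (unit_id, trial_id, condition, time_ms) and a version header."""
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table missing columns: {missing}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# lnadapt-spike-table v{SPIKE_TABLE_VERSION}\n")
        df[SPIKE_COLUMNS].to_csv(fh, index=False)


def read_spike_table(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# lnadapt-spike-table v"):
            raise SchemaVersionError(f"{path} lacks a spike-table version header")
        _check_version(int(header.rsplit("v", 1)[1]), SPIKE_TABLE_VERSION, "spike table")
        body = fh.read()
    try:
        df = pd.read_csv(_io.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas formats the message
        raise ValueError(f"{path}: malformed spike table: {exc}") from exc
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: spike table missing columns {missing}")
    times = pd.to_numeric(df["time_ms"], errors="coerce")
    bad = times.isna()
    if bad.any():
        # +3: version line, header line, 1-based data rows
        raise ValueError(f"{path}: non-numeric time_ms at line {int(bad.idxmax()) + 3}")
    df["time_ms"] = times
    return df


def spike_table_to_trains(df: pd.DataFrame, unit_id, condition=None) -> list[np.ndarray]:
    """Per-trial spike-time arrays (ms) for one unit, ordered by trial_id."""
    sub = df[df.unit_id == unit_id]
    if condition is not None:
        sub = sub[sub.condition == condition]
    return [np.sort(g["time_ms"].to_numpy(float)) for _, g in sub.groupby("trial_id", sort=True)]


# ---------------------------------------------------------------------------
# matrix archives (stimuli, responses)


def write_archive(path, metadata: dict, **arrays) -> None:
    """``.npz`` archive with named arrays and a JSON metadata string."""
    meta = dict(metadata)
    meta["schema_version"] = ARCHIVE_VERSION
    np.savez(path, __metadata__=np.array(json.dumps(meta)), **arrays)


def read_archive(path) -> tuple[dict, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__metadata__"]))
        _check_version(meta.pop("schema_version", -1), ARCHIVE_VERSION, "archive")
        arrays = {k: npz[k] for k in npz.files if k != "__metadata__"}
    return meta, arrays


def write_stimulus(stim, path) -> None:
    from .stimuli import DRCStimulus  # local import avoids a cycle

    assert isinstance(stim, DRCStimulus)
    meta = {
        "kind": "drc_stimulus",
        "chord_ms": stim.chord_ms,
        "ramp_ms": stim.ramp_ms,
        "grid": {
            "f_min": stim.grid.f_min,
            "f_max": stim.grid.f_max,
            "steps_per_octave": stim.grid.steps_per_octave,
        },
        "regimes": {
            lbl: {"mean_level": r.mean_level, "width": r.width} for lbl, r in stim.regimes.items()
        },
    }
    labels = np.array(stim.contrast_track, dtype="U16")
    write_archive(path, meta, levels=stim.levels, contrast_track=labels)


def read_stimulus(path):
    from .stimuli import ContrastRegime, DRCStimulus, make_frequency_grid

    meta, arrays = read_archive(path)
    g = meta["grid"]
    grid = make_frequency_grid(g["f_min"], g["f_max"], g["steps_per_octave"])
    regimes = {
        lbl: ContrastRegime(lbl, r["mean_level"], r["width"]) for lbl, r in meta["regimes"].items()
    }
    return DRCStimulus(
        levels=arrays["levels"],
        grid=grid,
        regimes=regimes,
        contrast_track=arrays["contrast_track"],
        chord_ms=meta["chord_ms"],
        ramp_ms=meta["ramp_ms"],
    )


def write_response(resp, path) -> None:
    meta = {
        "kind": "unit_response",
        "bin_ms": resp.bin_ms,
        "condition": resp.condition,
        "cortex_state": resp.cortex_state,
        "unit_id": resp.unit_id,
    }
    write_archive(path, meta, counts=resp.counts)


def read_response(path):
    from .simulate import UnitResponse

    meta, arrays = read_archive(path)
    return UnitResponse(
        counts=arrays["counts"],
        bin_ms=meta["bin_ms"],
        condition=meta["condition"],
        cortex_state=meta["cortex_state"],
        unit_id=meta["unit_id"],
    )


# ---------------------------------------------------------------------------
# configs


def write_config(config_dict: dict, path) -> None:
    doc = {"schema_version": CONFIG_VERSION, **config_dict}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaVersionError(f"{path} is not a mapping")
    _check_version(doc.pop("schema_version", -1), CONFIG_VERSION, "config")
    return doc
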