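import numpy as np
import pytest

import lnadapt as ln


@pytest.fixture(scope="session")
def grid():
    return ln.mouse_grid()


@pytest.fixture(scope="session")
def low_regime():
    return ln.ContrastRegime("low", 40.0, 20.0)


@pytest.fixture(scope="session")
def high_regime():
    return ln.ContrastRegime("high", 40.0, 40.0)


@pytest.fixture(scope="session")
def mouse_drcs(grid, low_regime, high_regime):
    """40-s constant-contrast DRCs in both mouse regimes (1600 chords)."""
    return {
        "low": ln.generate_drc(grid, low_regime, 1600, seed=101),
        "high": ln.generate_drc(grid, high_regime, 1600, seed=102),
    }


@pytest.fixture(scope="session")
def switching_drc(grid):
    """40 s of 2-s alternating 20/40-dB contrast epochs."""
    return ln.generate_switching_drc(grid, total_s=40.0, seed=103)


def simulate_screened_psth(unit, stimulus, n_repeats, seed, onset_ms=500.0):
    """Helper: simulate, onset-exclude, and return (psth, stimulus slice)."""
    resp = ln.exclude_onset(ln.simulate_unit_response(unit, stimulus, n_repeats, seed=seed), onset_ms)
    return resp.psth(), resp.stimulus
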