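"""Shared fixtures: small synthetic sessions and hand-built analysis objects."""

from types import SimpleNamespace

import numpy as np
import pytest

from ca3theta import lfp, synth
from ca3theta.lfp import ThetaPhaseSeries


@pytest.fixture(scope="session")
def control_session_small():
    """A small control-like session plus its extracted theta phase series."""
    cfg = synth.preset_config("control", n_cells=6, n_passes_per_cell=20, seed=101)
    session = synth.generate_session(cfg)
    channel = lfp.select_theta_channel(session)
    phases = lfp.extract_theta_phase(session.channel(channel))
    return cfg, session, phases


@pytest.fixture()
def analytic_phases():
    """An ideal 8 Hz phase series (no filtering) on a fine time grid."""

    def build(duration=300.0, freq=8.0, fs=1000.0):
        t = np.arange(0.0, duration, 1.0 / fs)
        u = 360.0 * freq * t
        return ThetaPhaseSeries(t, np.mod(u, 360.0), np.floor(u / 360.0).astype(int), "ideal", u)

    return build


def make_train(d, phases, cycles=None, unit_id="u0", **extra):
    """Duck-typed train for precession-level tests."""
    d = np.asarray(d, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if cycles is None:
        cycles = np.arange(d.size)
    return SimpleNamespace(
        unit_id=unit_id,
        d=d,
        spike_phases=np.mod(phases, 360.0),
        spike_cycles=np.asarray(cycles, dtype=int),
        **extra,
    )


@pytest.fixture()
def train_factory():
    return make_train
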