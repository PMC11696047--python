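"""Phenomenological oscillatory-interference model of a CA3 place cell.

A single model cell receives two excitatory theta-band oscillations -- a
dentate-gyrus input at 8.6 Hz weighted toward the early part of the place
field and a medial-entorhinal input at 8.5 Hz weighted toward the late part
-- and one inhibitory oscillation at the 8 Hz LFP theta frequency. The
rectified, spatially modulated sum is the intensity of an inhomogeneous
Poisson process; because the excitatory inputs run slightly faster than the
inhibition, spikes drift to earlier phases of the 8 Hz reference as the
traversal progresses: phase precession by interference.

Inputs:
    G_dg(t)  = gamma_dg  * (1 + cos(2 pi nu_dg t))
    G_mec(t) = gamma_mec * (1 + cos(psi + 2 pi nu_mec t))
    G_inh(t) = I_dc + A cos(phi_inh + 2 pi nu_inh t)
Spatial modulation (x = normalized position in [0, 1]):
    M_dg(x)  = N(x; 0.3, 0.45) ** eta_dg,   eta_dg  = 0.128
    M_mec(x) = N(x; 0.7, 0.75) ** eta_mec,  eta_mec = 1.88
Total drive:
    G(t) = max(0, M_dg G_dg + M_mec G_mec - (1/8) G_inh)

Spike phases are read from the 8 Hz reference oscillation phase-locked to
the inhibition, offset so that LFP phase 180 deg falls at the inhibition
minimum (maximal firing). Lesions are simulated by zeroing one excitatory
gain. The free parameters (A, phi_inh) are explored on a grid and matched
against empirical percentile bands of the four precession measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .circstats import circular_mean, circular_median, wrap_difference
from .precession import DEFAULT_SLOPE_BOUNDS, PrecessionMeasures, circ_lin_regression

log = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "SimulatedPass",
    "total_drive",
    "simulate_pass",
    "measure_pass",
    "simulate_experiment",
    "lesion_instantiate",
    "AdmissibilityGrid",
    "scan_parameter_grid",
    "percentile_band",
    "admissibility_match",
    "onset_offset_from_accepted",
    "psi_sensitivity",
]

MEASUREMENTS = ("slope", "rsquared", "phi_on", "phi_off")
CIRCULAR_MEASUREMENTS = ("phi_on", "phi_off")


@dataclass(frozen=True)
class ModelParams:
    """All symbols of the three-input interference model (angles in deg)."""

    nu_dg: float = 8.6  # Hz
    nu_mec: float = 8.5  # Hz
    nu_inh: float = 8.0  # Hz
    psi: float = 0.0  # excitatory phase differential, deg
    phi_inh: float = 260.0  # excitatory-inhibitory phase differential, deg
    A: float = 3.0  # inhibition oscillation amplitude
    i_dc_mean: float = 0.0  # baseline inhibition
    i_dc_var: float = 0.025
    gamma_dg: float = 1.0
    gamma_mec: float = 1.0
    eta_dg: float = 0.128
    eta_mec: float = 1.88
    mod_dg: tuple = (0.3, 0.45)  # (mu, sigma) of the DG spatial Gaussian
    mod_mec: tuple = (0.7, 0.75)
    inh_weight: float = 0.125
    duration: float = 2.0  # s, constant-velocity traversal of x in [0, 1]
    r_max: float = 15.0  # Hz, peak intensity after drive normalization
    lfp_offset: float = 180.0  # deg, LFP phase at minimum inhibition

    def validate(self):
        if min(self.nu_dg, self.nu_mec, self.nu_inh) <= 0:
            raise ValueError("oscillation frequencies must be positive")
        if self.A < 0 or self.duration <= 0 or self.r_max <= 0:
            raise ValueError("A >= 0, duration > 0, r_max > 0 required")
        if self.gamma_dg < 0 or self.gamma_mec < 0:
            raise ValueError("gains must be nonnegative")
        return self


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def total_drive(params: ModelParams, t, x, i_dc=None) -> np.ndarray:
    """Rectified total drive G(t) at times ``t`` and normalized positions
    ``x``. ``i_dc`` overrides the baseline inhibition draw (pass the sampled
    value; defaults to the mean, i.e. noise off)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if i_dc is None:
        i_dc = params.i_dc_mean
    g_dg = params.gamma_dg * (1.0 + np.cos(2.0 * np.pi * params.nu_dg * t))
    g_mec = params.gamma_mec * (1.0 + np.cos(np.deg2rad(params.psi) + 2.0 * np.pi * params.nu_mec * t))
    g_inh = i_dc + params.A * np.cos(np.deg2rad(params.phi_inh) + 2.0 * np.pi * params.nu_inh * t)
    m_dg = _gauss(x, *params.mod_dg) ** params.eta_dg
    m_mec = _gauss(x, *params.mod_mec) ** params.eta_mec
    drive = m_dg * g_dg + m_mec * g_mec - params.inh_weight * g_inh
    return np.maximum(drive, 0.0)


def reference_phase(params: ModelParams, t) -> np.ndarray:
    """Phase (deg, [0, 360)) of the 8 Hz LFP reference, phase-locked to the
    inhibitory oscillation with ``lfp_offset`` at the inhibition minimum."""
    t = np.asarray(t, dtype=float)
    ph = params.phi_inh + 360.0 * params.nu_inh * t + (params.lfp_offset - 180.0)
    return np.mod(ph, 360.0)


def reference_cycle(params: ModelParams, t) -> np.ndarray:
    u = params.phi_inh + 360.0 * params.nu_inh * np.asarray(t, dtype=float) + (params.lfp_offset - 180.0)
    return np.floor(u / 360.0).astype(int)


@dataclass
class SimulatedPass:
    """One constant-velocity traversal's spikes (times s, phases deg,
    positions in [0, 1])."""

    spike_times: np.ndarray
    spike_phases: np.ndarray
    spike_cycles: np.ndarray
    positions: np.ndarray
    i_dc: float
    empty: bool = False

    @property
    def d(self):  # precession-module duck typing
        return self.positions


def simulate_pass(params: ModelParams, rng=None, dt: float = 5e-4) -> SimulatedPass:
    """Simulate one traversal as an inhomogeneous Poisson process.

    The drive is normalized to peak intensity ``r_max``; the expected spike
    count is the intensity integral; spike times are drawn by inverse-CDF
    sampling of the normalized intensity (exact for an inhomogeneous Poisson
    process). The baseline inhibition I_dc is redrawn once per pass.
    """
    params.validate()
    rng = np.random.default_rng(rng)
    i_dc = float(rng.normal(params.i_dc_mean, np.sqrt(params.i_dc_var)))
    t = np.arange(0.0, params.duration + dt, dt)
    x = t / params.duration
    g = total_drive(params, t, x, i_dc=i_dc)
    gmax = g.max()
    if gmax <= 0:
        log.warning("zero total drive: empty pass")
        empty = np.empty(0)
        return SimulatedPass(empty, empty, empty.astype(int), empty, i_dc, empty=True)
    intensity = params.r_max * g / gmax
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (intensity[1:] + intensity[:-1]) * dt)])
    total = cum[-1]
    n = rng.poisson(total)
    if n == 0:
        empty = np.empty(0)
        return SimulatedPass(empty, empty, empty.astype(int), empty, i_dc, empty=True)
    u = np.sort(rng.uniform(0.0, total, n))
    times = np.interp(u, cum, t)
    return SimulatedPass(
        times,
        reference_phase(params, times),
        reference_cycle(params, times),
        times / params.duration,
        i_dc,
    )


def measure_pass(passes, slope_bounds=DEFAULT_SLOPE_BOUNDS) -> PrecessionMeasures | None:
    """Pooled precession measurement over one or several simulated passes,
    using the identical regression code path as the empirical analysis."""
    if isinstance(passes, SimulatedPass):
        passes = [passes]
    d = np.concatenate([p.positions for p in passes]) if passes else np.empty(0)
    th = np.concatenate([p.spike_phases for p in passes]) if passes else np.empty(0)
    if d.size < 5 or np.ptp(d) == 0:
        return None
    return circ_lin_regression(d, th, slope_bounds=slope_bounds)


def _pass_onset_offset(p: SimulatedPass):
    cyc = p.spike_cycles
    first = cyc == cyc.min()
    last = cyc == cyc.max()
    return circular_mean(p.spike_phases[first]), circular_mean(p.spike_phases[last])


def simulate_experiment(params: ModelParams, n_passes: int, rng=None, slope_bounds=DEFAULT_SLOPE_BOUNDS):
    """Simulate ``n_passes`` traversals and return the four measurements:
    pooled slope and R-squared, and the circular means of the per-pass onset
    and offset phases. NaNs where undefined (no spikes)."""
    rng = np.random.default_rng(rng)
    passes = [simulate_pass(params, rng) for _ in range(n_passes)]
    live = [p for p in passes if not p.empty]
    out = {k: float("nan") for k in MEASUREMENTS}
    m = measure_pass(live, slope_bounds=slope_bounds)
    if m is not None:
        out["slope"] = m.slope
        out["rsquared"] = m.rsquared
    oo = [_pass_onset_offset(p) for p in live if p.spike_times.size > 0]
    if oo:
        out["phi_on"] = circular_mean([a for a, _ in oo])
        out["phi_off"] = circular_mean([b for _, b in oo])
    return out, m


def lesion_instantiate(params: ModelParams, lesion: str = "none", ratio=None) -> ModelParams:
    """Return a copy of ``params`` with the lesion applied.

    ``lesion``: 'none', 'dg' (gamma_dg = 0) or 'mec' (gamma_mec = 0).
    ``ratio`` rescales the two gains to 75/125 (or the reverse, pass
    '125/75') of their mean while preserving the summed excitation;
    applying the same call twice is idempotent.
    """
    lesion = lesion.lower()
    if lesion not in ("none", "dg", "mec"):
        raise ValueError(f"unknown lesion label {lesion!r}")
    p = params
    if ratio is not None:
        total = p.gamma_dg + p.gamma_mec
        if isinstance(ratio, str):
            a, b = (float(v) for v in ratio.split("/"))
        else:
            a, b = (float(v) for v in ratio)
        fa, fb = a / (a + b), b / (a + b)
        p = replace(p, gamma_dg=fa * total, gamma_mec=fb * total)
    if lesion == "dg":
        p = replace(p, gamma_dg=0.0)
    elif lesion == "mec":
        p = replace(p, gamma_mec=0.0)
    return p


# --------------------------------------------------------- parameter scan


@dataclass
class AdmissibilityGrid:
    """Per-(A, phi_inh) measurement layers and, after matching, admissibility."""

    A_values: np.ndarray
    phi_values: np.ndarray
    layers: dict  # measurement -> (nA, nphi) array
    n_passes: int
    seed: int
    admissible: dict = field(default_factory=dict)  # measurement -> bool array
    overlap: np.ndarray | None = None

    @property
    def accepted(self) -> np.ndarray:
        if self.overlap is None:
            raise ValueError("run admissibility_match first")
        return self.overlap == len(self.admissible)

    def coverage(self) -> dict:
        """Fraction of grid points admissible per measurement (diagnostic)."""
        return {k: float(v.mean()) for k, v in self.admissible.items()}


def point_rng(seed: int, i: int, j: int):
    """Deterministic, reconstructible generator for grid point (i, j)."""
    return np.random.default_rng([seed, i, j])


def scan_parameter_grid(
    base: ModelParams,
    A_range=(0.0, 5.0),
    n_A: int = 25,
    phi_range=(0.0, 360.0),
    n_phi: int = 40,
    n_passes: int = 50,
    seed: int = 0,
) -> AdmissibilityGrid:
    """Simulate the model over the (A, phi_inh) grid.

    At every grid point ``n_passes`` traversals are simulated with a
    deterministic per-point seed and the four measurements recorded. The full-resolution
    grid is 250 x 1000; the default here is a 25 x 40 reduction (the full
    grid is hours-scale on one CPU).
    """
    A_vals = np.linspace(*A_range, n_A)
    phi_vals = np.linspace(phi_range[0], phi_range[1], n_phi, endpoint=False)
    layers = {k: np.full((n_A, n_phi), np.nan) for k in MEASUREMENTS}
    for i, A in enumerate(A_vals):
        for j, phi in enumerate(phi_vals):
            p = replace(base, A=float(A), phi_inh=float(phi))
            out, _ = simulate_experiment(p, n_passes, rng=point_rng(seed, i, j))
            for k in MEASUREMENTS:
                layers[k][i, j] = out[k]
    return AdmissibilityGrid(A_vals, phi_vals, layers, n_passes, seed)


def percentile_band(samples, coverage: float = 0.8, circular: bool = False):
    """Percentile interval centered on the median covering ``coverage`` of
    the sample. Circular bands are computed on deviations wrapped around the
    circular median and returned as (lo_deg, hi_deg) arc endpoints."""
    s = np.asarray(samples, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("empty sample for percentile band")
    tail = 100.0 * (1.0 - coverage) / 2.0
    if not circular:
        return float(np.percentile(s, tail)), float(np.percentile(s, 100.0 - tail))
    center = circular_median(s)
    dev = np.asarray(wrap_difference(s, center), dtype=float)
    lo, hi = np.percentile(dev, [tail, 100.0 - tail])
    return float(np.mod(center + lo, 360.0)), float(np.mod(center + hi, 360.0))


def _in_band(values, band, circular):
    lo, hi = band
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not circular:
        inside = (v >= lo) & (v <= hi)
    else:
        width = np.mod(hi - lo, 360.0)
        if width == 0:
            width = 360.0
        inside = np.mod(v - lo, 360.0) <= width
    return inside & ok


def admissibility_match(grid: AdmissibilityGrid, empirical_bands: dict) -> AdmissibilityGrid:
    """Mark grid points whose measurements fall inside the empirical bands.

    ``empirical_bands`` maps each measurement name to its (lo, hi) band;
    onset/offset bands are circular arcs. The overlap layer counts
    admissible measurements per point; points with all four are accepted.
    An empty accepted set is returned as-is (inspect ``coverage()``).
    """
    adm = {}
    for k in MEASUREMENTS:
        if k not in empirical_bands:
            raise KeyError(f"missing empirical band for {k!r}")
        adm[k] = _in_band(grid.layers[k], empirical_bands[k], k in CIRCULAR_MEASUREMENTS)
    overlap = np.sum([adm[k] for k in MEASUREMENTS], axis=0)
    out = AdmissibilityGrid(
        grid.A_values, grid.phi_values, grid.layers, grid.n_passes, grid.seed, adm, overlap
    )
    if not out.accepted.any():
        log.warning("empty accepted set; per-measurement coverage: %s", out.coverage())
    return out


def onset_offset_from_accepted(grid: AdmissibilityGrid, widened_bands: dict):
    """Distributions of onset/offset phases over the accepted region under
    the widened (90th-percentile) bands. Raises if still empty."""
    matched = admissibility_match(grid, widened_bands)
    acc = matched.accepted
    if not acc.any():
        raise ValueError(f"empty accepted set even after widening; coverage: {matched.coverage()}")
    return {
        "phi_on": grid.layers["phi_on"][acc],
        "phi_off": grid.layers["phi_off"][acc],
    }


def psi_sensitivity(
    base: ModelParams, psi_values, n_passes: int = 50, seed: int = 0, slope_bounds=DEFAULT_SLOPE_BOUNDS
):
    """Pooled slope as a function of the excitatory phase differential psi,
    all else fixed (for comparing sensitivity against phi_inh)."""
    out = np.full(len(psi_values), np.nan)
    for i, psi in enumerate(psi_values):
        p = replace(base, psi=float(psi))
        res, _ = simulate_experiment(p, n_passes, rng=np.random.default_rng([seed, 9999, i]), slope_bounds=slope_bounds)
        out[i] = res["slope"]
    return np.asarray(psi_values, dtype=float), out
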