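"""Synthetic session generator.

Builds complete :class:`~ca3theta.session.Session` objects with the
statistical structure the downstream analyses assume -- a theta-band LFP,
straight constant-speed runs across a linear track embedded in a 2-D arena,
place-modulated units whose spike phases precess along the field, and
optional co-active cell pairs with theta-timescale lags proportional to
field separation -- so every pipeline stage is testable without recordings.

Construction guarantees
-----------------------
* Spike times are placed so that the spike lies **exactly** on its intended
  phase-distance line as evaluated against the analytic phase of the clean
  theta component of the generated LFP: with zero jitter, every train's
  fitted circular-linear slope equals the configured slope.
* Pair units fire once per theta cycle (probabilistically, Gaussian-gated
  by their own field) at a fixed phase, the second unit offset by the
  configured lag, so the cross-correlogram peak nearest zero recovers the
  lag within one bin.

Presets
-------
``control``    narrow onset-phase concentration (kappa ~ 1.9) at a late mean
               onset (~228 deg), steep slope (-150 deg/traversal).
``dg_lesion``  broadened onset concentration (kappa ~ 0.42), shallower slope,
               extra early-phase spikes.
``mec_lesion`` preserved onset, inflated within-cycle phase jitter.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .session import LfpChannel, Session, SpikeUnit, TrackingSeries

__all__ = [
    "SyntheticConfig",
    "load_preset",
    "preset_config",
    "generate_session",
    "generate_pair_session",
    "PRESET_NAMES",
]

PRESET_NAMES = ("control", "dg_lesion", "mec_lesion")


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Stated world of one synthetic session (units: s, cm, deg, Hz)."""

    n_cells: int = 50
    n_passes_per_cell: int = 50
    theta_freq: float = 8.0
    theta_asymmetry: float = 0.0  # log duration ratio ascent/descent
    field_length: float = 30.0
    run_speed: float = 20.0
    precession_slope: float = -150.0  # deg per traversal; negative = precession
    onset_phase_mean: float = 228.4
    onset_phase_kappa: float = 1.91  # across-cell onset concentration
    within_cycle_sd: float = 40.0  # deg, von Mises phase jitter
    train_onset_sd: float = 15.0  # deg, train-to-train onset jitter within a cell
    early_phase_excess: float = 0.0  # per-cycle prob of an extra early-third spike
    spikes_per_pass: float = 9.0
    pair_spec: tuple = ()  # ((field_distance_cm, theta_lag_ms), ...)
    seed: int = 0
    arena_size: float = 100.0
    track_margin: float = 5.0
    track_y: float = 50.0
    lfp_fs: float = 500.0
    lfp_amplitude: float = 500.0  # uV
    lfp_noise_db: float = -20.0  # pink noise power relative to theta
    frame_rate: float = 29.97
    trial_gap: float = 1.0
    group_label: str = "SYNTH"

    def validate(self):
        if self.theta_freq <= 0 or self.lfp_fs <= 0 or self.run_speed <= 0:
            raise ConfigError("frequencies and speed must be positive")
        if self.onset_phase_kappa < 0:
            raise ConfigError("kappa must be >= 0")
        if not 0.0 <= self.early_phase_excess <= 1.0:
            raise ConfigError("early_phase_excess must be a probability")
        if self.field_length > self.arena_size - 2 * self.track_margin:
            raise ConfigError("infeasible geometry: field_length exceeds the track")
        return self


def load_preset(name: str) -> dict:
    """Load a preset's parameter overrides from the packaged YAML file."""
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = importlib.resources.files("ca3theta") / "presets" / f"{name}.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh) or {}


def preset_config(name: str, **overrides) -> SyntheticConfig:
    params = dict(load_preset(name))
    params.update(overrides)
    return SyntheticConfig(**params).validate()


def _sd_to_kappa(sd_deg: float) -> float:
    if sd_deg <= 0:
        return np.inf
    return 1.0 / np.deg2rad(sd_deg) ** 2


def _vm_jitter(rng, sd_deg: float, size) -> np.ndarray:
    """Von Mises jitter (deg) with circular sd approximately ``sd_deg``."""
    kappa = _sd_to_kappa(sd_deg)
    if np.isinf(kappa):
        return 0.0 if size is None else np.zeros(size)
    return np.rad2deg(rng.vonmises(0.0, kappa, size))


def _pink_noise(rng, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return pink / pink.std()


class _Track:
    """Linear track geometry shared by all units of a session."""

    def __init__(self, cfg: SyntheticConfig):
        self.x0 = cfg.track_margin
        self.x1 = cfg.arena_size - cfg.track_margin
        self.length = self.x1 - self.x0
        self.run_duration = self.length / cfg.run_speed
        self.period = self.run_duration + cfg.trial_gap
        self.speed = cfg.run_speed

    def trial_interval(self, i: int):
        t0 = i * self.period
        return (t0, t0 + self.run_duration)

    def x_at(self, i: int, t: np.ndarray) -> np.ndarray:
        t0 = i * self.period
        return np.clip(self.x0 + self.speed * (t - t0), self.x0, self.x1)

    def time_at(self, i: int, x) -> np.ndarray:
        t0 = i * self.period
        return t0 + (np.asarray(x, dtype=float) - self.x0) / self.speed


def _snap_spike_times(cfg, t_entry, d_targets, phase_line_offset, slope):
    """Spike times lying exactly on the phase-distance line.

    The intended phase at normalized field distance d is
    ``offset + slope * d`` while the LFP phase advances as 360 f t; both are
    linear in time, so their congruence (mod 360) has evenly spaced
    solutions. For each target distance we take the solution nearest the
    target time; the returned spikes then sit exactly on the line at their
    *realized* distances.
    """
    f = cfg.theta_freq
    v = cfg.run_speed
    L = cfg.field_length
    # phase_line(t) = offset + slope * (t - t_entry) * v / L
    a = 360.0 * f - slope * v / L  # deg/s advance of (lfp - line)
    b = -phase_line_offset + slope * v * t_entry / L
    t_targets = t_entry + np.asarray(d_targets, dtype=float) * L / v
    m = np.round((a * t_targets + b) / 360.0)
    return (360.0 * m - b) / a


def _unit_spikes(cfg, track, rng, center_x, onset_mu, frame_t):
    """All spike times of one precessing place cell across every pass.

    The first and last spike of each pass sit at the field entry and exit,
    and the per-pass phase line is pre-compensated for the train anchors the
    detector will use (the tracking frames bracketing the spikes), so the
    downstream regression on anchor-normalized distance recovers the
    configured slope exactly when jitter is zero. The anchor compensation is
    a short fixed-point iteration on the (discrete) anchor frame indices.
    """
    f = cfg.theta_freq
    L = cfg.field_length
    entry_x = center_x - L / 2.0
    spikes = []
    for i in range(cfg.n_passes_per_cell):
        t_entry = track.time_at(i, entry_x)
        onset = onset_mu + _vm_jitter(rng, cfg.train_onset_sd, None)
        n_interior = rng.poisson(max(cfg.spikes_per_pass - 2.0, 0.0))
        d = np.concatenate([[0.0], np.sort(rng.beta(2.0, 2.0, n_interior)), [1.0]])

        s_eff, off_eff = cfg.precession_slope, onset
        anchors = None
        for _ in range(6):
            t_exact = _snap_spike_times(cfg, t_entry, d, off_eff, s_eff)
            j0 = np.searchsorted(frame_t, t_exact[0], side="right") - 1
            j1 = np.searchsorted(frame_t, t_exact[-1], side="left")
            if (j0, j1) == anchors or j0 < 0 or j1 >= frame_t.size:
                break
            anchors = (j0, j1)
            pos0 = track.x_at(i, frame_t[j0])
            pos1 = track.x_at(i, frame_t[j1])
            span = pos1 - pos0
            if span <= 0:
                break
            s_eff = cfg.precession_slope * L / span
            off_eff = onset + cfg.precession_slope * (entry_x - pos0) / span

        # within-cycle jitter shifts the spike along the LFP phase axis
        jit = _vm_jitter(rng, cfg.within_cycle_sd, d.size)
        t_spk = t_exact + jit / (360.0 * f)
        if cfg.early_phase_excess > 0:
            n_half_cycles = max(1, int(round(0.5 * L / cfg.run_speed * f)))
            n_extra = rng.binomial(n_half_cycles, cfg.early_phase_excess)
            if n_extra:
                d_x = rng.uniform(0.0, 0.5, n_extra)
                ph_x = rng.uniform(0.0, 120.0, n_extra)
                t_x = _snap_spike_times(cfg, t_entry, d_x, 0.0, 0.0)
                t_x = t_x + ph_x / (360.0 * f)
                t_spk = np.concatenate([t_spk, t_x])
        lo, hi = track.trial_interval(i)
        t_spk = t_spk[(t_spk >= lo) & (t_spk <= hi)]
        spikes.append(t_spk)
    if not spikes:
        return np.empty(0)
    out = np.sort(np.concatenate(spikes))
    keep = np.concatenate([[True], np.diff(out) > 2e-3])  # refractory dedupe
    return out[keep]


def _pair_unit_spikes(cfg, track, rng, center_x, lag_s, spike_phase=200.0, gate_sigma=12.0, gate_halfwidth=30.0):
    """Once-per-theta-cycle spiking gated by a Gaussian place field.

    Returns spike times at the fixed theta phase (plus ``lag_s``), emitted
    in cycles where a Bernoulli draw under the field gate succeeds. The
    caller supplies the same per-cycle uniform draws to correlate paired
    units only through the shared cycle clock.
    """
    f = cfg.theta_freq
    spikes = []
    for i in range(cfg.n_passes_per_cell):
        lo, hi = track.trial_interval(i)
        k0 = int(np.ceil((lo * f * 360.0 - spike_phase) / 360.0))
        k1 = int(np.floor((hi * f * 360.0 - spike_phase) / 360.0))
        ks = np.arange(k0, k1 + 1)
        t_k = (spike_phase / 360.0 + ks) / f
        x_k = track.x_at(i, t_k)
        gate = np.abs(x_k - center_x) <= gate_halfwidth
        prob = np.exp(-0.5 * ((x_k - center_x) / gate_sigma) ** 2)
        fire = gate & (rng.uniform(size=t_k.size) < prob)
        t_spk = t_k[fire] + lag_s
        t_spk = t_spk[(t_spk >= lo) & (t_spk <= hi)]
        spikes.append(t_spk)
    return np.sort(np.concatenate(spikes)) if spikes else np.empty(0)


def _build_lfp(cfg, rng, t_total):
    n = int(np.ceil(t_total * cfg.lfp_fs)) + 1
    t = np.arange(n) / cfg.lfp_fs
    theta_phase = 2.0 * np.pi * cfg.theta_freq * t
    if cfg.theta_asymmetry != 0.0:
        # phase warp: positive asymmetry lengthens the ascending limb
        alpha = np.clip(cfg.theta_asymmetry, -0.9, 0.9)
        wave = np.cos(theta_phase - alpha * np.sin(theta_phase))
    else:
        wave = np.cos(theta_phase)
    theta = cfg.lfp_amplitude * wave
    theta_power = np.mean(theta**2)
    noise_power = theta_power * 10.0 ** (cfg.lfp_noise_db / 10.0)
    noise = _pink_noise(rng, n, cfg.lfp_fs) * np.sqrt(noise_power)
    main = theta + noise
    # second, weaker channel exercises reference-channel selection
    other = 0.3 * theta + _pink_noise(rng, n, cfg.lfp_fs) * np.sqrt(noise_power)
    return [
        LfpChannel("ch0", cfg.lfp_fs, main),
        LfpChannel("ch1", cfg.lfp_fs, other),
    ]


def _build_tracking(cfg, track, n_trials):
    t_total = n_trials * track.period
    t = np.arange(0.0, t_total, 1.0 / cfg.frame_rate)
    trial_idx = np.floor(t / track.period).astype(int)
    x = np.empty_like(t)
    for i in range(n_trials):
        sel = trial_idx == i
        x[sel] = track.x_at(i, t[sel])
    y = np.full_like(t, cfg.track_y)
    return TrackingSeries(t, x, y, frame_rate=cfg.frame_rate), t_total


def generate_session(cfg: SyntheticConfig) -> Session:
    """Generate a full synthetic session from the configuration.

    Identical ``cfg`` (including seed) gives an identical session.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    track = _Track(cfg)
    n_trials = cfg.n_passes_per_cell
    tracking, t_total = _build_tracking(cfg, track, n_trials)
    lfp = _build_lfp(cfg, rng, t_total)
    trials = [track.trial_interval(i) for i in range(n_trials)]

    units = []
    if cfg.n_cells > 0:
        lo = cfg.track_margin + cfg.field_length / 2.0 + 5.0
        hi = cfg.arena_size - lo
        centers = np.linspace(lo, hi, cfg.n_cells)
        onsets = cfg.onset_phase_mean + (
            np.rad2deg(rng.vonmises(0.0, cfg.onset_phase_kappa, cfg.n_cells))
            if cfg.onset_phase_kappa > 0 and np.isfinite(cfg.onset_phase_kappa)
            else np.zeros(cfg.n_cells)
        )
        for c, (cx, mu) in enumerate(zip(centers, onsets)):
            units.append(SpikeUnit(f"cell{c:03d}", _unit_spikes(cfg, track, rng, cx, mu, tracking.t)))

    for p, (dist, lag_ms) in enumerate(cfg.pair_spec):
        if abs(lag_ms) > 500.0 / cfg.theta_freq:
            warnings.warn(
                f"pair {p}: lag {lag_ms} ms exceeds half a theta cycle; wrapping ambiguity",
                RuntimeWarning,
                stacklevel=2,
            )
        base_x = cfg.arena_size / 2.0 - dist / 2.0
        units.append(
            SpikeUnit(f"pair{p}A", _pair_unit_spikes(cfg, track, rng, base_x, 0.0))
        )
        units.append(
            SpikeUnit(f"pair{p}B", _pair_unit_spikes(cfg, track, rng, base_x + dist, lag_ms / 1000.0))
        )

    return Session(
        session_id=f"synth-{cfg.seed}",
        units=units,
        tracking=tracking,
        lfp=lfp,
        trials=trials,
        group_label=cfg.group_label,
        meta={"synthetic": True, "seed": cfg.seed},
    ).validate()


def generate_pair_session(cfg: SyntheticConfig) -> Session:
    """Session containing only the configured co-active pairs."""
    if not cfg.pair_spec:
        raise ConfigError("generate_pair_session requires a nonempty pair_spec")
    return generate_session(replace(cfg, n_cells=0))
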