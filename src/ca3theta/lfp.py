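"""LFP filtering, theta phase extraction, band power, wave asymmetry and the
speed dependence of theta frequency.

Theta phase convention
----------------------
Phase is the angle of the analytic signal of the 6-10 Hz band-passed LFP,
``atan2(Im H(s), Re H(s))``, mapped to degrees on [0, 360). Phase 0 is the
peak of the filtered wave; a theta *cycle* is the interval between successive
phase-0 crossings, and every sample carries a nondecreasing integer cycle
index. All filters are zero-phase (forward-backward) so phase estimates are
unbiased by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import linregress

from .session import LfpChannel, Session, in_trials_mask

__all__ = [
    "bandpass",
    "ThetaPhaseSeries",
    "extract_theta_phase",
    "select_theta_channel",
    "band_power",
    "AsymmetryResult",
    "asymmetry_index",
    "theta_speed_regression",
    "theta_frequency",
]

THETA_BAND = (6.0, 10.0)
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (6.0, 10.0),
    "slow_gamma": (25.0, 50.0),
    "fast_gamma": (50.0, 100.0),
}


def bandpass(x, fs: float, lo: float, hi: float, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order ``order``, applied forward-backward)."""
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz exceeds Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class ThetaPhaseSeries:
    """Instantaneous theta phase sampled on the LFP clock.

    ``phase`` is wrapped to [0, 360); ``cycle_index`` increments by one at
    every wrap. ``unwrapped`` (phase + 360 * absolute cycle) supports linear
    interpolation at arbitrary spike times.
    """

    t: np.ndarray
    phase: np.ndarray
    cycle_index: np.ndarray
    source_channel: str
    unwrapped: np.ndarray

    def phase_at(self, times) -> np.ndarray:
        """Phase (deg, [0, 360)) at arbitrary times, by interpolating the
        unwrapped phase."""
        u = np.interp(np.asarray(times, dtype=float), self.t, self.unwrapped)
        return np.mod(u, 360.0)

    def unwrapped_at(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.t, self.unwrapped)

    def cycle_at(self, times) -> np.ndarray:
        """Integer theta-cycle index at arbitrary times (same origin as
        ``cycle_index``)."""
        u = self.unwrapped_at(times)
        base = np.floor(self.unwrapped[0] / 360.0)
        return (np.floor(u / 360.0) - base).astype(int)

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_index[-1] - self.cycle_index[0] + 1)


def extract_theta_phase(lfp: LfpChannel, band=THETA_BAND) -> ThetaPhaseSeries:
    """Instantaneous theta phase of one LFP channel via the Hilbert transform."""
    if lfp.fs < 200:
        raise ValueError("extract_theta_phase requires fs >= 200 Hz")
    if lfp.duration < 3.0 / band[0]:
        raise ValueError("segment shorter than 3 theta cycles")
    s = bandpass(lfp.samples, lfp.fs, *band)
    analytic = signal.hilbert(s)
    u = np.rad2deg(np.unwrap(np.angle(analytic)))
    phase = np.mod(u, 360.0)
    base = np.floor(u[0] / 360.0)
    cycle = (np.floor(u / 360.0) - base).astype(int)
    return ThetaPhaseSeries(lfp.t, phase, cycle, lfp.channel_id, u)


def select_theta_channel(session: Session, band=THETA_BAND) -> str:
    """Reference-channel choice: the channel with the largest theta-band
    rectified RMS power (RMS of the 6-10 Hz filtered signal)."""
    if not session.lfp:
        raise ValueError("session has no LFP channels")
    best_id, best_rms = None, 0.0
    for ch in session.lfp:
        filt = bandpass(ch.samples, ch.fs, *band)
        rms = float(np.sqrt(np.mean(filt**2)))
        if rms > best_rms:
            best_id, best_rms = ch.channel_id, rms
    if best_id is None:
        raise ValueError("all LFP channels are zero in the theta band")
    return best_id


def band_power(lfp: LfpChannel, bands=None) -> dict:
    """Average power (uV^2) of the band-passed signal in each named band."""
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    out = {}
    for name, (lo, hi) in bands.items():
        if hi >= lfp.fs / 2:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist for fs={lfp.fs}")
        if not np.any(lfp.samples):
            out[name] = 0.0
            continue
        filt = bandpass(lfp.samples, lfp.fs, lo, hi)
        out[name] = float(np.mean(filt**2))
    return out


@dataclass
class AsymmetryResult:
    per_cycle: np.ndarray
    mean: float
    n_skipped: int


def asymmetry_index(lfp: LfpChannel, broad_band=(1.0, 80.0)) -> AsymmetryResult:
    """Theta-wave asymmetry: log duration ratio of ascending to descending limb.

    Cycles are segmented on the 6-10 Hz phase; within each cycle the wave
    peak is the maximum of the 1-80 Hz filtered signal over the first half
    (phase 0-180 deg) and the trough is the minimum over the second half
    (180-360 deg). The per-cycle index is ``ln(ascent / descent)`` where
    ascent runs trough -> next peak and descent runs peak -> trough; zero
    means a symmetric wave. Cycles without usable extrema are skipped and
    counted.
    """
    phases = extract_theta_phase(lfp)
    if phases.n_cycles < 3:
        raise ValueError("asymmetry_index needs at least 3 complete theta cycles")
    broad = bandpass(lfp.samples, lfp.fs, *broad_band)
    t = lfp.t

    cycles = np.arange(phases.cycle_index[0] + 1, phases.cycle_index[-1])  # complete only
    peak_t = np.full(cycles.size, np.nan)
    trough_t = np.full(cycles.size, np.nan)
    skipped = 0
    for i, c in enumerate(cycles):
        in_cycle = phases.cycle_index == c
        first = in_cycle & (phases.phase < 180.0)
        second = in_cycle & (phases.phase >= 180.0)
        if first.sum() < 2 or second.sum() < 2:
            skipped += 1
            continue
        peak_t[i] = t[first][np.argmax(broad[first])]
        trough_t[i] = t[second][np.argmin(broad[second])]

    idx = []
    for i in range(cycles.size - 1):
        descent = trough_t[i] - peak_t[i]
        ascent = peak_t[i + 1] - trough_t[i]
        if not (np.isfinite(descent) and np.isfinite(ascent)) or descent <= 0 or ascent <= 0:
            skipped += 1
            continue
        idx.append(np.log(ascent / descent))
    idx = np.asarray(idx)
    mean = float(idx.mean()) if idx.size else float("nan")
    return AsymmetryResult(idx, mean, skipped)


def _speed(tracking):
    from .trains import estimate_speed

    return estimate_speed(tracking)


def _peak_theta_frequency_series(
    ch: LfpChannel, band=THETA_BAND, window_s: float = 5.0, step_s: float = 0.5
):
    """Time-resolved peak frequency in the theta band from a sliding-window
    spectrogram (5 s window, 0.5 s step, zero-padded for fine frequency
    resolution)."""
    nper = int(round(window_s * ch.fs))
    if ch.samples.size < nper:
        raise ValueError("LFP shorter than the spectrogram window")
    noverlap = nper - int(round(step_s * ch.fs))
    nfft = int(2 ** np.ceil(np.log2(nper * 4)))
    f, tt, Sxx = signal.spectrogram(
        ch.samples, fs=ch.fs, nperseg=nper, noverlap=noverlap, nfft=nfft, window="hann"
    )
    sel = (f >= band[0]) & (f <= band[1])
    peak = f[sel][np.argmax(Sxx[sel], axis=0)]
    return ch.t0 + tt, peak


def theta_speed_regression(
    session: Session, v_min: float = 2.0, speed_bin: float = 2.0, channel: str | None = None
):
    """Regression of theta frequency on running speed.

    The time-resolved 6-10 Hz peak frequency is interpolated to the tracking
    samples, restricted to in-trial movement (speed > ``v_min``), speed is
    binned at ``speed_bin`` cm/s, and a linear regression is fitted to the
    per-bin mean frequencies. Returns ``(r, p, slope)`` with slope in
    Hz / (cm/s).
    """
    ch = session.channel(channel) if channel else session.channel(select_theta_channel(session))
    tt, peak = _peak_theta_frequency_series(ch)
    track = session.tracking
    speed = _speed(track)
    mask = in_trials_mask(track.t, session.trials) & (speed > v_min)
    dt = np.median(np.diff(track.t)) if track.t.size > 1 else 0.0
    if mask.sum() * dt < 60.0:
        raise ValueError("theta_speed_regression needs >= 60 s of tracked movement")
    freq = np.interp(track.t[mask], tt, peak)
    spd = speed[mask]
    bins = np.floor(spd / speed_bin).astype(int)
    centers, means = [], []
    for b in np.unique(bins):
        sel = bins == b
        centers.append((b + 0.5) * speed_bin)
        means.append(freq[sel].mean())
    if len(centers) < 3:
        raise ValueError("fewer than 3 occupied speed bins")
    res = linregress(np.asarray(centers), np.asarray(means))
    return float(res.rvalue), float(res.pvalue), float(res.slope)


def theta_frequency(session: Session, v_min: float = 2.0, channel: str | None = None) -> float:
    """Session theta frequency: median 6-10 Hz peak frequency during movement."""
    ch = session.channel(channel) if channel else session.channel(select_theta_channel(session))
    tt, peak = _peak_theta_frequency_series(ch)
    track = session.tracking
    speed = _speed(track)
    mask = in_trials_mask(track.t, session.trials) & (speed > v_min)
    if not np.any(mask):
        raise ValueError("empty movement mask")
    freq = np.interp(track.t[mask], tt, peak)
    return float(np.median(freq))
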