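"""Cell-pair theta-timescale sequence analysis.

For simultaneously recorded, co-active cell pairs: eligibility screening on
shared theta cycles, the cross-correlogram lag tau of the peak nearest zero,
the signed separation d of the two place-field peaks, and the compression
regression of tau on d whose positive slope is the signature of theta
sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import linregress

log = logging.getLogger(__name__)

__all__ = [
    "PairCounts",
    "pair_eligibility",
    "cross_correlogram",
    "cross_correlogram_tau",
    "field_distance",
    "compression_regression",
    "project_train_to_pair_axis",
    "PairRecord",
]


@dataclass
class PairCounts:
    shared_cycles: int
    cycles_a: int
    cycles_b: int
    spike_share_a: float  # fraction of A's spikes in shared cycles
    spike_share_b: float
    cycle_share_a: float  # shared / cycles in which A spiked
    cycle_share_b: float


@dataclass
class PairRecord:
    unit_a: str
    unit_b: str
    eligible: bool
    counts: PairCounts
    tau_ms: float | None = None
    d_cm: float | None = None
    direction_sign: int = 0


def pair_eligibility(
    spikes_a,
    spikes_b,
    phases,
    min_shared_cycles: int = 50,
    min_spike_share: float = 0.2,
    min_cycle_share: float = 0.1,
):
    """Evaluate the three co-activity predicates on cycle-labeled spikes.

    (a) >= ``min_shared_cycles`` theta cycles in which both units spiked;
    (b) >= ``min_spike_share`` of each unit's spikes fall in shared cycles;
    (c) shared cycles are >= ``min_cycle_share`` of each unit's active
    cycles. Returns ``(eligible, PairCounts)``.
    """
    ca = np.asarray(phases.cycle_at(np.asarray(spikes_a, dtype=float)))
    cb = np.asarray(phases.cycle_at(np.asarray(spikes_b, dtype=float)))
    if ca.size == 0 or cb.size == 0:
        counts = PairCounts(0, 0, 0, 0.0, 0.0, 0.0, 0.0)
        return False, counts
    set_a, set_b = np.unique(ca), np.unique(cb)
    shared = np.intersect1d(set_a, set_b, assume_unique=True)
    spike_share_a = float(np.isin(ca, shared).mean())
    spike_share_b = float(np.isin(cb, shared).mean())
    counts = PairCounts(
        shared_cycles=int(shared.size),
        cycles_a=int(set_a.size),
        cycles_b=int(set_b.size),
        spike_share_a=spike_share_a,
        spike_share_b=spike_share_b,
        cycle_share_a=shared.size / set_a.size,
        cycle_share_b=shared.size / set_b.size,
    )
    eligible = (
        counts.shared_cycles >= min_shared_cycles
        and counts.spike_share_a >= min_spike_share
        and counts.spike_share_b >= min_spike_share
        and counts.cycle_share_a >= min_cycle_share
        and counts.cycle_share_b >= min_cycle_share
    )
    return eligible, counts


def cross_correlogram(spikes_a, spikes_b, bin_ms: float = 10.0, window_s: float = 4.0):
    """Spike cross-correlogram: histogram of t_b - t_a over +-window/2.

    Returns ``(lags_ms, counts)`` with lag-bin centers in milliseconds.
    """
    a = np.sort(np.asarray(spikes_a, dtype=float))
    b = np.sort(np.asarray(spikes_b, dtype=float))
    half = window_s / 2.0
    bin_s = bin_ms / 1000.0
    # bin centers on integer multiples of the bin width, symmetric about 0
    n_half = int(round(half / bin_s))
    centers_s = np.arange(-n_half, n_half + 1) * bin_s
    edges = np.concatenate([centers_s - bin_s / 2.0, [centers_s[-1] + bin_s / 2.0]])
    half = -edges[0]
    counts = np.zeros(edges.size - 1)
    lo = np.searchsorted(b, a - half, side="left")
    hi = np.searchsorted(b, a + half, side="right")
    for t, i0, i1 in zip(a, lo, hi):
        if i1 > i0:
            counts += np.histogram(b[i0:i1] - t, bins=edges)[0]
    lags_ms = 1000.0 * 0.5 * (edges[:-1] + edges[1:])
    return lags_ms, counts


def cross_correlogram_tau(
    spikes_a,
    spikes_b,
    bin_ms: float = 10.0,
    window_s: float = 4.0,
    smooth_ms: float = 20.0,
    search_ms: float = 200.0,
):
    """Theta-timescale lag: the smoothed-correlogram local maximum closest
    to zero lag, searched within +- ``search_ms``. Plateau ties break toward
    the smaller absolute lag; a flat correlogram yields None.
    """
    lags, counts = cross_correlogram(spikes_a, spikes_b, bin_ms, window_s)
    if counts.sum() == 0:
        log.warning("flat cross-correlogram: no spikes in window")
        return None
    smooth = gaussian_filter1d(counts.astype(float), smooth_ms / bin_ms)
    sel = np.abs(lags) <= search_ms
    idx = np.flatnonzero(sel)
    seg = smooth[idx]
    if np.ptp(seg) == 0:
        log.warning("flat cross-correlogram in the search window")
        return None
    # local maxima (plateau-aware): >= both neighbors, with global-window ends allowed
    peaks = []
    for k in range(seg.size):
        left = seg[k - 1] if k > 0 else -np.inf
        right = seg[k + 1] if k < seg.size - 1 else -np.inf
        if seg[k] >= left and seg[k] >= right:
            peaks.append(k)
    if not peaks:
        return None
    k = min(peaks, key=lambda k: (abs(lags[idx[k]]), -seg[k]))
    return float(lags[idx[k]])


def field_distance(field_a, field_b, direction=None) -> float:
    """Signed Euclidean separation of two place-field peaks.

    Positive when field A is visited before field B along the run
    ``direction`` (a 2-vector); unsigned with a warning when no direction is
    available.
    """
    pa = np.asarray(field_a.peak_xy, dtype=float)
    pb = np.asarray(field_b.peak_xy, dtype=float)
    d = float(np.hypot(*(pb - pa)))
    if direction is None:
        warnings.warn("run direction undefined; returning unsigned field distance", RuntimeWarning, stacklevel=2)
        return d
    u = np.asarray(direction, dtype=float)
    nu = np.hypot(*u)
    if nu == 0:
        warnings.warn("zero-length run direction; returning unsigned field distance", RuntimeWarning, stacklevel=2)
        return d
    sign = np.sign(float(np.dot(pb - pa, u / nu)))
    return d if sign == 0 else float(sign) * d


def compression_regression(pairs):
    """Linear regression of theta lag tau (ms) on field separation d (cm).

    ``pairs`` is a sequence of (d, tau); returns ``(r, p, slope)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("compression_regression needs >= 3 (d, tau) pairs")
    d, tau = arr[:, 0], arr[:, 1]
    if np.ptp(d) == 0:
        raise ValueError("constant field distances")
    res = linregress(d, tau)
    return float(res.rvalue), float(res.pvalue), float(res.slope)


def project_train_to_pair_axis(train, field_a, field_b) -> np.ndarray:
    """Project a train's spike positions onto the segment joining the two
    field peaks; the segment midpoint is the origin, positive toward B."""
    pa = np.asarray(field_a.peak_xy, dtype=float)
    pb = np.asarray(field_b.peak_xy, dtype=float)
    seg = pb - pa
    norm = np.hypot(*seg)
    if norm == 0:
        raise ValueError("coincident field peaks: zero-length pair axis")
    u = seg / norm
    mid = 0.5 * (pa + pb)
    xy = np.column_stack([train.spike_x, train.spike_y])
    return (xy - mid) @ u
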