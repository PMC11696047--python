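"""Spike-train (pass) detection, movement masking, rate maps, spatial firing
measures and 20%-contour place fields.

A *spike train* (a.k.a. pass) is the unit of phase-precession analysis: a
maximal run of >= 5 consecutive spikes with inter-spike intervals <= 0.5 s,
kept only if it lasts 0.3-2.5 s, its path is >= 20 cm long, the path
endpoints are >= 10 cm apart, and the animal's mean speed over the pass
exceeds 2 cm/s. A cell contributes no trains at all if its session mean rate
is outside [0.1, 5] Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter
from skimage import measure as skmeasure

from .session import Session, SpikeUnit, TrackingSeries, in_trials_mask

log = logging.getLogger(__name__)

__all__ = [
    "TrainCriteria",
    "DetectedTrain",
    "estimate_speed",
    "movement_mask",
    "detect_trains",
    "normalized_distance",
    "RateMap",
    "rate_map",
    "PlaceField",
    "extract_place_field",
    "SpatialMeasures",
    "spatial_measures",
    "information_content",
    "selectivity",
    "sparsity",
]


@dataclass(frozen=True)
class TrainCriteria:
    """Validity thresholds for spike-train detection."""

    min_spikes: int = 5
    max_isi: float = 0.5  # s
    min_duration: float = 0.3  # s (first to last spike)
    max_duration: float = 2.5  # s
    min_path_length: float = 20.0  # cm
    min_endpoint_separation: float = 10.0  # cm
    min_mean_speed: float = 2.0  # cm/s
    rate_gate: tuple = (0.1, 5.0)  # Hz, applied to the cell's session rate


@dataclass
class DetectedTrain:
    """One qualifying pass: spikes, phases, geometry and normalized distances."""

    unit_id: str
    spike_times: np.ndarray
    spike_phases: np.ndarray  # deg, [0, 360)
    spike_cycles: np.ndarray  # theta cycle index per spike
    spike_x: np.ndarray
    spike_y: np.ndarray
    start_xy: tuple
    end_xy: tuple
    t_start: float  # anchor tracking sample before the first spike
    t_end: float  # anchor tracking sample after the last spike
    path_length: float  # cm, along tracking between the anchors
    d: np.ndarray  # normalized distance per spike, [0, 1]

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        """Spike-defined extent: last spike time minus first spike time."""
        return float(self.spike_times[-1] - self.spike_times[0])

    @property
    def endpoint_separation(self) -> float:
        return float(np.hypot(self.end_xy[0] - self.start_xy[0], self.end_xy[1] - self.start_xy[1]))

    @property
    def mean_speed(self) -> float:
        return self.path_length / (self.t_end - self.t_start)

    def satisfies(self, criteria: TrainCriteria = TrainCriteria()) -> bool:
        """Independent re-check of all five validity predicates."""
        isis = np.diff(self.spike_times)
        return bool(
            self.n_spikes >= criteria.min_spikes
            and (isis.size == 0 or isis.max() <= criteria.max_isi)
            and criteria.min_duration <= self.duration <= criteria.max_duration
            and self.path_length >= criteria.min_path_length
            and self.endpoint_separation >= criteria.min_endpoint_separation
            and self.mean_speed > criteria.min_mean_speed
        )


def estimate_speed(tracking: TrackingSeries, smooth_s: float = 0.25) -> np.ndarray:
    """Running speed (cm/s) from central differences of the tracked position,
    smoothed with a ``smooth_s``-second boxcar."""
    t, x, y = tracking.t, tracking.x, tracking.y
    if t.size < 2:
        return np.zeros(t.size)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    dt = np.median(np.diff(t))
    w = max(1, int(round(smooth_s / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def movement_mask(tracking: TrackingSeries, trials, v_min: float = 2.0) -> np.ndarray:
    """True where the (smoothed) speed exceeds ``v_min`` inside a trial."""
    if not trials:
        raise ValueError("movement_mask requires at least one trial interval")
    speed = estimate_speed(tracking)
    return in_trials_mask(tracking.t, trials) & (speed > v_min)


def _cumulative_path(tracking: TrackingSeries) -> np.ndarray:
    steps = np.hypot(np.diff(tracking.x), np.diff(tracking.y))
    return np.concatenate([[0.0], np.cumsum(steps)])


def detect_trains(
    unit: SpikeUnit,
    tracking: TrackingSeries,
    phases,
    trials=None,
    criteria: TrainCriteria = TrainCriteria(),
) -> list:
    """Detect all qualifying spike trains of one unit.

    ``phases`` is a ThetaPhaseSeries used to stamp each spike with its theta
    phase and cycle index. When ``trials`` is given, the cell-level rate gate
    uses the summed trial time and spikes outside trials are ignored.
    Returns an empty list when the cell fails the rate gate.
    """
    spikes = unit.spike_times
    if trials:
        total_time = float(sum(b - a for a, b in trials))
        spikes = spikes[in_trials_mask(spikes, trials)]
    else:
        total_time = float(tracking.t[-1] - tracking.t[0]) if tracking.t.size > 1 else 0.0
    if total_time <= 0:
        return []
    rate = unit.n_spikes / total_time
    lo, hi = criteria.rate_gate
    if rate < lo or rate > hi:
        return []

    cum = _cumulative_path(tracking)
    trains = []
    if spikes.size == 0:
        return trains

    # maximal runs with ISI <= max_isi
    breaks = np.flatnonzero(np.diff(spikes) > criteria.max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [spikes.size - 1]])

    for s0, s1 in zip(starts, ends):
        run = spikes[s0 : s1 + 1]
        if run.size < criteria.min_spikes:
            continue
        duration = run[-1] - run[0]
        if not (criteria.min_duration <= duration <= criteria.max_duration):
            continue
        # anchors: last tracking sample before first spike / first after last
        i0 = np.searchsorted(tracking.t, run[0], side="right") - 1
        i1 = np.searchsorted(tracking.t, run[-1], side="left")
        if i0 < 0 or i1 >= tracking.t.size or i1 <= i0:
            continue
        path_length = float(cum[i1] - cum[i0])
        if path_length < criteria.min_path_length:
            continue
        start_xy = (float(tracking.x[i0]), float(tracking.y[i0]))
        end_xy = (float(tracking.x[i1]), float(tracking.y[i1]))
        sep = float(np.hypot(end_xy[0] - start_xy[0], end_xy[1] - start_xy[1]))
        if sep < criteria.min_endpoint_separation:
            continue
        span = float(tracking.t[i1] - tracking.t[i0])
        if span <= 0 or path_length / span <= criteria.min_mean_speed:
            continue
        sx, sy = tracking.position_at(run)
        cum_at = np.interp(run, tracking.t, cum)
        d = (cum_at - cum[i0]) / path_length
        d = np.clip(d, 0.0, 1.0)
        trains.append(
            DetectedTrain(
                unit_id=unit.unit_id,
                spike_times=run.copy(),
                spike_phases=phases.phase_at(run) if phases is not None else np.full(run.size, np.nan),
                spike_cycles=phases.cycle_at(run) if phases is not None else np.zeros(run.size, int),
                spike_x=sx,
                spike_y=sy,
                start_xy=start_xy,
                end_xy=end_xy,
                t_start=float(tracking.t[i0]),
                t_end=float(tracking.t[i1]),
                path_length=path_length,
                d=d,
            )
        )
    return trains


def normalized_distance(train: DetectedTrain) -> np.ndarray:
    """Per-spike normalized distance: cumulative path length from the train
    start to the spike, divided by the total path length."""
    if train.path_length <= 0:
        raise ValueError("train has zero path length")
    return train.d


def train_length_spikes(train: DetectedTrain) -> float:
    """Train length L = sum of Euclidean steps between consecutive spike
    positions (the spatial-measures definition)."""
    return float(np.hypot(np.diff(train.spike_x), np.diff(train.spike_y)).sum())


# -------------------------------------------------------------- rate maps


@dataclass
class RateMap:
    """Occupancy-normalized, smoothed firing-rate grid."""

    rates: np.ndarray  # Hz, (ny, nx); NaN where unvisited
    occupancy: np.ndarray  # seconds per bin
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float = 5.0
    smoothing: float = 15.0  # cm, total kernel size (support)

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy > 0

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rates))

    def bin_centers(self):
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )


def rate_map(
    unit: SpikeUnit,
    tracking: TrackingSeries,
    trials,
    bin_size: float = 5.0,
    smoothing: float = 15.0,
    v_min: float = 2.0,
) -> RateMap:
    """Construct the smoothed occupancy-normalized rate map.

    Occupancy counts tracking frames (x 1/frame_rate seconds) in 5 cm bins
    while the animal moves > 2 cm/s inside a trial; spikes outside those
    intervals are excluded. The spike-count / occupancy quotient is smoothed
    with a 2-D Gaussian of total size ``smoothing`` cm (sigma = smoothing/6,
    truncated at 3 sigma).
    """
    mask = movement_mask(tracking, trials, v_min=v_min)
    if not np.any(mask):
        raise ValueError("no occupancy: movement mask is empty")
    tx, ty = tracking.x[mask], tracking.y[mask]

    x_edges = np.arange(tracking.x.min(), tracking.x.max() + bin_size, bin_size)
    y_edges = np.arange(tracking.y.min(), tracking.y.max() + bin_size, bin_size)
    if x_edges.size < 2:
        x_edges = np.array([tracking.x.min(), tracking.x.min() + bin_size])
    if y_edges.size < 2:
        y_edges = np.array([tracking.y.min(), tracking.y.min() + bin_size])

    occ_counts, _, _ = np.histogram2d(ty, tx, bins=[y_edges, x_edges])
    occupancy = occ_counts / tracking.frame_rate

    moving_times = tracking.t[mask]
    # spikes kept only when the nearest tracking sample is a moving, in-trial one
    idx = np.clip(np.searchsorted(tracking.t, unit.spike_times), 0, tracking.t.size - 1)
    keep = mask[idx]
    sx, sy = tracking.position_at(unit.spike_times[keep])
    spk_counts, _, _ = np.histogram2d(sy, sx, bins=[y_edges, x_edges])

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(occupancy > 0, spk_counts / occupancy, 0.0)

    sigma_bins = (smoothing / 6.0) / bin_size
    if sigma_bins > 0:
        # normalized smoothing so unvisited bins do not dilute visited ones
        w = (occupancy > 0).astype(float)
        num = gaussian_filter(raw * w, sigma_bins, truncate=3.0)
        den = gaussian_filter(w, sigma_bins, truncate=3.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(den > 0, num / den, np.nan)
    else:
        rates = raw.copy()
    rates = np.where(occupancy > 0, rates, np.nan)
    if moving_times.size and not np.any(occupancy > 0):
        raise ValueError("zero occupancy everywhere")
    return RateMap(rates, occupancy, x_edges, y_edges, bin_size, smoothing)


@dataclass
class PlaceField:
    """The 20%-of-peak place field: contour polygon and peak."""

    contour: np.ndarray  # (k, 2) polygon vertices in cm (x, y)
    peak_xy: tuple
    peak_rate: float
    n_regions: int = 1  # supra-threshold connected regions found


def extract_place_field(rmap: RateMap, threshold_frac: float = 0.2) -> PlaceField:
    """Place field as the connected region >= 20% of the peak rate.

    Contours come from marching squares on the smoothed map; if several
    disjoint supra-threshold regions exist, the one containing the peak is
    kept and the count is logged. The peak location is refined to sub-bin
    precision by a quadratic fit around the maximal bin.
    """
    rates = np.nan_to_num(rmap.rates, nan=0.0)
    peak = rates.max()
    if peak <= 0:
        raise ValueError("degenerate place field: flat or empty rate map")
    level = threshold_frac * peak
    iy, ix = np.unravel_index(np.argmax(rates), rates.shape)

    xc, yc = rmap.bin_centers()

    def to_cm(rc):
        # marching-squares coords are (row, col) in bin index space
        return np.column_stack(
            [np.interp(rc[:, 1], np.arange(xc.size), xc), np.interp(rc[:, 0], np.arange(yc.size), yc)]
        )

    # pad so fields touching the map edge still close
    padded = np.pad(rates, 1, mode="constant", constant_values=0.0)
    contours = skmeasure.find_contours(padded, level)
    contours = [c - 1.0 for c in contours]
    if not contours:
        raise ValueError("no contour at the 20% level")

    peak_rc = np.array([iy, ix], dtype=float)
    chosen = None
    for c in contours:
        if MplPath(c).contains_point(peak_rc):
            chosen = c
            break
    if chosen is None:
        chosen = min(contours, key=lambda c: np.min(np.hypot(c[:, 0] - iy, c[:, 1] - ix)))
    if len(contours) > 1:
        log.info("extract_place_field: %d supra-threshold regions; kept peak region", len(contours))

    # sub-bin peak via separable quadratic interpolation
    px, py = xc[ix], yc[iy]

    def refine(vals, center, step):
        a, b, c = vals
        denom = a - 2 * b + c
        if denom >= 0 or abs(denom) < 1e-12:
            return center
        return center + 0.5 * step * (a - c) / denom

    if 0 < ix < rates.shape[1] - 1:
        px = refine(rates[iy, ix - 1 : ix + 2], xc[ix], rmap.bin_size)
    if 0 < iy < rates.shape[0] - 1:
        py = refine(rates[iy - 1 : iy + 2, ix], yc[iy], rmap.bin_size)

    return PlaceField(to_cm(chosen), (float(px), float(py)), float(peak), len(contours))


# ------------------------------------------------------ spatial measures


def information_content(rates, occupancy_p, mean_rate: float) -> float:
    """Spatial information H = sum_x lambda(x) log2(lambda(x)/lambda) p(x)
    over occupied bins (bits/s). Bins with zero rate contribute zero."""
    lam = np.asarray(rates, dtype=float).ravel()
    p = np.asarray(occupancy_p, dtype=float).ravel()
    if mean_rate <= 0:
        raise ValueError("information undefined for zero mean rate")
    ok = np.isfinite(lam) & (p > 0) & (lam > 0)
    return float(np.sum(lam[ok] * np.log2(lam[ok] / mean_rate) * p[ok]))


def selectivity(rates, occupancy_p) -> float:
    """S = E[lambda] / E[lambda^2], expectations occupancy-weighted over bins."""
    lam = np.asarray(rates, dtype=float).ravel()
    p = np.asarray(occupancy_p, dtype=float).ravel()
    ok = np.isfinite(lam) & (p > 0)
    e1 = np.average(lam[ok], weights=p[ok])
    e2 = np.average(lam[ok] ** 2, weights=p[ok])
    if e2 <= 0:
        raise ValueError("selectivity undefined for an all-zero map")
    return float(e1 / e2)


def sparsity(rates, mean_rate: float) -> float:
    """s = lambda_max / lambda."""
    if mean_rate <= 0:
        raise ValueError("sparsity undefined for zero mean rate")
    return float(np.nanmax(rates) / mean_rate)


@dataclass
class SpatialMeasures:
    rate: float  # lambda = N / T, Hz
    proportion_in_trains: float  # N_t / N
    spikes_per_train: float  # N / N_tr (as conventionally printed)
    train_length: float  # mean L over trains, cm (spike-position polyline)
    bins_covered: float  # mean 2x2 cm bins covered by train paths
    information: float | None  # bits/s
    selectivity: float | None
    sparsity: float | None


def spatial_measures(
    unit: SpikeUnit, trains, rmap: RateMap, total_time: float, tracking: TrackingSeries = None
) -> SpatialMeasures:
    """All per-cell spatial firing measures; None where undefined (rate 0)."""
    N = unit.n_spikes
    lam = N / total_time if total_time > 0 else 0.0
    Nt = int(sum(tr.n_spikes for tr in trains))
    prop = Nt / N if N > 0 else 0.0
    n_tr = len(trains)
    spt = N / n_tr if n_tr else float("nan")
    tl = float(np.mean([train_length_spikes(tr) for tr in trains])) if trains else float("nan")

    covered = float("nan")
    if trains and tracking is not None:
        counts = []
        for tr in trains:
            sel = (tracking.t >= tr.t_start) & (tracking.t <= tr.t_end)
            bx = np.floor(tracking.x[sel] / 2.0).astype(int)
            by = np.floor(tracking.y[sel] / 2.0).astype(int)
            counts.append(len(set(zip(bx, by))))
        covered = float(np.mean(counts))

    if lam <= 0:
        return SpatialMeasures(lam, prop, spt, tl, covered, None, None, None)
    p = rmap.occupancy / rmap.occupancy.sum()
    H = information_content(np.nan_to_num(rmap.rates, nan=0.0), p, lam)
    S = selectivity(np.nan_to_num(rmap.rates, nan=0.0), p)
    s = sparsity(rmap.rates, lam)
    return SpatialMeasures(lam, prop, spt, tl, covered, H, S, s)
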