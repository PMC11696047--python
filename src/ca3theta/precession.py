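"""Circular-linear regression and all phase-precession measurements.

The central fit is the resultant-length-maximizing circular-linear
regression: given normalized distances ``d`` in [0, 1] and spike phases
``theta`` (deg), the slope ``a`` (deg per traversal) maximizes the mean
resultant length of the residuals ``theta - a d``; the phase offset ``phi0``
is the circular mean of the residuals at the optimum, and significance comes
from the circular-linear correlation between the observed phases and the
fitted ones. A negative slope with p < 0.05 is the operational definition of
phase precession.

The regression is exposed both as a scikit-learn style estimator
(:class:`CircularLinearRegression`) and as the plain function
:func:`circ_lin_regression`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .circstats import circular_mean, circular_median, circular_variance, wrap_degrees

__all__ = [
    "PrecessionMeasures",
    "CircularLinearRegression",
    "circ_lin_regression",
    "slope_by_cell",
    "slope_by_train",
    "OnsetOffset",
    "onset_offset",
    "cell_onset_offset",
    "phase_distribution_thirds",
    "initial_cycle_count",
    "cycle_mean_transform",
    "variance_profile",
]

DEFAULT_SLOPE_BOUNDS = (-720.0, 720.0)


@dataclass
class PrecessionMeasures:
    """Result of one circular-linear regression."""

    slope: float  # deg per normalized traversal
    phi0: float  # deg, [0, 360)
    r_cl: float  # circular-linear correlation
    rsquared: float  # r_cl ** 2 ("explained variance")
    pvalue: float
    n_spikes: int
    resultant: float  # mean resultant length at the fitted slope


def _resultant_profile(d, theta_deg, slopes):
    """Mean resultant length of theta - a*d for every slope in ``slopes``."""
    phase = np.deg2rad(theta_deg)[None, :] - np.deg2rad(slopes)[:, None] * d[None, :]
    z = np.exp(1j * phase).mean(axis=1)
    return np.abs(z)


def _circ_circ_corr(alpha_deg, beta_deg):
    """Jammalamadaka-SenGupta circular-circular correlation and its normal-
    approximation p-value."""
    a = np.deg2rad(alpha_deg)
    b = np.deg2rad(beta_deg)
    sa = np.sin(a - np.angle(np.exp(1j * a).mean()))
    sb = np.sin(b - np.angle(np.exp(1j * b).mean()))
    den = np.sqrt((sa**2).sum() * (sb**2).sum())
    if den <= 0:
        return 0.0, 1.0
    r = float((sa * sb).sum() / den)
    n = a.size
    l20 = (sa**2).mean()
    l02 = (sb**2).mean()
    l22 = ((sa**2) * (sb**2)).mean()
    if l22 <= 0:
        return r, 1.0
    z = r * np.sqrt(n * l20 * l02 / l22)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, min(p, 1.0)


class CircularLinearRegression(BaseEstimator):
    """Circular-linear regression of spike phase on normalized distance.

    Parameters
    ----------
    slope_bounds : (float, float)
        Search interval for the slope, deg per traversal. The default
        covers two full theta cycles of precession in either direction.
    grid_step : float
        Coarse-grid resolution (deg per traversal) for the global search.
    refine : bool
        Polish the grid optimum with a bounded scalar optimization within
        one grid step.

    Attributes (after ``fit``)
    --------------------------
    slope_, phi0_, r_, rsquared_, pvalue_, resultant_, n_
    """

    def __init__(self, slope_bounds=DEFAULT_SLOPE_BOUNDS, grid_step=1.0, refine=True):
        self.slope_bounds = slope_bounds
        self.grid_step = grid_step
        self.refine = refine

    def fit(self, X, y):
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            if d.shape[1] != 1:
                raise ValueError("X must be a single distance feature")
            d = d[:, 0]
        theta = wrap_degrees(np.asarray(y, dtype=float))
        if d.size != theta.size:
            raise ValueError("X and y must have equal length")
        if d.size < 5:
            raise ValueError("circular-linear regression needs n >= 5 spikes")
        if np.ptp(d) == 0:
            raise ValueError("degenerate distances: all d equal")

        lo, hi = self.slope_bounds
        slopes = np.arange(lo, hi + self.grid_step, self.grid_step)
        prof = _resultant_profile(d, theta, slopes)
        best = int(np.argmax(prof))
        a = float(slopes[best])
        if self.refine:
            res = optimize.minimize_scalar(
                lambda s: -_resultant_profile(d, theta, np.array([s]))[0],
                bounds=(max(lo, a - self.grid_step), min(hi, a + self.grid_step)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun >= prof[best]:
                a = float(res.x)

        resid = theta - a * d
        phi0 = circular_mean(resid)
        fitted = wrap_degrees(phi0 + a * d)
        r, p = _circ_circ_corr(theta, fitted)

        self.slope_ = a
        self.phi0_ = phi0
        self.r_ = r
        self.rsquared_ = r**2
        self.pvalue_ = p
        self.resultant_ = float(_resultant_profile(d, theta, np.array([a]))[0])
        self.n_ = int(d.size)
        return self

    def predict(self, X):
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        return wrap_degrees(self.phi0_ + self.slope_ * d)

    def measures_(self) -> PrecessionMeasures:
        return PrecessionMeasures(
            self.slope_, self.phi0_, self.r_, self.rsquared_, self.pvalue_, self.n_, self.resultant_
        )


def circ_lin_regression(d, theta_deg, slope_bounds=DEFAULT_SLOPE_BOUNDS, grid_step=1.0):
    """Fit the circular-linear regression; returns :class:`PrecessionMeasures`."""
    est = CircularLinearRegression(slope_bounds=slope_bounds, grid_step=grid_step)
    est.fit(np.asarray(d, dtype=float), np.asarray(theta_deg, dtype=float))
    return est.measures_()


# --------------------------------------------------- per-cell / per-train


def _pool(trains):
    d = np.concatenate([tr.d for tr in trains]) if trains else np.empty(0)
    th = np.concatenate([tr.spike_phases for tr in trains]) if trains else np.empty(0)
    return d, th


def slope_by_cell(trains, alpha: float = 0.05, slope_bounds=DEFAULT_SLOPE_BOUNDS):
    """Pooled regression over all of a cell's in-train spikes.

    Returns ``(measures, precessing)`` where the flag requires p < alpha AND
    a negative slope; ``(None, False)`` when fewer than 5 pooled spikes.
    """
    d, th = _pool(trains)
    if d.size < 5:
        return None, False
    m = circ_lin_regression(d, th, slope_bounds=slope_bounds)
    return m, bool(m.pvalue < alpha and m.slope < 0)


def slope_by_train(trains, slope_bounds=DEFAULT_SLOPE_BOUNDS):
    """Per-train regressions plus the cell's arithmetic mean train slope.

    Slopes are bounded reals (deg per traversal), so the per-cell average is
    arithmetic, not circular.
    """
    per_train = [
        circ_lin_regression(tr.d, tr.spike_phases, slope_bounds=slope_bounds) for tr in trains
    ]
    mean_slope = float(np.mean([m.slope for m in per_train])) if per_train else float("nan")
    return per_train, mean_slope


# ------------------------------------------------------- onset / offset


@dataclass
class OnsetOffset:
    phi_on: float  # deg
    phi_off: float  # deg


def onset_offset(train) -> OnsetOffset:
    """Circular mean phase of the spikes in the first (possibly truncated)
    theta cycle of the train, and likewise for the last cycle."""
    cyc = np.asarray(train.spike_cycles)
    ph = np.asarray(train.spike_phases)
    first = cyc == cyc.min()
    last = cyc == cyc.max()
    return OnsetOffset(circular_mean(ph[first]), circular_mean(ph[last]))


def cell_onset_offset(trains) -> OnsetOffset:
    """Per-cell statistic: circular median across the cell's trains."""
    oo = [onset_offset(tr) for tr in trains]
    if not oo:
        raise ValueError("cell has no trains")
    return OnsetOffset(
        circular_median([o.phi_on for o in oo]),
        circular_median([o.phi_off for o in oo]),
    )


# ------------------------------------------------- distribution summaries


def phase_distribution_thirds(phases_deg, d=None, n_pos_bins: int = 10):
    """Proportion of spikes in the early/mid/late thirds of the theta cycle.

    Thirds are the half-open intervals [0, 120), [120, 240), [240, 360) deg.
    Returns ``(proportions, mean_phase)``; when ``d`` is supplied, also a
    (n_pos_bins, 3) row-normalized table of third proportions per
    normalized-position bin (NaN rows where a bin is empty).
    """
    ph = wrap_degrees(np.atleast_1d(phases_deg))
    if ph.size == 0:
        raise ValueError("no spikes")
    thirds = np.floor(ph / 120.0).astype(int)
    props = np.array([(thirds == k).mean() for k in range(3)])
    mean_phase = circular_mean(ph)
    if d is None:
        return props, mean_phase
    dd = np.clip(np.asarray(d, dtype=float), 0.0, np.nextafter(1.0, 0.0))
    pos = np.floor(dd * n_pos_bins).astype(int)
    table = np.full((n_pos_bins, 3), np.nan)
    for b in range(n_pos_bins):
        sel = pos == b
        if sel.any():
            table[b] = [(thirds[sel] == k).mean() for k in range(3)]
    return props, mean_phase, table


def initial_cycle_count(train) -> int:
    """Number of spikes within the first 360 deg of unwrapped theta phase
    after (and including) the first spike."""
    u = np.asarray(train.spike_phases) + 360.0 * np.asarray(train.spike_cycles)
    return int(np.count_nonzero(u < u[0] + 360.0))


@dataclass
class CycleMeanTrain:
    """A train collapsed to one representative point per occupied theta cycle."""

    d: np.ndarray
    spike_phases: np.ndarray
    spike_cycles: np.ndarray
    unit_id: str = ""


def cycle_mean_transform(train) -> CycleMeanTrain:
    """Replace each theta cycle's spikes by their circular-mean phase and
    mean normalized distance (the cycle-mean analysis)."""
    cyc = np.asarray(train.spike_cycles)
    ph = np.asarray(train.spike_phases)
    d = np.asarray(train.d)
    out_d, out_ph, out_c = [], [], []
    for c in np.unique(cyc):
        sel = cyc == c
        out_d.append(d[sel].mean())
        out_ph.append(circular_mean(ph[sel]))
        out_c.append(c)
    return CycleMeanTrain(
        np.asarray(out_d), np.asarray(out_ph), np.asarray(out_c), getattr(train, "unit_id", "")
    )


def variance_profile(trains, n_bins: int = 10):
    """Circular variance of pooled spike phases per normalized-distance bin.

    Returns an array of length ``n_bins`` with NaN for empty bins.
    """
    d, th = _pool(trains)
    dd = np.clip(d, 0.0, np.nextafter(1.0, 0.0))
    pos = np.floor(dd * n_bins).astype(int)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = pos == b
        if sel.any():
            out[b] = circular_variance(th[sel])
    return out
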