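"""Circular statistics for theta-phase data.

Descriptive quantities (circular mean, resultant length, variance, von Mises
concentration) and the hypothesis tests used throughout the pipeline: a
circular MANOVA for equality of circular means, a concentration
(dispersion-homogeneity) test, a circular Cohen's d, chi-square tests of
proportions, and Holm-Bonferroni correction.

Angle convention
----------------
All public interfaces take and return angles in **degrees** on ``[0, 360)``.
Radians appear only inside function bodies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wrap_degrees",
    "wrap_difference",
    "circular_mean",
    "resultant_length",
    "circular_variance",
    "circular_std",
    "circular_median",
    "kappa_from_resultant",
    "estimate_kappa",
    "CircularSample",
    "TestResult",
    "circular_manova",
    "concentration_test",
    "circular_effect_size",
    "chi2_proportions",
    "holm_bonferroni",
]


def wrap_degrees(angles):
    """Wrap angles (deg) onto [0, 360)."""
    return np.mod(np.asarray(angles, dtype=float), 360.0)


def wrap_difference(a, b):
    """Smallest signed angular difference a - b in degrees, in (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)[()]


def _rad(angles_deg):
    return np.deg2rad(np.asarray(angles_deg, dtype=float))


def circular_mean(angles_deg, weights=None) -> float:
    """Circular mean direction in degrees on [0, 360)."""
    th = _rad(angles_deg)
    if th.size == 0:
        raise ValueError("circular_mean of an empty sample")
    if weights is None:
        c, s = np.cos(th).mean(), np.sin(th).mean()
    else:
        w = np.asarray(weights, dtype=float)
        c = np.average(np.cos(th), weights=w)
        s = np.average(np.sin(th), weights=w)
    mean = float(np.mod(np.rad2deg(np.arctan2(s, c)), 360.0))
    return 0.0 if mean >= 360.0 else mean  # guard fp wrap of tiny negatives


def resultant_length(angles_deg) -> float:
    """Mean resultant length R-bar in [0, 1]."""
    th = _rad(angles_deg)
    if th.size == 0:
        raise ValueError("resultant_length of an empty sample")
    return float(np.hypot(np.cos(th).mean(), np.sin(th).mean()))


def circular_variance(angles_deg) -> float:
    """Circular variance V = 1 - R-bar, in [0, 1]."""
    return 1.0 - resultant_length(angles_deg)


def circular_std(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R-bar), returned in degrees."""
    r = resultant_length(angles_deg)
    if r <= 0.0:
        return float("inf")
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


def circular_median(angles_deg) -> float:
    """Circular median: the sample direction minimizing the mean arc distance.

    Uses the Fisher definition d(theta, m) = 180 - |180 - |theta - m||, with
    candidate medians restricted to the observed angles (and antipodes broken
    toward the candidate closer to the circular mean).
    """
    a = wrap_degrees(np.atleast_1d(angles_deg))
    if a.size == 0:
        raise ValueError("circular_median of an empty sample")
    if a.size == 1:
        return float(a[0])
    diffs = np.abs(a[:, None] - a[None, :])
    arc = 180.0 - np.abs(180.0 - diffs)
    cost = arc.mean(axis=1)
    best = np.flatnonzero(np.isclose(cost, cost.min()))
    if best.size == 1:
        return float(a[best[0]])
    # tie-break: candidate closest to the circular mean direction
    mu = circular_mean(a)
    dev = np.abs(wrap_difference(a[best], mu))
    return float(a[best[np.argmin(dev)]])


def kappa_from_resultant(rbar: float) -> float:
    """Von Mises concentration from the resultant length (A-inverse approximation).

    Best & Fisher piecewise approximation of A^-1(R-bar).
    """
    r = float(rbar)
    if r < 0.0 or r > 1.0:
        raise ValueError("resultant length must be in [0, 1]")
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    denom = r**3 - 4.0 * r**2 + 3.0 * r
    return 1.0 / denom if denom > 0 else float("inf")


def estimate_kappa(angles_deg) -> float:
    """Maximum-likelihood-style kappa estimate for a circular sample."""
    return kappa_from_resultant(resultant_length(angles_deg))


@dataclass
class CircularSample:
    """A sample of angles (deg) with its circular descriptive statistics."""

    angles: np.ndarray

    def __post_init__(self):
        self.angles = wrap_degrees(np.atleast_1d(self.angles))
        if self.angles.size == 0:
            raise ValueError("CircularSample requires at least one angle")

    @property
    def n(self) -> int:
        return int(self.angles.size)

    @property
    def mean(self) -> float:
        return circular_mean(self.angles)

    @property
    def resultant(self) -> float:
        return resultant_length(self.angles)

    @property
    def variance(self) -> float:
        return 1.0 - self.resultant

    @property
    def kappa(self) -> float:
        return kappa_from_resultant(self.resultant)

    @property
    def median(self) -> float:
        return circular_median(self.angles)


@dataclass
class TestResult:
    statistic: float
    df: object
    pvalue: float
    method: str
    extra: dict = field(default_factory=dict)


def _as_angles(sample):
    if isinstance(sample, CircularSample):
        return sample.angles
    return wrap_degrees(np.atleast_1d(sample))


def circular_manova(groups, statistic: str = "wilks") -> TestResult:
    """Test for a common circular mean across groups via one-factor MANOVA.

    Each angle theta contributes the bivariate observation (cos theta,
    sin theta); group is the single factor. The default Wilks' lambda is
    referred, via the Bartlett correction, to a chi-square distribution with
    p*(g-1) degrees of freedom (2 df for two groups). A Pillai-trace
    alternative is exposed but non-default.
    """
    gs = [_as_angles(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("circular_manova needs at least two groups")
    for g in gs:
        if g.size < 5:
            raise ValueError("each group needs n >= 5")
    th = [_rad(g) for g in gs]
    X = np.concatenate([np.column_stack([np.cos(t), np.sin(t)]) for t in th])
    labels = np.concatenate([np.full(t.size, i) for i, t in enumerate(th)])
    n, p = X.shape
    g = len(gs)
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros((p, p))
    for i in range(g):
        Xi = X[labels == i]
        ci = Xi - Xi.mean(axis=0)
        W += ci.T @ ci
    df = p * (g - 1)
    if statistic == "wilks":
        detW, detT = np.linalg.det(W), np.linalg.det(T)
        if detT <= 0:
            raise ValueError("degenerate total scatter (all angles identical?)")
        lam = max(detW / detT, np.finfo(float).tiny)
        chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam)
    elif statistic == "pillai":
        B = T - W
        V = float(np.trace(B @ np.linalg.inv(T)))
        chi2 = (n - 1 - (p + g) / 2.0) * V
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    chi2 = max(float(chi2), 0.0)
    pval = float(stats.chi2.sf(chi2, df))
    return TestResult(chi2, df, pval, f"circular MANOVA ({statistic}, chi2 approx.)")


def concentration_test(sample1, sample2) -> TestResult:
    """Two-sample test for equal von Mises concentration.

    The Fisher (1993) procedure keyed on the weighted mean resultant length
    r_w: a variance-stabilizing angular transform of each sample's resultant
    with a normal reference for dispersed data (r_w < 0.45 uses
    2 asin(r sqrt(3/8)); 0.45 <= r_w <= 0.70 uses asinh((r - 1.089)/0.258)),
    and a two-sided dispersion-ratio F test for concentrated data
    (r_w > 0.70). The statistic is reported as U in all regimes; it is
    symmetric in the two samples up to sign.
    """
    a1, a2 = _as_angles(sample1), _as_angles(sample2)
    if a1.size < 10 or a2.size < 10:
        raise ValueError("concentration_test needs n >= 10 per sample")
    n1, n2 = a1.size, a2.size
    r1, r2 = resultant_length(a1), resultant_length(a2)
    if r1 < 0.05 and r2 < 0.05:
        warnings.warn(
            "both samples nearly uniform (resultant ~ 0); concentration test unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    rw = (n1 * r1 + n2 * r2) / (n1 + n2)
    if rw < 0.45:
        def g(r):
            return 2.0 * np.arcsin(min(1.0, r * np.sqrt(3.0 / 8.0)))

        se = np.sqrt(0.375 * (1.0 / (n1 - 4) + 1.0 / (n2 - 4)))
        U = (g(r1) - g(r2)) / se
        pval = 2.0 * stats.norm.sf(abs(U))
        df = None
    elif rw <= 0.70:
        def g(r):
            return np.arcsinh((r - 1.089) / 0.258)

        se = 0.893 * np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        U = (g(r1) - g(r2)) / se
        pval = 2.0 * stats.norm.sf(abs(U))
        df = None
    else:
        d1 = (n1 - n1 * r1) / (n1 - 1)
        d2 = (n2 - n2 * r2) / (n2 - 1)
        U = d1 / d2
        pval = 2.0 * min(stats.f.sf(U, n1 - 1, n2 - 1), stats.f.cdf(U, n1 - 1, n2 - 1))
        df = (n1 - 1, n2 - 1)
    return TestResult(float(U), df, float(min(pval, 1.0)), "concentration test (Fisher)")


def circular_effect_size(sample1, sample2) -> float:
    """Circular Cohen's d: wrapped mean difference over pooled circular spread.

    d = (m1 - m2) / s12 with circular means (difference wrapped to
    (-180, 180] degrees) and circular variances in the pooled term
    s12 = sqrt(((n1-1) V1 + (n2-1) V2) / (n1 + n2 - 2)).
    """
    a1, a2 = _as_angles(sample1), _as_angles(sample2)
    if a1.size < 2 or a2.size < 2:
        raise ValueError("circular_effect_size needs n >= 2 per sample")
    m1, m2 = circular_mean(a1), circular_mean(a2)
    v1, v2 = circular_variance(a1), circular_variance(a2)
    n1, n2 = a1.size, a2.size
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    diff = float(wrap_difference(m1, m2))
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled circular variance; effect size infinite", RuntimeWarning, stacklevel=2)
        return float(np.sign(diff)) * float("inf")
    return diff / float(pooled)


def chi2_proportions(successes, totals) -> TestResult:
    """Chi-square test that two or more proportions are equal.

    ``successes[i]`` out of ``totals[i]``; no continuity correction (matching
    the conventional uncorrected chi-square test of proportions).
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(k < 0) or np.any(n <= 0) or np.any(k > n):
        raise ValueError("invalid counts")
    table = np.column_stack([k, n - k])
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; chi-square approximation poor", RuntimeWarning, stacklevel=2)
    if np.allclose(table[:, 0] / n, table[0, 0] / n[0]):
        return TestResult(0.0, table.shape[0] - 1, 1.0, "chi-square proportions")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), int(df), float(p), "chi-square proportions")


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values for a family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, method="holm")
    return adj
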