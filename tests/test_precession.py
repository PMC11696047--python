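"""Circular-linear regression and the phase-precession measurements."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca3theta import precession as pr
from ca3theta.circstats import circular_mean, circular_variance, wrap_difference
from conftest import make_train


def brute_force_slope(d, theta, lo=-720.0, hi=720.0, step=1.0):
    """Independent oracle: dense grid maximization of the resultant length."""
    slopes = np.arange(lo, hi + step, step)
    phase = np.deg2rad(theta)[None, :] - np.deg2rad(slopes)[:, None] * np.asarray(d)[None, :]
    r = np.abs(np.exp(1j * phase).mean(axis=1))
    return float(slopes[np.argmax(r)])


def noisy_instance(rng, n=None):
    n = n if n is not None else rng.integers(8, 60)
    d = np.sort(rng.uniform(0, 1, n))
    slope = rng.uniform(-700, 700)
    kappa = rng.uniform(0.5, 30.0)
    theta = (rng.uniform(0, 360) + slope * d + np.rad2deg(rng.vonmises(0, kappa, n))) % 360
    return d, theta


class TestRegression:
    def test_noiseless_negative_line(self):
        d = np.linspace(0, 1, 40)
        theta = (360.0 - 360.0 * d) % 360.0
        m = pr.circ_lin_regression(d, theta)
        assert m.slope == pytest.approx(-360.0, abs=0.01)
        assert m.rsquared > 0.99
        assert m.pvalue < 0.05

    def test_constant_phase_zero_slope(self):
        d = np.linspace(0, 1, 30)
        m = pr.circ_lin_regression(d, np.full(30, 123.0))
        assert m.slope == pytest.approx(0.0, abs=0.01)
        assert abs(m.r_cl) < 1e-6
        assert m.pvalue > 0.5

    @pytest.mark.parametrize("true_slope", [-360.0, -150.0, 0.0, 90.0])
    def test_noiseless_recovery_exact(self, true_slope):
        rng = np.random.default_rng(int(abs(true_slope)))
        d = np.sort(rng.uniform(0, 1, 25))
        theta = (200.0 + true_slope * d) % 360.0
        m = pr.circ_lin_regression(d, theta)
        assert m.slope == pytest.approx(true_slope, abs=0.01)
        assert abs(wrap_difference(m.phi0, 200.0)) < 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            d, theta = noisy_instance(rng)
            m = pr.circ_lin_regression(d, theta)
            assert abs(m.slope - brute_force_slope(d, theta)) <= 1.0

    @given(st.integers(0, 10_000), st.floats(-360, 360))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_rotation_invariance(self, seed, rot):
        """Global phase rotation leaves the slope fixed and shifts phi0."""
        rng = np.random.default_rng(seed)
        d, theta = noisy_instance(rng, n=30)
        m1 = pr.circ_lin_regression(d, theta)
        m2 = pr.circ_lin_regression(d, (theta + rot) % 360)
        assert m2.slope == pytest.approx(m1.slope, abs=0.5)
        assert abs(wrap_difference(m2.phi0, m1.phi0 + rot)) < 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_reflection_equivariance(self, seed):
        """Reflecting d -> 1 - d negates the slope."""
        rng = np.random.default_rng(seed)
        d, theta = noisy_instance(rng, n=30)
        m1 = pr.circ_lin_regression(d, theta)
        m2 = pr.circ_lin_regression(1.0 - d, theta)
        assert m2.slope == pytest.approx(-m1.slope, abs=0.5)

    def test_degenerate_distances(self):
        with pytest.raises(ValueError):
            pr.circ_lin_regression(np.full(10, 0.5), np.linspace(0, 300, 10))

    def test_sklearn_interface(self):
        est = pr.CircularLinearRegression(grid_step=2.0)
        assert est.get_params()["grid_step"] == 2.0
        d = np.linspace(0, 1, 20)
        est.fit(d.reshape(-1, 1), (100.0 - 200.0 * d) % 360.0)
        pred = est.predict(np.array([[0.0], [0.5]]))
        assert pred[0] == pytest.approx(100.0, abs=1.0)
        assert est.slope_ == pytest.approx(-200.0, abs=0.1)
        cloned = type(est)(**est.get_params())
        assert cloned.get_params() == est.get_params()


class TestSlopeByCellAndTrain:
    def line_train(self, slope, phi0=300.0, n=20, cycles_per_train=8):
        d = np.linspace(0, 1, n)
        theta = (phi0 + slope * d) % 360
        cycles = np.floor(np.linspace(0, cycles_per_train - 1e-9, n)).astype(int)
        return make_train(d, theta, cycles)

    def test_pooled_noiseless_flagged(self):
        trains = [self.line_train(-360.0) for _ in range(3)]
        m, flag = pr.slope_by_cell(trains)
        assert flag
        assert m.slope == pytest.approx(-360.0, abs=0.1)

    def test_positive_slope_not_flagged(self):
        trains = [self.line_train(+200.0) for _ in range(3)]
        m, flag = pr.slope_by_cell(trains)
        assert m.pvalue < 0.05
        assert not flag  # sign gate

    def test_too_few_spikes_null(self):
        m, flag = pr.slope_by_cell([])
        assert m is None and not flag

    def test_train_mean_is_arithmetic(self):
        trains = [self.line_train(-300.0), self.line_train(-100.0)]
        per_train, mean_slope = pr.slope_by_train(trains)
        assert per_train[0].slope == pytest.approx(-300.0, abs=0.1)
        assert mean_slope == pytest.approx(-200.0, abs=0.1)

    def test_identical_trains_mean_equals_single(self):
        tr = self.line_train(-150.0)
        _, mean_slope = pr.slope_by_train([tr, tr])
        assert mean_slope == pytest.approx(-150.0, abs=0.1)


class TestOnsetOffset:
    def test_first_cycle_mean(self):
        tr = make_train([0, 0.1, 0.5, 0.7, 0.9], [240, 240, 100, 80, 60], [0, 0, 1, 2, 3])
        oo = pr.onset_offset(tr)
        assert oo.phi_on == pytest.approx(240.0)
        assert oo.phi_off == pytest.approx(60.0)

    def test_circular_mean_not_arithmetic(self):
        tr = make_train([0, 0.05, 0.9], [350, 10, 100], [0, 0, 5])
        assert pr.onset_offset(tr).phi_on == pytest.approx(0.0, abs=1e-6)

    def test_precessing_train_onset_after_offset(self):
        d = np.linspace(0, 1, 30)
        theta = (300.0 - 250.0 * d) % 360
        cycles = np.arange(30) // 4
        tr = make_train(d, theta, cycles)
        oo = pr.onset_offset(tr)
        # onset in the late half of the cycle, offset in the early half
        assert oo.phi_on > 180.0 > oo.phi_off
        assert oo.phi_on == pytest.approx(300.0 - 250.0 * np.mean(d[:4]), abs=1.0)

    def test_cell_median_across_trains(self):
        trains = [
            make_train([0, 1], [200, 100], [0, 3]),
            make_train([0, 1], [220, 90], [0, 3]),
            make_train([0, 1], [240, 80], [0, 3]),
        ]
        oo = pr.cell_onset_offset(trains)
        assert oo.phi_on == pytest.approx(220.0)
        assert oo.phi_off == pytest.approx(90.0)


class TestDistributions:
    def test_thirds_point_mass(self):
        props, mean = pr.phase_distribution_thirds([10.0, 10.0, 10.0])
        assert props == pytest.approx([1.0, 0.0, 0.0])
        assert mean == pytest.approx(10.0)

    def test_thirds_boundary_half_open(self):
        props, _ = pr.phase_distribution_thirds([120.0])
        assert props == pytest.approx([0.0, 1.0, 0.0])

    def test_thirds_uniform_large_n(self):
        rng = np.random.default_rng(1)
        props, _ = pr.phase_distribution_thirds(rng.uniform(0, 360, 30000))
        assert np.allclose(props, 1.0 / 3.0, atol=0.02)

    def test_position_resolved_table(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 1, 500)
        props, _, table = pr.phase_distribution_thirds(rng.uniform(0, 360, 500), d=d)
        assert table.shape == (10, 3)
        occupied = ~np.isnan(table[:, 0])
        assert np.allclose(table[occupied].sum(axis=1), 1.0)

    def test_initial_cycle_count(self):
        tr = make_train(np.linspace(0, 1, 5), [300, 250, 200, 150, 100], [0, 0, 0, 0, 0])
        assert pr.initial_cycle_count(tr) == 5
        tr2 = make_train(np.linspace(0, 1, 5), [200] * 5, [0, 1, 2, 3, 4])
        assert pr.initial_cycle_count(tr2) == 1

    def test_initial_cycle_poisson_rate(self):
        """Constant-rate spiking at lambda: the window holds the first spike
        plus ~ lambda / f further ones (rate oracle, Monte-Carlo tolerance)."""
        rng = np.random.default_rng(3)
        lam, f, T = 40.0, 8.0, 2.0
        counts = []
        for _ in range(1500):
            t = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
            if t.size == 0:
                continue
            u = 360.0 * f * t
            tr = make_train(t / T, u % 360, np.floor(u / 360).astype(int))
            counts.append(pr.initial_cycle_count(tr))
        assert np.mean(counts) == pytest.approx(1.0 + lam / f, rel=0.05)


class TestCycleMean:
    def test_identity_when_one_spike_per_cycle(self):
        tr = make_train([0.1, 0.3, 0.5], [300, 200, 100], [0, 1, 2])
        out = pr.cycle_mean_transform(tr)
        np.testing.assert_allclose(out.d, tr.d)
        np.testing.assert_allclose(out.spike_phases, tr.spike_phases)

    def test_transform_raises_rsquared_under_jitter(self):
        """Collapsing within-cycle jitter onto cycle means recovers a cleaner
        precession fit (the analytic rescue logic)."""
        rng = np.random.default_rng(4)
        improved = 0
        for _ in range(20):
            n_cyc = 12
            cycles = np.repeat(np.arange(n_cyc), 4)
            d = cycles / n_cyc + rng.uniform(0, 1.0 / n_cyc, cycles.size)
            clean = 300.0 - 250.0 * d
            theta = (clean + rng.uniform(-60, 60, d.size)) % 360
            tr = make_train(d, theta, cycles)
            raw = pr.circ_lin_regression(tr.d, tr.spike_phases)
            out = pr.cycle_mean_transform(tr)
            coll = pr.circ_lin_regression(out.d, out.spike_phases)
            improved += coll.rsquared > raw.rsquared
        assert improved >= 15

    def test_variance_not_increased_by_averaging(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(20):
            cycles = np.repeat(np.arange(10), 5)
            theta = (200.0 + np.rad2deg(rng.vonmises(0, 1.5, cycles.size))) % 360
            tr = make_train(np.linspace(0, 1, cycles.size), theta, cycles)
            out = pr.cycle_mean_transform(tr)
            wins += circular_variance(out.spike_phases) <= circular_variance(tr.spike_phases) + 1e-9
        assert wins >= 18


class TestVarianceProfile:
    def test_noiseless_low_everywhere(self):
        d = np.linspace(0, 1, 200)
        theta = (300.0 - 250.0 * d) % 360
        tr = make_train(d, theta, np.zeros_like(d))
        profile = pr.variance_profile([tr])
        # within a 0.1-wide bin the line spans only 25 degrees
        assert np.nanmax(profile) < 0.05

    def test_first_half_jitter_localized(self):
        rng = np.random.default_rng(6)
        d = np.linspace(0, 1, 2000)
        theta = np.where(d < 0.5, rng.uniform(0, 360, d.size), 200.0)
        tr = make_train(d, theta, np.zeros_like(d))
        profile = pr.variance_profile([tr])
        assert np.nanmin(profile[:5]) > 0.5
        assert np.nanmax(profile[5:]) < 0.05

    def test_uniform_phases_unit_variance(self):
        rng = np.random.default_rng(7)
        tr = make_train(rng.uniform(0, 1, 5000), rng.uniform(0, 360, 5000), np.zeros(5000))
        profile = pr.variance_profile([tr])
        assert np.nanmin(profile) > 0.9

    def test_empty_bin_nan(self):
        tr = make_train([0.05, 0.06, 0.95, 0.96], [10, 20, 200, 210], [0, 0, 5, 5])
        profile = pr.variance_profile([tr])
        assert np.isnan(profile[4])
        assert np.isfinite(profile[0])
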