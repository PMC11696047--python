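"""The oscillatory-interference model: drive equations, Poisson spiking,
lesions, the parameter scan and admissibility matching."""

from dataclasses import replace

import numpy as np
import pytest

from ca3theta import model as M
from ca3theta.circstats import circular_variance


def drive_oracle(p, t, x, i_dc):
    """Independent direct evaluation of the input equations (coded apart
    from the implementation on purpose)."""
    g_dg = p.gamma_dg * (1 + np.cos(2 * np.pi * p.nu_dg * t))
    g_mec = p.gamma_mec * (1 + np.cos(np.deg2rad(p.psi) + 2 * np.pi * p.nu_mec * t))
    g_inh = i_dc + p.A * np.cos(np.deg2rad(p.phi_inh) + 2 * np.pi * p.nu_inh * t)

    def gauss(x, mu, sig):
        return np.exp(-((x - mu) ** 2) / (2 * sig**2)) / (sig * np.sqrt(2 * np.pi))

    m_dg = gauss(x, 0.3, 0.45) ** p.eta_dg
    m_mec = gauss(x, 0.7, 0.75) ** p.eta_mec
    total = m_dg * g_dg + m_mec * g_mec - g_inh / 8.0
    return np.where(total > 0, total, 0.0)


class TestDrive:
    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        p = M.ModelParams(A=2.5, phi_inh=130.0, psi=25.0, i_dc_mean=0.7)
        t = rng.uniform(0, 2, 1000)
        x = rng.uniform(0, 1, 1000)
        np.testing.assert_allclose(
            M.total_drive(p, t, x, i_dc=0.7), drive_oracle(p, t, x, 0.7), rtol=1e-12
        )

    def test_pure_inhibition_rectified_to_zero(self):
        p = M.ModelParams(gamma_dg=0.0, gamma_mec=0.0, A=0.0, i_dc_mean=2.0, i_dc_var=0.0)
        t = np.linspace(0, 2, 500)
        assert np.all(M.total_drive(p, t, t / 2, i_dc=2.0) == 0.0)

    def test_no_inhibition_equals_excitation(self):
        p = M.ModelParams(A=0.0, i_dc_mean=0.0)
        t = np.linspace(0, 2, 500)
        x = t / 2
        g = M.total_drive(p, t, x, i_dc=0.0)
        assert np.all(g >= 0.0)
        p_zero_inh = replace(p, inh_weight=0.0)
        np.testing.assert_allclose(g, M.total_drive(p_zero_inh, t, x, i_dc=0.0))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            M.ModelParams(nu_dg=-1.0).validate()


def constant_drive_params(r_max=15.0, duration=2.0):
    """Negative DC inhibition with zero gains gives a constant drive of 1/8,
    so the normalized intensity is flat at r_max."""
    return M.ModelParams(
        gamma_dg=0.0,
        gamma_mec=0.0,
        A=0.0,
        i_dc_mean=-1.0,
        i_dc_var=0.0,
        r_max=r_max,
        duration=duration,
    )


class TestSpiking:
    def test_constant_drive_poisson_mean(self):
        """Spike counts under flat intensity r over T match Poisson(r T)."""
        p = constant_drive_params(r_max=12.0, duration=2.0)
        rng = np.random.default_rng(1)
        counts = [M.simulate_pass(p, rng).spike_times.size for _ in range(1000)]
        se = np.sqrt(24.0 / 1000)
        assert np.mean(counts) == pytest.approx(24.0, abs=3 * se)

    def test_constant_drive_dispersion_unity(self):
        p = constant_drive_params(r_max=12.0, duration=2.0)
        rng = np.random.default_rng(2)
        counts = np.array([M.simulate_pass(p, rng).spike_times.size for _ in range(1000)])
        dispersion = counts.var() / counts.mean()
        assert dispersion == pytest.approx(1.0, abs=0.15)

    def test_zero_drive_empty_flagged(self):
        p = M.ModelParams(gamma_dg=0.0, gamma_mec=0.0, A=0.0, i_dc_mean=5.0, i_dc_var=0.0)
        out = M.simulate_pass(p, np.random.default_rng(0))
        assert out.empty and out.spike_times.size == 0

    def test_phi_inh_periodicity(self):
        """Shifting phi_inh by 360 deg changes nothing, spike for spike."""
        p1 = M.ModelParams(phi_inh=100.0)
        p2 = M.ModelParams(phi_inh=460.0)
        s1 = M.simulate_pass(p1, np.random.default_rng(3))
        s2 = M.simulate_pass(p2, np.random.default_rng(3))
        np.testing.assert_allclose(s1.spike_times, s2.spike_times)
        np.testing.assert_allclose(s1.spike_phases, s2.spike_phases, atol=1e-9)

    def test_control_parameters_precess(self):
        """The reference control point (A=3, phi=260, I_dc=0, psi=0) yields
        pooled passes with a significant negative slope."""
        p = M.ModelParams()
        hits = 0
        for k in range(20):
            _, m = M.simulate_experiment(p, 15, rng=np.random.default_rng([20, k]))
            hits += m is not None and m.slope < 0 and m.pvalue < 0.05
        assert hits >= 18


class TestMeasurement:
    def test_deterministic_line_measured(self):
        d = np.linspace(0.05, 0.95, 30)
        phases = (300.0 - 360.0 * d) % 360
        sp = M.SimulatedPass(d * 2.0, phases, np.arange(30), d, 0.0)
        m = M.measure_pass(sp)
        assert m.slope == pytest.approx(-360.0, abs=0.1)

    def test_pooling_stabilizes_rsquared(self):
        p = M.ModelParams()
        pooled_r2 = []
        single_r2 = []
        for k in range(15):
            rng = np.random.default_rng([5, k])
            passes = [M.simulate_pass(p, rng) for _ in range(20)]
            live = [q for q in passes if not q.empty]
            pooled = M.measure_pass(live)
            singles = [M.measure_pass(q) for q in live]
            pooled_r2.append(pooled.rsquared)
            single_r2.extend(s.rsquared for s in singles if s is not None)
        assert np.std(pooled_r2) < np.std(single_r2)


class TestLesions:
    def test_dg_lesion_zeroes_gain(self):
        p = M.lesion_instantiate(M.ModelParams(), "dg")
        assert p.gamma_dg == 0.0 and p.gamma_mec == 1.0

    def test_ratio_preserves_total(self):
        p = M.lesion_instantiate(M.ModelParams(), "none", ratio="75/125")
        assert p.gamma_dg == pytest.approx(0.75)
        assert p.gamma_mec == pytest.approx(1.25)
        assert p.gamma_dg + p.gamma_mec == pytest.approx(2.0)

    def test_idempotent(self):
        p1 = M.lesion_instantiate(M.ModelParams(), "mec")
        p2 = M.lesion_instantiate(p1, "mec")
        assert p1 == p2

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            M.lesion_instantiate(M.ModelParams(), "ca1")

    def test_double_lesion_silent(self):
        """Both gains zero and nonnegative inhibition: no spikes. (Requires
        A <= I_dc, else the rectifier passes the negative inhibition swing.)"""
        p = M.lesion_instantiate(
            M.lesion_instantiate(M.ModelParams(A=0.0, i_dc_mean=0.5, i_dc_var=0.0), "dg"), "mec"
        )
        out = M.simulate_pass(p, np.random.default_rng(0))
        assert out.empty


class TestScan:
    def test_reduced_grid_runs_and_layers_finite(self):
        grid = M.scan_parameter_grid(M.ModelParams(), n_A=5, n_phi=8, n_passes=8, seed=3)
        for k in M.MEASUREMENTS:
            assert grid.layers[k].shape == (5, 8)
            assert np.isfinite(grid.layers[k]).mean() > 0.9

    def test_grid_point_reproducible_standalone(self):
        grid = M.scan_parameter_grid(M.ModelParams(), n_A=4, n_phi=6, n_passes=10, seed=11)
        i, j = 2, 4
        p = replace(M.ModelParams(), A=float(grid.A_values[i]), phi_inh=float(grid.phi_values[j]))
        out, _ = M.simulate_experiment(p, 10, rng=M.point_rng(11, i, j))
        assert out["slope"] == grid.layers["slope"][i, j]


class TestAdmissibility:
    def small_grid(self):
        return M.scan_parameter_grid(M.ModelParams(), n_A=4, n_phi=8, n_passes=8, seed=2)

    def wide_bands(self):
        return {
            "slope": (-1e9, 1e9),
            "rsquared": (-1.0, 2.0),
            "phi_on": (0.0, 359.999),
            "phi_off": (0.0, 359.999),
        }

    def test_infinite_bands_accept_everything(self):
        grid = self.small_grid()
        matched = M.admissibility_match(grid, self.wide_bands())
        assert matched.accepted.all()
        assert matched.overlap.max() == 4

    def test_slope_exclusion_empties_accepted_set(self):
        grid = self.small_grid()
        bands = self.wide_bands()
        bands["slope"] = (1e6, 2e6)
        matched = M.admissibility_match(grid, bands)
        assert not matched.admissible["slope"].any()
        assert not matched.accepted.any()
        assert matched.coverage()["slope"] == 0.0

    def test_widening_never_shrinks(self):
        grid = self.small_grid()
        narrow = self.wide_bands()
        narrow["slope"] = (-460.0, -420.0)
        wide = dict(narrow, slope=(-500.0, -380.0))
        acc_narrow = M.admissibility_match(grid, narrow).accepted
        acc_wide = M.admissibility_match(grid, wide).accepted
        assert np.all(acc_wide | ~acc_narrow)  # narrow set is a subset

    def test_single_accepted_point_is_point_mass(self):
        grid = self.small_grid()
        bands = self.wide_bands()
        target = grid.layers["slope"][1, 3]
        bands["slope"] = (target - 1e-6, target + 1e-6)
        dists = M.onset_offset_from_accepted(grid, bands)
        assert dists["phi_on"].size >= 1
        if dists["phi_on"].size == 1:
            assert circular_variance(dists["phi_on"]) == 0.0

    def test_empty_after_widening_raises(self):
        grid = self.small_grid()
        bands = self.wide_bands()
        bands["rsquared"] = (5.0, 6.0)
        with pytest.raises(ValueError, match="empty accepted set"):
            M.onset_offset_from_accepted(grid, bands)

    def test_circular_band_wraps(self):
        band = (350.0, 20.0)  # arc through 0
        inside = M._in_band(np.array([355.0, 10.0, 180.0]), band, circular=True)
        assert inside.tolist() == [True, True, False]

    def test_percentile_band_circular(self):
        rng = np.random.default_rng(8)
        s = (350.0 + np.rad2deg(rng.vonmises(0, 8.0, 400))) % 360
        lo, hi = M.percentile_band(s, 0.8, circular=True)
        width = (hi - lo) % 360
        assert width < 60.0
        inside = M._in_band(s, (lo, hi), circular=True)
        assert inside.mean() == pytest.approx(0.8, abs=0.05)
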