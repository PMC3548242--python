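import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slowmodes.neural_field import (
    ModeBasis,
    NeuralFieldParams,
    PowerSpectrum,
    assert_stable_modes,
    center_frequency,
    center_frequency_curve,
    coupling_gain,
    default_frequency_grid,
    dispersive_propagator,
    firing_rate_sigmoid,
    laplacian_eigenvalues,
    mode_jacobian,
    normalize_spectrum,
    power_spectrum,
    simulate_mode_sde,
)


class TestFiringRateSigmoid:
    @pytest.mark.parametrize(
        "eta, expected",
        [
            (30.0, 0.5),  # at threshold
            (1e4, 1.0),  # saturation
            (0.0, 1.0 / (1.0 + np.exp(0.54 * 30.0))),  # ~9.2e-8 at rest
        ],
    )
    def test_values(self, eta, expected, params):
        assert firing_rate_sigmoid(eta, params) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_strictly_increasing(self, a, b):
        p = NeuralFieldParams()
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert firing_rate_sigmoid(hi, p) > firing_rate_sigmoid(lo, p)

    def test_nonfinite_input_rejected(self, params):
        with pytest.raises(ValueError):
            firing_rate_sigmoid(np.nan, params)


class TestDispersivePropagator:
    def test_causality(self, params):
        assert dispersive_propagator(5.0, -0.001, params) == 0.0
        assert dispersive_propagator(5.0, 0.0, params) == 0.0
        assert dispersive_propagator(5.0, 0.001, params) > 0.0

    def test_negative_distance_rejected(self, params):
        with pytest.raises(ValueError):
            dispersive_propagator(-1.0, 0.01, params)

    def test_total_mass_equals_connection_count(self, params):
        # 2-D quadrature of 2 pi r G(r, t) over r > 0, t > 0
        r = np.linspace(1e-4, 80.0, 1200)
        t = np.linspace(1e-6, 0.05, 1500)
        rr, tt = np.meshgrid(r, t, indexing="ij")
        integrand = 2.0 * np.pi * rr * dispersive_propagator(rr, tt, params)
        mass = np.trapezoid(np.trapezoid(integrand, t, axis=1), r)
        assert mass == pytest.approx(params.g0, rel=5e-3)

    def test_temporal_marginal_decays_at_axonal_rate(self, params):
        r = np.linspace(1e-4, 100.0, 4000)
        t = np.linspace(2e-3, 2e-2, 40)
        marg = np.array(
            [np.trapezoid(2.0 * np.pi * r * dispersive_propagator(r, ti, params), r) for ti in t]
        )
        slope = np.polyfit(t, np.log(marg), 1)[0]
        assert -slope == pytest.approx(params.axonal_rate, rel=0.01)


class TestModeBasis:
    def test_closed_form_eigenvalues(self):
        mb = laplacian_eigenvalues(50.0, 2)
        np.testing.assert_allclose(
            mb.lam, [0.0, -((np.pi / 50.0) ** 2), -((2 * np.pi / 50.0) ** 2)]
        )

    def test_default_cutoff_gives_seventeen_modes(self):
        assert len(ModeBasis().lam) == 17
        assert ModeBasis().lam[0] == 0.0

    def test_invalid_orderings_rejected(self):
        with pytest.raises(ValueError):
            ModeBasis(eigenvalues=(0.0, -1.0, -0.5))
        with pytest.raises(ValueError):
            ModeBasis(domain_length=-1.0)


class TestCouplingGain:
    def test_value_at_threshold(self, params):
        # rho * G0 * (nu/2 sigma) * 1/4
        assert coupling_gain(params.chi, params) == pytest.approx(135000.0)

    def test_vanishes_far_below_threshold(self, params):
        assert coupling_gain(-1e3, params) < 1e-200

    def test_maximal_at_threshold(self, params):
        grid = np.linspace(0.0, 60.0, 601)
        gains = coupling_gain(grid, params)
        assert grid[np.argmax(gains)] == pytest.approx(params.chi)


class TestModeJacobian:
    def test_structure_and_entries(self, params):
        j = mode_jacobian(0.0, params.chi, params)
        assert j[0].tolist() == [0.0, 0.0, 1.0]
        assert j[1, 1] == pytest.approx(-params.axonal_rate)  # -500 1/s
        assert j[2, 0] == pytest.approx(-1.0 / params.tau**2)
        assert j[2, 1] == pytest.approx(params.gamma / params.tau)
        assert j[2, 2] == pytest.approx(-2.0 / params.tau)

    def test_decoupled_limit_eigenvalues(self, params, basis):
        # far below threshold c -> 0 and the matrix is block-triangular
        lam = basis.lam[3]
        j = mode_jacobian(lam, -1e3, params)
        expected = {params.axonal_rate * (params.sigma**2 * lam - 1.0)}
        synaptic = np.linalg.eigvals(j[np.ix_([0, 2], [0, 2])])
        got = np.linalg.eigvals(j)
        for mu in expected:
            assert np.min(np.abs(got - mu)) < 1e-6 * abs(mu)
        for mu in synaptic:
            assert np.min(np.abs(got - mu)) < 1e-6 * max(abs(mu), 1.0)

    def test_fast_modes_stable_over_sweep(self, params, basis):
        for z1 in np.linspace(0.0, 2 * params.chi, 61):
            assert_stable_modes(basis, z1, params)


class TestPowerSpectrum:
    def test_positive_everywhere(self, params, basis, freqs):
        spec = power_spectrum(15.0, freqs, basis, params)
        assert np.all(spec.power > 0)

    def test_low_frequencies_rise_near_threshold(self, params, basis, freqs):
        s0 = normalize_spectrum(power_spectrum(0.0, freqs, basis, params))
        s1 = normalize_spectrum(power_spectrum(params.chi, freqs, basis, params))

        def band_mass(s, lo, hi):
            m = (s.freqs >= lo) & (s.freqs <= hi)
            return np.trapezoid(s.power[m], s.freqs[m])

        assert band_mass(s1, 1, 8) > band_mass(s0, 1, 8)
        assert band_mass(s1, 13, 60) < band_mass(s0, 13, 60)

    def test_bad_grid_rejected(self, params, basis):
        with pytest.raises(ValueError):
            power_spectrum(0.0, np.array([2.0, 1.0]), basis, params)


class TestNormalizeAndCenterFrequency:
    def test_unit_mass_and_idempotence(self, params, basis, freqs):
        s = normalize_spectrum(power_spectrum(10.0, freqs, basis, params))
        assert s.integral() == pytest.approx(1.0, abs=1e-9)
        again = normalize_spectrum(s)
        np.testing.assert_allclose(again.power, s.power, rtol=1e-12)

    def test_uniform_density(self):
        f = np.linspace(1.0, 61.0, 241)
        s = normalize_spectrum(PowerSpectrum(freqs=f, power=np.ones_like(f)))
        np.testing.assert_allclose(s.power, 1.0 / 60.0)
        assert center_frequency(s) == pytest.approx(31.0, rel=1e-9)

    def test_spike_returns_its_frequency(self):
        f = np.arange(1.0, 60.1, 0.25)
        p = np.zeros_like(f)
        p[np.argmin(np.abs(f - 17.0))] = 1.0
        s = normalize_spectrum(PowerSpectrum(freqs=f, power=p))
        assert center_frequency(s) == pytest.approx(17.0, abs=0.25)

    def test_spectrum_export_frame(self, params, basis, freqs):
        df = power_spectrum(5.0, freqs, basis, params).to_frame()
        assert list(df.columns) == ["freq_hz", "power", "normalized_power"]
        assert np.trapezoid(df.normalized_power, df.freq_hz) == pytest.approx(1.0, abs=1e-9)

    def test_unnormalized_input_rejected(self, freqs):
        with pytest.raises(ValueError):
            center_frequency(PowerSpectrum(freqs=freqs, power=np.ones_like(freqs)))

    def test_zero_spectrum_rejected(self, freqs):
        with pytest.raises(ValueError):
            normalize_spectrum(PowerSpectrum(freqs=freqs, power=np.zeros_like(freqs)))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalization_integral_property(self, seed):
        rng = np.random.default_rng(seed)
        f = np.sort(rng.uniform(1.0, 60.0, size=50))
        f = np.unique(f)
        if f.size < 3:
            return
        p = rng.random(f.size) + 1e-3
        s = normalize_spectrum(PowerSpectrum(freqs=f, power=p))
        assert s.integral() == pytest.approx(1.0, abs=1e-9)
        assert f[0] <= center_frequency(s) <= f[-1]


class TestCenterFrequencyCurve:
    def test_monotone_decreasing_to_threshold(self, params, basis, freqs):
        z1 = np.arange(0.0, params.chi + 1e-9, 0.5)
        curve = center_frequency_curve(z1, basis, params, 1.0, freqs)
        assert np.all(np.diff(curve[:, 1]) < 0)

    def test_minimum_at_threshold_when_straddled(self, params, basis, freqs):
        z1 = np.arange(0.0, 2 * params.chi + 1e-9, 1.0)
        curve = center_frequency_curve(z1, basis, params, 1.0, freqs)
        assert curve[np.argmin(curve[:, 1]), 0] == pytest.approx(params.chi)

    def test_singleton_grid(self, params, basis, freqs):
        curve = center_frequency_curve([12.0], basis, params, 1.0, freqs)
        assert curve.shape == (1, 2)


class TestSimulateModeSde:
    def test_deterministic_under_seed(self, params, basis):
        _, s1 = simulate_mode_sde(basis, 10.0, params, duration=0.5, seed=5)
        _, s2 = simulate_mode_sde(basis, 10.0, params, duration=0.5, seed=5)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.z1, b.z1)

    def test_zero_noise_stays_at_rest(self, params, basis):
        _, states = simulate_mode_sde(basis, 10.0, params, noise_sd=0.0, duration=0.2, seed=1)
        for s in states:
            assert np.all(s.z1 == 0.0)

    def test_coarse_dt_rejected(self, params, basis):
        with pytest.raises(ValueError):
            simulate_mode_sde(basis, 0.0, params, dt=1e-3)

    def test_unstable_configuration_rejected(self, params):
        wide = ModeBasis(domain_length=50.0, kc=4)
        with pytest.raises(ValueError, match="unstable"):
            simulate_mode_sde(wide, 30.0, params, duration=0.1, seed=0)
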