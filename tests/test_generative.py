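import numpy as np
import pytest

from slowmodes import _kernels
from slowmodes.generative import (
    BoldSeries,
    ConnectivityParams,
    HemodynamicParams,
    bold_observation,
    hemo_param_array,
    hemodynamic_flow,
    integrate_generative,
    neural_flow,
    obs_const_array,
)


@pytest.fixture(scope="module")
def hp():
    return HemodynamicParams()


class TestNeuralFlow:
    def test_zero_state(self):
        assert np.all(neural_flow(np.zeros(3), -np.eye(3)) == 0.0)

    def test_identity_decay(self):
        np.testing.assert_allclose(neural_flow(np.ones(3), -np.eye(3)), -np.ones(3))

    def test_matches_manual_product(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((3, 3))
        x = rng.standard_normal(3)
        manual = np.array([sum(a[i, j] * x[j] for j in range(3)) for i in range(3)])
        np.testing.assert_allclose(neural_flow(x, a), manual)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            neural_flow(np.ones(2), -np.eye(3))


class TestHemodynamicFlow:
    def test_rest_is_fixed_point(self, hp):
        np.testing.assert_allclose(hemodynamic_flow(np.zeros(4), 0.0, hp), np.zeros(4), atol=1e-15)

    def test_drive_enters_vasodilatory_row_only(self, hp):
        d = hemodynamic_flow(np.zeros(4), 0.7, hp)
        np.testing.assert_allclose(d, [0.7, 0.0, 0.0, 0.0], atol=1e-15)

    def test_overflow_guard(self, hp):
        with pytest.raises((OverflowError, ValueError)):
            hemodynamic_flow(np.array([0.0, 60.0, 0.0, 0.0]), 0.0, hp)

    def test_step_response_peaks_then_undershoots(self, hp):
        # canonical balloon behavior: flow rises during the stimulus and
        # dips below baseline after it ends
        drive = np.zeros((12, 1))
        drive[1:4] = 1.0  # 9 s stimulus
        traj, bold = integrate_generative(
            -np.eye(1), hp, drive=drive, n_scans=12, TR=3.0, dt=0.01, seed=0
        )
        lf = traj.x_h[:, 0, 1]
        assert lf.max() > 0.3
        assert lf[lf.argmax() :].min() < -0.02
        assert bold.y.max() > 1.0 and bold.y.min() < -0.05


class TestBoldObservation:
    def test_zero_at_rest(self, hp):
        assert bold_observation(np.zeros(4), hp) == 0.0

    def test_extravascular_coefficient(self, hp):
        assert hp.k1 == pytest.approx(4.3 * 40.3 * 0.34 * 0.04, rel=1e-12)
        assert hp.k1 == pytest.approx(2.356, abs=1e-3)

    def test_unit_intravascular_ratio_drops_volume_term(self, hp):
        # with epsilon0 = 1 the (1 - eps0)(1 - e^{lv}) term contributes 0
        x = np.array([0.0, 0.0, 0.7, 0.0])
        expected = hp.V0 * (hp.k2 * (1.0 - np.exp(-0.7)))
        assert bold_observation(x, hp) == pytest.approx(expected, rel=1e-12)

    def test_scaled_zero_log_scaling_identity(self, hp):
        assert hp.scaled(np.zeros(6)) == hp


class TestKernelsAgainstReference:
    """The numba kernels must agree with the pure-Python flows."""

    def test_hemo_flow(self, hp):
        rng = np.random.default_rng(7)
        packed = hemo_param_array([hp])
        for _ in range(25):
            xh = rng.uniform(-1.5, 1.5, size=4)
            xn = rng.uniform(-1, 1)
            np.testing.assert_allclose(
                _kernels.hemo_flow(xh, xn, packed[0]),
                hemodynamic_flow(xh, xn, hp),
                rtol=1e-12,
            )

    def test_observe(self, hp):
        rng = np.random.default_rng(8)
        oc = obs_const_array([hp] * 2)
        z = np.concatenate([rng.uniform(-1, 1, 2), rng.uniform(-0.5, 0.5, 8)])
        got = _kernels.observe(z, oc)
        for r in range(2):
            assert got[r] == pytest.approx(bold_observation(z[2 + 4 * r : 6 + 4 * r], hp))

    def test_jacobian_matches_numeric_differences(self, hp):
        rng = np.random.default_rng(9)
        a = np.array([[-1.0, 0.3], [0.2, -0.8]])
        packed = hemo_param_array([hp] * 2)
        z = np.concatenate([rng.uniform(-0.5, 0.5, 2), rng.uniform(-0.3, 0.3, 8)])
        jac = _kernels.full_jac(z, a, packed)
        u = np.zeros(2)
        eps = 1e-6
        for j in range(10):
            zp = z.copy()
            zp[j] += eps
            zm = z.copy()
            zm[j] -= eps
            col = (_kernels.full_flow(zp, a, packed, u) - _kernels.full_flow(zm, a, packed, u)) / (2 * eps)
            np.testing.assert_allclose(jac[:, j], col, atol=1e-5, rtol=1e-5)

    def test_observation_jacobian(self, hp):
        rng = np.random.default_rng(10)
        oc = obs_const_array([hp])
        z = np.concatenate([[0.1], rng.uniform(-0.3, 0.3, 4)])
        h = _kernels.observe_jac(z, oc)
        eps = 1e-6
        for j in range(5):
            zp = z.copy()
            zp[j] += eps
            zm = z.copy()
            zm[j] -= eps
            col = (_kernels.observe(zp, oc) - _kernels.observe(zm, oc)) / (2 * eps)
            np.testing.assert_allclose(h[:, j], col, atol=1e-6)


class TestIntegrateGenerative:
    def test_rest_stays_at_rest(self):
        _, bold = integrate_generative(
            -np.eye(3), HemodynamicParams(), state_noise_sd=0.0, n_scans=700, TR=3.0, dt=0.05, seed=0
        )
        assert np.max(np.abs(bold.y)) < 1e-12

    def test_seed_reproducibility(self):
        kw = dict(state_noise_sd=0.1, n_scans=50, TR=3.0, dt=0.01, seed=4)
        _, b1 = integrate_generative(-np.eye(2), HemodynamicParams(), **kw)
        _, b2 = integrate_generative(-np.eye(2), HemodynamicParams(), **kw)
        np.testing.assert_array_equal(b1.y, b2.y)

    def test_neural_superposition(self):
        # with noise off the neural stage is linear: response to summed
        # drives equals the sum of responses
        a = np.array([[-1.0, 0.2], [0.1, -1.0]])
        d1 = np.zeros((60, 2))
        d1[10:20, 0] = 1.0
        d2 = np.zeros((60, 2))
        d2[30:44, 1] = 0.5
        kw = dict(n_scans=60, TR=3.0, dt=0.01)
        t1, _ = integrate_generative(a, HemodynamicParams(), drive=d1, **kw)
        t2, _ = integrate_generative(a, HemodynamicParams(), drive=d2, **kw)
        t12, _ = integrate_generative(a, HemodynamicParams(), drive=d1 + d2, **kw)
        np.testing.assert_allclose(t12.x_n, t1.x_n + t2.x_n, atol=1e-8)

    def test_integrator_convergence_under_dt_halving(self):
        a = -np.eye(2)
        drive = np.zeros((40, 2))
        drive[5:10] = 1.0
        _, coarse = integrate_generative(a, HemodynamicParams(), drive=drive, n_scans=40, TR=3.0, dt=0.02)
        _, fine = integrate_generative(a, HemodynamicParams(), drive=drive, n_scans=40, TR=3.0, dt=0.01)
        rel = np.linalg.norm(coarse.y - fine.y) / np.linalg.norm(fine.y)
        assert rel < 1e-3

    def test_default_acquisition_geometry(self):
        _, bold = integrate_generative(
            -np.eye(3), HemodynamicParams(), state_noise_sd=0.05, n_scans=700, TR=3.0, dt=0.05, seed=1
        )
        assert bold.y.shape == (700, 3)
        assert bold.TR == 3.0

    def test_divergence_reports_error(self):
        unstable = np.array([[0.5]])
        with pytest.raises(RuntimeError, match="diverged"), pytest.warns(UserWarning):
            integrate_generative(unstable, HemodynamicParams(), drive=np.ones((200, 1)), n_scans=200, TR=3.0, dt=0.05)

    def test_bold_series_validation(self):
        with pytest.raises(ValueError):
            BoldSeries(times=np.arange(3.0), y=np.full((3, 1), np.nan), TR=1.0)

    def test_connectivity_validation(self):
        with pytest.raises(ValueError):
            ConnectivityParams(A=np.ones((2, 3)))
        with pytest.warns(UserWarning):
            ConnectivityParams(A=np.array([[1.0]]))
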