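import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from serialbump import (
    NetworkParams,
    PlasticityParams,
    build_connectivity,
    initial_state,
    ou_stationary_sd,
    preferred_angles,
    recurrent_current,
    step_gating,
    step_noise,
    step_plasticity,
    transfer_rate,
)
from serialbump.circular import wrap_deg

PARAMS = NetworkParams()


class TestParams:
    def test_defaults_validate(self):
        NetworkParams()
        PlasticityParams()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_neurons=1),
            dict(tau_s=0.0),
            dict(tau_n=-1.0),
            dict(dt=0.0),
            dict(sigma_conn=0.0),
            dict(J_plus=-0.1),
            dict(J_minus=0.1),
        ],
    )
    def test_invalid_network_params(self, kwargs):
        with pytest.raises(ValueError):
            NetworkParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(x_ceiling=1.0),
            dict(y_base=0.0),
            dict(y_base=0.999, x_ceiling=0.008),
            dict(tau_F=0.0),
            dict(tau_D=-1.0),
        ],
    )
    def test_invalid_plasticity_params(self, kwargs):
        with pytest.raises(ValueError):
            PlasticityParams(**kwargs)

    def test_with_returns_modified_copy(self):
        p = PARAMS.with_(sigma_n=0.0)
        assert p.sigma_n == 0.0
        assert PARAMS.sigma_n == 0.009


class TestTransferRate:
    def test_removable_singularity_value(self):
        # a*I - b = 0 at I = b/a = 0.4 nA; the limit is 1/d
        assert transfer_rate(0.4, PARAMS) == pytest.approx(1.0 / 0.154, rel=1e-12)

    def test_continuity_at_singularity(self):
        eps = 1e-9
        left = transfer_rate(0.4 - eps, PARAMS)
        right = transfer_rate(0.4 + eps, PARAMS)
        assert left == pytest.approx(1.0 / 0.154, rel=1e-5)
        assert right == pytest.approx(1.0 / 0.154, rel=1e-5)

    def test_driven_value(self):
        # at I = 1 nA, a*I - b = 162 and the exponential correction is tiny
        assert transfer_rate(1.0, PARAMS) == pytest.approx(162.0, abs=1e-6)

    def test_deep_below_threshold_is_zero(self):
        assert transfer_rate(-100.0, PARAMS) == 0.0

    def test_monotonic_nonnegative(self):
        I = np.linspace(-2.0, 2.0, 2001)
        f = transfer_rate(I, PARAMS)
        assert np.all(f >= 0.0)
        assert np.all(np.diff(f) > 0.0) or np.all(np.diff(f) >= 0.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            transfer_rate(np.nan, PARAMS)
        with pytest.raises(ValueError):
            transfer_rate(np.array([0.1, np.inf]), PARAMS)

    def test_scalar_in_scalar_out(self):
        assert isinstance(transfer_rate(0.5, PARAMS), float)

    @given(st.floats(min_value=-5.0, max_value=5.0, allow_nan=False))
    def test_matches_formula_away_from_singularity(self, I):
        x = PARAMS.gain_a * I - PARAMS.thresh_b
        if abs(x) < 1e-6:
            return
        expected = x / (1.0 - np.exp(-PARAMS.curv_d * x))
        if not np.isfinite(expected):
            expected = 0.0
        assert transfer_rate(I, PARAMS) == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestConnectivity:
    def test_against_brute_force(self, net64):
        conn = build_connectivity(net64)
        theta = preferred_angles(net64.n_neurons)
        n = net64.n_neurons
        expected = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                d = wrap_deg(theta[i] - theta[j])
                expected[i, j] = (
                    net64.J_minus
                    + net64.J_plus * np.exp(-(d**2) / (2.0 * net64.sigma_conn**2))
                ) / n
        np.testing.assert_allclose(conn.weights, expected, rtol=1e-12)

    def test_symmetric(self, net64):
        w = build_connectivity(net64).weights
        np.testing.assert_allclose(w, w.T, rtol=1e-12)

    def test_circulant(self, net64):
        w = build_connectivity(net64).weights
        for i in range(1, net64.n_neurons):
            np.testing.assert_allclose(w[i], np.roll(w[0], i), rtol=1e-12)

    def test_self_coupling_is_peak(self, net64):
        w = build_connectivity(net64).weights
        assert w[0, 0] == pytest.approx(
            (net64.J_minus + net64.J_plus) / net64.n_neurons
        )
        assert np.argmax(w[0]) == 0

    def test_far_coupling_inhibitory(self, net64):
        w = build_connectivity(net64).weights
        opposite = net64.n_neurons // 2
        assert w[0, opposite] < 0.0

    def test_recurrent_current_matches_matmul(self, net64, rng):
        conn = build_connectivity(net64)
        s = rng.uniform(0.0, 1.0, size=net64.n_neurons)
        np.testing.assert_allclose(
            recurrent_current(s, conn), conn.weights @ s, rtol=1e-12
        )

    def test_recurrent_current_batched(self, net64, rng):
        conn = build_connectivity(net64)
        s = rng.uniform(0.0, 1.0, size=(3, net64.n_neurons))
        out = recurrent_current(s, conn)
        assert out.shape == s.shape
        np.testing.assert_allclose(out[1], conn.weights @ s[1], rtol=1e-12)

    def test_dimension_mismatch_raises(self, net64):
        conn = build_connectivity(net64)
        with pytest.raises(ValueError):
            recurrent_current(np.zeros(12), conn)


class TestGating:
    def test_fixed_point_constant_rate(self):
        # ds/dt = 0 at s* = gamma*f*tau_s / (1 + gamma*f*tau_s)
        f = 40.0
        tau = PARAMS.tau_s * 1e-3
        s_star = PARAMS.gamma * f * tau / (1.0 + PARAMS.gamma * f * tau)
        s = np.array([0.0])
        for _ in range(40000):
            s = step_gating(s, np.array([f]), PARAMS, PARAMS.dt)
        assert s[0] == pytest.approx(s_star, rel=1e-6)

    def test_stays_in_unit_interval(self):
        s = np.array([0.0])
        for _ in range(10000):
            s = step_gating(s, np.array([500.0]), PARAMS, PARAMS.dt)
            assert 0.0 <= s[0] <= 1.0

    def test_plastic_drive_reduces_opening(self):
        s0 = np.array([0.2])
        rates = np.array([40.0])
        plain = step_gating(s0, rates, PARAMS, PARAMS.dt)
        plast = PlasticityParams()  # y_base < 1, F = 0, D = 1
        gated = step_gating(
            s0, rates, PARAMS, PARAMS.dt, plast, np.zeros(1), np.ones(1)
        )
        assert gated[0] < plain[0]

    def test_degenerate_plasticity_matches_plain(self):
        plast = PlasticityParams(
            alpha=0.0, x_ceiling=0.0, p_release=0.0, y_base=1.0
        )
        s0 = np.array([0.3])
        rates = np.array([25.0])
        a = step_gating(s0, rates, PARAMS, PARAMS.dt)
        b = step_gating(s0, rates, PARAMS, PARAMS.dt, plast, np.zeros(1), np.ones(1))
        assert a[0] == b[0]


class TestPlasticity:
    def test_fixed_points_match_closed_form(self):
        plast = PlasticityParams()
        f = 40.0
        # dF/dt = 0: F* = alpha*x*f / (alpha*f + 1/tau_F)
        F_star = plast.alpha * plast.x_ceiling * f / (
            plast.alpha * f + 1.0 / plast.tau_F
        )
        # dD/dt = 0: D* = 1 / (1 + p*f*F*tau_D)
        D_star = 1.0 / (1.0 + plast.p_release * f * F_star * plast.tau_D)
        F, D = np.zeros(1), np.ones(1)
        rates = np.array([f])
        for _ in range(120000):  # 60 s at dt = 0.5 ms
            F, D = step_plasticity(F, D, rates, plast, 0.5)
        assert F[0] == pytest.approx(F_star, abs=1e-6)
        assert D[0] == pytest.approx(D_star, abs=1e-6)

    def test_silence_decays_to_baseline(self):
        plast = PlasticityParams()
        F, D = np.array([0.005]), np.array([0.95])
        rates = np.zeros(1)
        for _ in range(100000):  # 50 s, about 12 augmentation time constants
            F, D = step_plasticity(F, D, rates, plast, 0.5)
        assert F[0] == pytest.approx(0.0, abs=1e-7)
        assert D[0] == pytest.approx(1.0, abs=1e-7)

    def test_F_bounded_by_ceiling(self):
        plast = PlasticityParams()
        F, D = np.zeros(1), np.ones(1)
        rates = np.array([500.0])
        for _ in range(50000):
            F, D = step_plasticity(F, D, rates, plast, 0.5)
            assert F[0] <= plast.x_ceiling + 1e-12
            assert 0.0 <= D[0] <= 1.0

    def test_disabled_raises(self):
        plast = PlasticityParams(enabled=False)
        with pytest.raises(ValueError):
            step_plasticity(np.zeros(1), np.ones(1), np.zeros(1), plast, 0.5)


class TestNoise:
    def test_zero_sigma_relaxes_to_mean(self):
        p = PARAMS.with_(sigma_n=0.0)
        I = np.array([p.I0 + 0.05])
        z = np.zeros(1)
        # one exact-update step of dt = tau_n decays the deviation by 1/e
        out = step_noise(I, p, p.tau_n, z)
        assert out[0] - p.I0 == pytest.approx(0.05 * np.exp(-1.0), rel=1e-12)
        for _ in range(100):
            I = step_noise(I, p, p.dt, z)
        assert I[0] == pytest.approx(p.I0, abs=1e-9)

    def test_stationary_mean_and_sd(self, rng):
        n_steps, n_par = 20000, 64
        I = np.full(n_par, PARAMS.I0)
        samples = np.empty((n_steps, n_par))
        for k in range(n_steps):
            I = step_noise(I, PARAMS, PARAMS.dt, rng.standard_normal(n_par))
            samples[k] = I
        stat = samples[2000:]
        sd_target = ou_stationary_sd(PARAMS)
        n_eff = stat.size * (1 - np.exp(-PARAMS.dt / PARAMS.tau_n)) / 2
        se_mean = sd_target / np.sqrt(n_eff)
        assert abs(stat.mean() - PARAMS.I0) < 3 * se_mean
        assert stat.std() == pytest.approx(sd_target, rel=0.05)

    def test_stationary_sd_value(self):
        assert ou_stationary_sd(PARAMS) == pytest.approx(0.009 / np.sqrt(2.0))

    def test_same_seed_same_trajectory(self):
        out = []
        for _ in range(2):
            g = np.random.default_rng(123)
            I = np.full(8, PARAMS.I0)
            for _ in range(100):
                I = step_noise(I, PARAMS, PARAMS.dt, g.standard_normal(8))
            out.append(I.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_autocorrelation_time(self, rng):
        # lag-k autocorrelation of the exact update is exp(-k*dt/tau_n)
        n_steps = 200000
        I = np.array([PARAMS.I0])
        xs = np.empty(n_steps)
        for k in range(n_steps):
            I = step_noise(I, PARAMS, PARAMS.dt, rng.standard_normal(1))
            xs[k] = I[0]
        x = xs[1000:] - xs[1000:].mean()
        lag = 4  # 2 ms = tau_n
        rho = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
        assert rho == pytest.approx(np.exp(-1.0), abs=0.02)


class TestInitialState:
    def test_single(self, net64):
        st0 = initial_state(net64)
        assert st0.s.shape == (64,)
        assert np.all(st0.s == 0.0)
        assert np.all(st0.F == 0.0)
        assert np.all(st0.D == 1.0)
        assert np.all(st0.I_noise == net64.I0)
        assert st0.t_ms == 0.0

    def test_batched(self, net64):
        st0 = initial_state(net64, batch=5)
        assert st0.s.shape == (5, 64)
        assert st0.preferred_angles.shape == (64,)

    def test_preferred_angles_tile_circle(self):
        th = preferred_angles(256)
        assert th[0] == 0.0
        assert th[-1] == pytest.approx(360.0 - 360.0 / 256)
        np.testing.assert_allclose(np.diff(th), 360.0 / 256)
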