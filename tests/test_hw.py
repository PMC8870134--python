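"""Hammerstein-Wiener structure, simulation, RLS and identification."""

import numpy as np
import pytest

from emgforce.evaluation import r_squared
from emgforce.hw import (
    HWConfig,
    HWModel,
    LinearBlock,
    StaticNonlinearity,
    build_regressor,
    identify_hw,
    prediction_error,
    rls_init,
    rls_update,
    simulate_hw,
    _rls_pass,
    _rls_pass_numpy,
)
from emgforce.signals import SignalTrace


def poly(*coeffs):
    return StaticNonlinearity(family="polynomial", coefficients=list(coeffs))


def ident():
    return StaticNonlinearity.identity()


def random_stable_model(rng):
    """Random small H-W model with polynomial blocks and a stable 2nd-order
    linear block (poles drawn inside the unit circle)."""
    r1, r2 = rng.uniform(-0.9, 0.9, 2)
    f = [-(r1 + r2), r1 * r2]
    b = rng.uniform(-1, 1, 2)
    nk = int(rng.integers(0, 3))
    return HWModel(
        input_nl=poly(0.0, rng.uniform(0.5, 1.5), rng.uniform(-0.3, 0.3)),
        linear=LinearBlock(b=b, f=f, nk=nk),
        output_nl=poly(rng.uniform(-0.2, 0.2), rng.uniform(0.5, 1.5),
                       rng.uniform(-0.2, 0.2)),
    )


def oracle_simulate(model, u):
    """Independent sample-by-sample recursion (no scipy filtering)."""
    def ev(nl, x):
        if nl.family == "identity":
            return x
        return sum(c * x**p for p, c in enumerate(nl.coefficients))

    b, f, nk = model.linear.b, model.linear.f, model.linear.nk
    v = [ev(model.input_nl, ui) for ui in u]
    x = []
    for k in range(len(u)):
        acc = 0.0
        for j, bj in enumerate(b):
            idx = k - nk - j
            if idx >= 0:
                acc += bj * v[idx]
        for m, fm in enumerate(f, start=1):
            if k - m >= 0:
                acc -= fm * x[k - m]
        x.append(acc)
    return np.array([ev(model.output_nl, xi) for xi in x])


class TestSimulate:
    def test_identity_chain_is_identity(self, rng):
        m = HWModel(ident(), LinearBlock(b=[1.0], f=[], nk=0), ident())
        u = rng.standard_normal(50)
        assert np.array_equal(simulate_hw(m, u), u)

    def test_static_squaring(self):
        m = HWModel(poly(0, 0, 1), LinearBlock(b=[1.0], f=[], nk=0), ident())
        assert np.array_equal(simulate_hw(m, np.array([1.0, 2, 3])), [1, 4, 9])

    def test_matches_independent_recursion(self, rng):
        for _ in range(10):
            m = random_stable_model(rng)
            u = rng.standard_normal(300)
            y = simulate_hw(m, u)
            assert np.max(np.abs(y - oracle_simulate(m, u))) < 1e-10

    def test_unstable_block_warns(self, rng):
        m = HWModel(ident(), LinearBlock(b=[1.0], f=[-2.0], nk=0), ident())
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                simulate_hw(m, np.ones(2000))


class TestRegressor:
    def test_minimal_orders(self):
        u = np.array([1.0, 2, 3, 4])
        assert np.array_equal(build_regressor(u, u, 2, (1, 0, 0)), [3.0])

    def test_hand_worked_example(self):
        u = np.array([1.0, 2, 3, 4])
        y = np.array([0.0, 1, 2, 3])
        phi = build_regressor(u, y, 3, (2, 1, 1))
        assert np.array_equal(phi, [3.0, 2.0, -2.0])

    @pytest.mark.parametrize("orders", [(1, 0, 0), (2, 1, 1), (3, 2, 0), (1, 3, 2)])
    def test_length_is_nb_plus_nf(self, rng, orders):
        u = rng.standard_normal(20)
        y = rng.standard_normal(20)
        nb, nf, nk = orders
        k0 = max(nb - 1 + nk, nf)
        assert build_regressor(u, y, k0, orders).size == nb + nf

    def test_below_warmup_rejected(self):
        with pytest.raises(ValueError):
            build_regressor(np.ones(10), np.ones(10), 0, (2, 1, 1))


class TestRLS:
    def test_init(self):
        s = rls_init(3, 1e4)
        assert np.array_equal(s.theta_hat, np.zeros(3))
        assert np.array_equal(s.P, 1e4 * np.eye(3))
        assert s.k == 0

    def test_zero_regressor_leaves_state_unchanged(self):
        s = rls_init(2, 100.0)
        s2 = rls_update(s, np.zeros(2), 5.0)
        assert np.array_equal(s2.theta_hat, s.theta_hat)
        assert np.array_equal(s2.P, s.P)

    def test_scalar_noise_free_convergence(self):
        s = rls_init(1, 1e6)
        for u in range(1, 201):
            s = rls_update(s, np.array([float(u)]), 2.0 * u)
        assert abs(s.theta_hat[0] - 2.0) < 1e-6

    def test_matches_batch_regularised_least_squares(self, rng):
        n, p, p0 = 200, 5, 1e4
        Phi = rng.standard_normal((n, p))
        theta_true = rng.standard_normal(p)
        y = Phi @ theta_true + 0.1 * rng.standard_normal(n)
        s = rls_init(p, p0)
        for k in range(n):
            s = rls_update(s, Phi[k], y[k])
        batch = np.linalg.solve(Phi.T @ Phi + np.eye(p) / p0, Phi.T @ y)
        assert np.max(np.abs(s.theta_hat - batch)) < 1e-8

    def test_P_stays_symmetric_positive_definite(self, rng):
        s = rls_init(4, 1e3)
        for _ in range(10_000):
            s = rls_update(s, rng.standard_normal(4), rng.standard_normal())
        assert np.array_equal(s.P, s.P.T)
        assert np.min(np.linalg.eigvalsh(s.P)) > 0

    def test_fast_pass_matches_reference_loop(self, rng):
        v = rng.standard_normal(2000)
        z = rng.standard_normal(2000)
        t1, tr1 = _rls_pass(v, z, 2, 2, 1, 1e4)
        t2, tr2 = _rls_pass_numpy(v, z, 2, 2, 1, 1e4)
        assert np.max(np.abs(tr1 - tr2)) < 1e-8


class TestIdentify:
    @pytest.fixture
    def generator(self):
        return HWModel(
            input_nl=poly(0.0, 0.3, 0.7),
            linear=LinearBlock(b=[0.6, 0.3], f=[-0.5, 0.06], nk=1),
            output_nl=ident(),
        )

    def test_noise_free_recovery(self, generator, smooth_input, rng):
        y = simulate_hw(generator, smooth_input.samples)
        m = identify_hw(smooth_input,
                        SignalTrace(y, fs=100.0, kind="normalised"))
        u2 = SignalTrace(
            np.clip(np.convolve(rng.uniform(0, 1, 800), np.ones(20) / 20,
                                mode="same"), 0, 1),
            fs=100.0, kind="normalised")
        yh = simulate_hw(generator, u2.samples)
        ysim = simulate_hw(m, u2.samples)
        k0 = m.warmup
        assert r_squared(yh[k0:], ysim[k0:]) >= 0.99

    def test_recovery_under_output_noise(self, generator, smooth_input, rng):
        y = simulate_hw(generator, smooth_input.samples)
        yn = y + 0.05 * np.std(y) * rng.standard_normal(y.size)
        m = identify_hw(smooth_input, SignalTrace(yn, fs=100.0, kind="normalised"))
        ysim = simulate_hw(m, smooth_input.samples)
        k0 = m.warmup
        assert r_squared(y[k0:], ysim[k0:]) >= 0.95

    def test_linear_system_recovery(self, rng):
        true = HWModel(ident(), LinearBlock(b=[0.5, 0.25], f=[-0.4, 0.1], nk=1),
                       ident())
        u = rng.standard_normal(3000)
        y = simulate_hw(true, u)
        m = identify_hw(SignalTrace(u, fs=100.0, kind="normalised"),
                        SignalTrace(y, fs=100.0, kind="normalised"),
                        HWConfig(input_family="identity", output_family="identity"))
        assert np.max(np.abs(m.linear.b - true.linear.b)) < 1e-3
        assert np.max(np.abs(m.linear.f - true.linear.f)) < 1e-3

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            identify_hw(SignalTrace(np.ones(500), fs=100.0, kind="normalised"),
                        SignalTrace(np.ones(500), fs=100.0, kind="normalised"))

    def test_short_record_rejected(self, rng):
        with pytest.raises(ValueError):
            identify_hw(SignalTrace(rng.uniform(0, 1, 20), fs=100.0),
                        SignalTrace(rng.uniform(0, 1, 20), fs=100.0))


class TestPredictionError:
    def test_zero_on_own_generator_data(self, rng):
        m = random_stable_model(rng)
        u = SignalTrace(rng.standard_normal(500), fs=100.0, kind="normalised")
        y = simulate_hw(m, u)
        eps = prediction_error(m, u, y)
        assert np.max(np.abs(eps.samples)) < 1e-8

    def test_constant_shift_appears_in_mean(self, rng):
        m = random_stable_model(rng)
        u = SignalTrace(rng.standard_normal(500), fs=100.0, kind="normalised")
        y = simulate_hw(m, u)
        y_shift = y.with_samples(y.samples + 1.5)
        eps = prediction_error(m, u, y_shift)
        assert np.mean(eps.samples) == pytest.approx(1.5, abs=1e-9)

    def test_identified_model_beats_zero_predictor(self, smooth_input, rng):
        gen = HWModel(poly(0.0, 1.0, 0.3),
                      LinearBlock(b=[0.7], f=[-0.3], nk=1), ident())
        y = simulate_hw(gen, smooth_input.samples)
        yn = SignalTrace(y + 0.02 * rng.standard_normal(y.size), fs=100.0,
                         kind="normalised")
        m = identify_hw(smooth_input, yn)
        eps = prediction_error(m, smooth_input, yn)
        rms_model = np.sqrt(np.mean(eps.samples**2))
        rms_zero = np.sqrt(np.mean(yn.samples[m.warmup:] ** 2))
        assert rms_model <= rms_zero


class TestThetaAndSerialisation:
    def test_theta_pack_unpack_round_trip(self, rng):
        m = random_stable_model(rng)
        theta = m.theta
        m2 = m.with_theta(theta)
        assert np.array_equal(m2.theta, theta)

    def test_theta_length_matches_orders(self, rng):
        m = random_stable_model(rng)
        expected = (m.input_nl.n_params + m.linear.nb + m.linear.nf
                    + m.output_nl.n_params)
        assert m.theta.size == expected
        with pytest.raises(ValueError):
            m.with_theta(np.zeros(expected + 1))

    def test_json_round_trip_preserves_simulation(self, rng, tmp_path):
        m = random_stable_model(rng)
        m.save(tmp_path / "model.json")
        m2 = HWModel.load(tmp_path / "model.json")
        u = rng.standard_normal(200)
        assert np.array_equal(simulate_hw(m, u), simulate_hw(m2, u))

    def test_identified_model_serialises_with_trajectory(self, smooth_input,
                                                         tmp_path):
        gen = HWModel(poly(0.0, 1.0), LinearBlock(b=[0.8], f=[-0.2], nk=0),
                      ident())
        y = SignalTrace(simulate_hw(gen, smooth_input.samples), fs=100.0,
                        kind="normalised")
        m = identify_hw(smooth_input, y)
        m.save(tmp_path / "m.json")
        m2 = HWModel.load(tmp_path / "m.json")
        assert m2.converged == m.converged
        assert np.array_equal(m2.theta, m.theta)
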