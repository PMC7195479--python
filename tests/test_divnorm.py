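"""Divisive-normalization dynamics, analytic kernel, and likelihood."""

import numpy as np
import pytest
from scipy.special import expit, logit

from clicknorm.task import (
    ClickTrain,
    Dataset,
    TaskProtocol,
    generate_click_train,
    generate_dataset,
    simulate_choices,
)
from clicknorm.divnorm import (
    DivNormObserver,
    DivNormParams,
    choice_probability,
    choice_probability_matrix,
    decision_variable,
    gain_trajectory,
    kernel_weights,
    log_likelihood,
    simulate_dynamics,
    static_normalization,
)


class TestStaticNormalization:
    def test_symmetric_pair(self):
        assert np.allclose(static_normalization([1, 1], 0.0), [0.5, 0.5])

    def test_semisaturation(self):
        assert np.allclose(static_normalization([2, 0, 0], 2.0), [0.5, 0, 0])

    def test_monotone_in_semisaturation(self):
        u = np.array([0.5, 1.5, 3.0])
        f1 = static_normalization(u, 1.0)
        f2 = static_normalization(u, 2.0)
        assert np.all(f2 < f1)
        assert static_normalization(u, 0.0).sum() == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            static_normalization([0.0, 0.0], 0.0)


class TestDynamics:
    def test_empty_train_stays_at_origin(self, exemplar_params):
        train = ClickTrain(np.array([]), np.array([]), 1.0)
        traj = simulate_dynamics(exemplar_params, train, dt=1e-3)
        assert np.all(traj.R_left == 0)
        assert np.all(traj.R_right == 0)
        assert np.all(traj.G == 0)

    def test_single_click_closed_form_without_inhibition(self):
        # one click at t=0 spanning the whole 1-s stimulus: R jumps by
        # 1/tau_R and decays as (1/tau_R) exp(-t/tau_R); G stays 0
        params = DivNormParams(tau_R=0.3, tau_G=1.0, omega_I=0.0)
        train = ClickTrain(np.array([0.0]), np.array([1]), 1.0)
        traj = simulate_dynamics(params, train, dt=1e-3)
        exact = (1 / 0.3) * np.exp(-traj.time_grid / 0.3)
        assert np.max(np.abs(traj.R_left - exact)) < 1e-8
        assert np.all(traj.G == 0)

    def test_fine_step_self_oracle_and_gain_growth(self, exemplar_params,
                                                   train):
        coarse = simulate_dynamics(exemplar_params, train, dt=1e-3)
        fine = simulate_dynamics(exemplar_params, train, dt=1e-5)
        # compare at decision time and at the shared click nodes
        assert abs(coarse.delta[-1] - fine.delta[-1]) < 1e-4
        assert abs(coarse.G[-1] - fine.G[-1]) < 1e-4
        peak = np.argmax(coarse.G)
        assert np.all(np.diff(coarse.G[: peak + 1]) >= -1e-12)

    def test_grid_contains_click_times(self, exemplar_params, train):
        traj = simulate_dynamics(exemplar_params, train, dt=1e-3)
        for t in train.times:
            assert np.min(np.abs(traj.time_grid - t)) < 1e-12

    def test_dt_larger_than_spacing_rejected(self, exemplar_params, train):
        with pytest.raises(ValueError):
            simulate_dynamics(exemplar_params, train, dt=0.2)


class TestGainTrajectory:
    def test_zero_inhibition_weight(self, proto):
        params = DivNormParams(tau_R=1.0, tau_G=2.0, omega_I=0.0)
        _, G = gain_trajectory(params, proto)
        assert np.all(G == 0)

    def test_shared_across_sign_sequences(self, proto, exemplar_params, rng):
        t1 = generate_click_train(proto, "L", rng)
        t2 = generate_click_train(proto, "R", rng)
        assert not np.array_equal(t1.signs, t2.signs)
        g1 = simulate_dynamics(exemplar_params, t1, dt=1e-3).G
        g2 = simulate_dynamics(exemplar_params, t2, dt=1e-3).G
        assert np.max(np.abs(g1 - g2)) < 1e-12

    def test_matches_full_simulation(self, proto, exemplar_params, train):
        _, G = gain_trajectory(exemplar_params, proto, dt=1e-3)
        full = simulate_dynamics(exemplar_params, train, dt=1e-3)
        assert np.max(np.abs(G - full.G)) < 1e-10


class TestKernelWeights:
    def test_pure_recency_kernel_without_inhibition(self, train):
        params = DivNormParams(tau_R=0.4, tau_G=3.0, omega_I=0.0)
        kw = kernel_weights(params, train)
        exact = (1 / 0.4) * np.exp(-(1.0 - train.times) / 0.4)
        assert np.array_equal(kw.per_click_K, exact)

    def test_exemplar_parameters_give_interior_bump(self, exemplar_params,
                                                    train):
        kw = kernel_weights(exemplar_params, train)
        i_star = int(np.argmax(kw.per_click_K))
        assert 0 < i_star < 19

    def test_kernel_positive_and_continuous_in_parameters(self, train):
        base = DivNormParams(tau_R=1.5, tau_G=4.0, omega_I=10.0)
        k0 = kernel_weights(base, train).per_click_K
        assert np.all(k0 > 0)
        for eps in (1e-5, 1e-6):
            kp = kernel_weights(
                DivNormParams(tau_R=1.5 + eps, tau_G=4.0, omega_I=10.0), train
            ).per_click_K
            assert np.max(np.abs(kp - k0)) < 50 * eps


class TestDecisionVariable:
    def test_sign_flip_antisymmetry(self, exemplar_params, train):
        d1 = decision_variable(exemplar_params, train)
        d2 = decision_variable(exemplar_params, train.flipped())
        assert d1 == pytest.approx(-d2, abs=1e-14)

    def test_all_left_train_is_positive(self, proto, exemplar_params):
        train = ClickTrain(proto.click_times, np.ones(20, int), 1.0)
        assert decision_variable(exemplar_params, train) > 0

    def test_dual_route_equivalence(self, exemplar_params, train):
        traj = simulate_dynamics(exemplar_params, train, dt=1e-3)
        dv = decision_variable(exemplar_params, train, dt=1e-3)
        assert abs(traj.delta[-1] - dv) < 1e-4


class TestChoiceProbability:
    def test_logit_identity_at_zero(self, proto):
        # sigma huge makes delta'/sigma vanish: p = logistic(bias)
        params = DivNormParams(1.0, 1.0, 1.0, sigma=1e9, bias=0.0)
        train = ClickTrain(proto.click_times, np.ones(20, int), 1.0)
        assert choice_probability(params, train) == pytest.approx(0.5)

    def test_mirror_probabilities_sum_to_one(self, exemplar_params, train):
        params = DivNormParams(
            exemplar_params.tau_R, exemplar_params.tau_G,
            exemplar_params.omega_I, sigma=0.01, mu=0.003, bias=0.0,
        )
        p1 = choice_probability(params, train)
        p2 = choice_probability(params, train.flipped())
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_composition_of_verified_parts(self, exemplar_params, train):
        params = DivNormParams(
            exemplar_params.tau_R, exemplar_params.tau_G,
            exemplar_params.omega_I, sigma=1.0, mu=0.0, bias=0.0,
        )
        dv = decision_variable(params, train)
        assert choice_probability(params, train) == pytest.approx(
            expit(dv / 1.0), abs=1e-12
        )

    def test_matrix_route_matches_scalar(self, exemplar_params, proto, rng):
        params = DivNormParams(2.27, 11.1, 36.2, sigma=0.02, mu=-0.001,
                               bias=0.3)
        ds = generate_dataset(proto, 50, rng)
        pm = choice_probability_matrix(
            params, ds.signs_matrix(), proto.click_times, 1.0
        )
        ps = np.array([choice_probability(params, t.train)
                       for t in ds.trials])
        assert np.allclose(pm, ps, atol=1e-12)


class TestLogLikelihood:
    def test_guessing_limit(self, proto, rng):
        ds = generate_dataset(proto, 200, rng)
        ds = simulate_choices(ds, lambda t: 0.5, rng)
        params = DivNormParams(1.0, 1.0, 1.0, sigma=1e9, bias=0.0)
        n = len(ds)
        assert abs(log_likelihood(params, ds) - n * np.log(0.5)) < 1e-6 * n

    def test_single_trial_known_probability(self, proto, rng):
        ds = generate_dataset(proto, 1, rng)
        ds = simulate_choices(ds, lambda t: 1.0, rng)  # forced left
        params = DivNormParams(1.0, 1.0, 1.0, sigma=1e9, bias=float(logit(0.9)))
        assert log_likelihood(params, ds) == pytest.approx(np.log(0.9),
                                                           abs=1e-9)

    def test_per_trial_loop_oracle(self, proto, rng):
        params = DivNormParams(2.27, 11.1, 36.2, sigma=0.02, mu=-0.002,
                               bias=0.1)
        ds = generate_dataset(proto, 100, rng)
        ds = simulate_choices(ds, DivNormObserver(params, proto), rng)
        ll = log_likelihood(params, ds)
        brute = 0.0
        for t in ds.trials:
            p = choice_probability(params, t.train)
            p = min(max(p, 1e-10), 1 - 1e-10)
            brute += np.log(p) if t.choice == "L" else np.log1p(-p)
        assert ll == pytest.approx(brute, abs=1e-9)

    def test_mirror_symmetry_at_zero_bias(self, proto, rng):
        params = DivNormParams(1.5, 8.0, 20.0, sigma=0.03, mu=0.001, bias=0.0)
        ds = generate_dataset(proto, 300, rng)
        ds = simulate_choices(ds, DivNormObserver(params, proto), rng)
        assert log_likelihood(params, ds) == pytest.approx(
            log_likelihood(params, ds.mirrored()), abs=1e-9
        )

    def test_missing_choices_rejected(self, proto, rng, exemplar_params):
        ds = generate_dataset(proto, 10, rng)
        with pytest.raises(ValueError):
            log_likelihood(exemplar_params, ds)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau_R": 0.0, "tau_G": 1.0, "omega_I": 1.0},
            {"tau_R": 1.0, "tau_G": -1.0, "omega_I": 1.0},
            {"tau_R": 1.0, "tau_G": 1.0, "omega_I": -0.1},
            {"tau_R": 1.0, "tau_G": 1.0, "omega_I": 1.0, "sigma": 0.0},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            DivNormParams(**kwargs)


def test_trajectory_export_is_tidy(exemplar_params, train):
    traj = simulate_dynamics(exemplar_params, train, dt=1e-3)
    df = traj.to_frame()
    assert list(df.columns) == ["t", "R_left", "R_right", "G", "delta"]
    assert np.allclose(df["delta"], df["R_left"] - df["R_right"])
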