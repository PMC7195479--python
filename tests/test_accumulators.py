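"""DDM/LCA closed forms, sensory adaptation, and the density-propagation
likelihood of the bounded adaptive accumulator."""

import numpy as np
import pytest
from scipy.special import ndtr

from clicknorm.task import (
    ClickTrain,
    TaskProtocol,
    generate_click_train,
    generate_dataset,
    simulate_choices,
)
from clicknorm.accumulators import (
    BruntonParams,
    LCAParams,
    adaptation_magnitudes,
    apply_click,
    benchmark_log_likelihood,
    brunton_choice_probability,
    ddm_choice_probability,
    fokker_planck_step,
    lca_bounded_choice_probability,
    lca_choice_probability,
    make_density_grid,
)


class TestLCAClosedForm:
    def test_time_symmetric_balanced_train_is_even_odds(self, proto):
        # equal left/right counts arranged symmetrically in time
        signs = np.array([1, -1] * 10)
        signs_rev = signs[::-1]
        train = ClickTrain(proto.click_times, signs + 0 * signs_rev, 1.0)
        p = lca_choice_probability(LCAParams(lam=0.0, sigma_a=1.0), train)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_matches_euler_simulation(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        params = LCAParams(lam=-1.5, sigma_a=1.2, bias=0.3)
        p_exact = lca_choice_probability(params, train)
        # independent path-simulation oracle
        n_paths, dt = 40_000, 1e-3
        sim = np.random.default_rng(0)
        a = np.zeros(n_paths)
        t = 0.0
        click_idx = 0
        nst = int(round(1.0 / dt))
        for step in range(nst):
            while click_idx < 20 and abs(t - train.times[click_idx]) < dt / 2:
                a += train.signs[click_idx]
                click_idx += 1
            a += params.lam * a * dt + params.sigma_a * np.sqrt(dt) * sim.standard_normal(n_paths)
            t += dt
        p_mc = np.mean(a > params.bias)
        se = np.sqrt(p_mc * (1 - p_mc) / n_paths)
        assert abs(p_exact - p_mc) < 4 * se + 0.01

    def test_mirror_sum_at_zero_bias(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        params = LCAParams(lam=0.8, sigma_a=0.9)
        p = lca_choice_probability(params, train)
        q = lca_choice_probability(params, train.flipped())
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_ddm_is_lam_zero(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        assert ddm_choice_probability(1.3, 0.2, train) == pytest.approx(
            lca_choice_probability(LCAParams(0.0, 1.3, 0.2), train)
        )


class TestAdaptation:
    def test_neutral_phi_gives_unit_magnitudes(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        assert np.all(adaptation_magnitudes(train, 1.0, 0.3) == 1.0)

    def test_instant_recovery_limit(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        mags = adaptation_magnitudes(train, 0.5, 1e-6)
        assert np.all(np.abs(mags - 1.0) < 1e-3)

    def test_hand_recursion_two_clicks(self):
        train = ClickTrain(np.array([0.0, 0.05]), np.array([1, 1]), 1.0)
        slow = adaptation_magnitudes(train, 0.5, 1e3)
        assert slow == pytest.approx([1.0, 0.5], abs=1e-4)
        fast = adaptation_magnitudes(train, 0.5, 0.05)
        assert fast[1] == pytest.approx(1 - 0.5 * np.exp(-1), abs=1e-12)

    def test_sides_adapt_independently(self):
        train = ClickTrain(np.array([0.0, 0.05, 0.10]),
                           np.array([1, -1, 1]), 1.0)
        mags = adaptation_magnitudes(train, 0.5, 1e3)
        # the interleaved right click neither adapts nor is adapted by left
        assert mags[1] == 1.0
        assert mags[2] == pytest.approx(0.5, abs=1e-4)

    def test_depression_then_facilitation(self):
        train = ClickTrain(np.array([0.0, 0.05]), np.array([1, 1]), 1.0)
        assert adaptation_magnitudes(train, 2.0, 1e3)[1] == pytest.approx(
            2.0, abs=1e-3
        )


class TestFokkerPlanck:
    def test_vanishing_diffusion_leaves_density(self):
        g = make_density_grid(1.0, 201)
        out = fokker_planck_step(g, 0.0, 1e-3, 0.0125)
        assert np.allclose(out.masses, g.masses)
        assert out.absorbed_left == 0.0

    def test_free_diffusion_matches_gaussian(self):
        g = make_density_grid(1.0, 1001)
        sigma, T, nst = 0.1, 1.0, 80
        for _ in range(nst):
            g = fokker_planck_step(g, 0.0, sigma, T / nst)
        x = g.a_values
        dx = x[1] - x[0]
        s = sigma * np.sqrt(T)
        exact = ndtr((x + dx / 2) / s) - ndtr((x - dx / 2) / s)
        assert 0.5 * np.sum(np.abs(g.masses - exact)) < 1e-3

    def test_mass_conserved_every_step(self):
        g = make_density_grid(2.0, 301)
        for _ in range(40):
            g = fokker_planck_step(g, 1.0, 0.8, 0.0125)
            assert abs(g.total_mass - 1.0) < 1e-9

    def test_strong_outward_drift_absorbs(self):
        g = make_density_grid(1.0, 201)
        g = apply_click(g, 0.9)
        for _ in range(20):
            g = fokker_planck_step(g, 20.0, 0.05, 0.0125)
        assert g.absorbed_left >= 0.99

    def test_narrow_kernel_with_drift_rejected(self):
        g = make_density_grid(1.0, 1001)
        with pytest.raises(ValueError, match="increase dt"):
            fokker_planck_step(g, 2.0, 1e-3, 1e-4)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            make_density_grid(1.0, 101)
        with pytest.raises(ValueError):
            make_density_grid(1.0, 500)


class TestBruntonModel:
    def test_mirror_sum_symmetric_parameters(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        bp = BruntonParams(sigma_a=0.8, lam=0.5, B=3.0, phi=1.0, tau_phi=1.0)
        p = brunton_choice_probability(bp, train)
        q = brunton_choice_probability(bp, train.flipped())
        assert p + q == pytest.approx(1.0, abs=1e-6)

    def test_unbounded_limit_matches_lca(self, proto):
        rng = np.random.default_rng(1)
        for _ in range(3):
            train = generate_click_train(proto, "L", rng)
            lam, sa, b = rng.uniform(-2, 2), rng.uniform(0.7, 2), rng.uniform(-1, 1)
            p_lca = lca_choice_probability(LCAParams(lam, sa, b), train)
            p_fp = brunton_choice_probability(
                BruntonParams(sa, lam, 50.0, 1.0, 1.0, b), train,
                n_nodes=2001, dt=0.0125,
            )
            assert abs(p_lca - p_fp) < 1e-3

    def test_sticky_bound_ignores_post_crossing_evidence(self, proto):
        all_left = ClickTrain(proto.click_times, np.ones(20, int), 1.0)
        flipped_tail = np.ones(20, int)
        flipped_tail[10:] = -1
        tail_train = ClickTrain(proto.click_times, flipped_tail, 1.0)
        bp = BruntonParams(sigma_a=1e-3, lam=0.0, B=5.0, phi=1.0, tau_phi=1.0)
        p1 = brunton_choice_probability(bp, all_left)
        p2 = brunton_choice_probability(bp, tail_train)
        assert p1 > 0.999
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_adaptation_neutrality(self, proto, rng):
        train = generate_click_train(proto, "L", rng)
        p_ref = lca_bounded_choice_probability(
            LCAParams(0.4, 1.1, 0.1), B=4.0, train=train
        )
        for tau_phi in (1e-3, 1.0, 50.0):
            bp = BruntonParams(1.1, 0.4, 4.0, 1.0, tau_phi, 0.1)
            assert brunton_choice_probability(bp, train) == pytest.approx(
                p_ref, abs=1e-12
            )

    def test_nesting_of_model_family(self, proto):
        rng = np.random.default_rng(4)
        for _ in range(5):
            train = generate_click_train(proto, "L", rng)
            sa, b = rng.uniform(0.7, 2), rng.uniform(-1, 1)
            p1 = ddm_choice_probability(sa, b, train)
            p2 = lca_choice_probability(LCAParams(0.0, sa, b), train)
            p3 = brunton_choice_probability(
                BruntonParams(sa, 0.0, 50.0, 1.0, 1.0, b), train,
                n_nodes=2001,
            )
            assert abs(p1 - p2) < 1e-12
            assert abs(p1 - p3) < 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BruntonParams(1.0, 0.0, -1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            BruntonParams(1.0, 0.0, 2.0, 1.0, 1.0, bias=2.5)


class TestBenchmarkLikelihood:
    def _choice_data(self, proto, n, observer, seed):
        rng = np.random.default_rng(seed)
        ds = generate_dataset(proto, n, rng)
        return simulate_choices(ds, observer, rng)

    def test_guessing_parameters(self, proto):
        ds = self._choice_data(proto, 150, lambda t: 0.5, 0)
        params = LCAParams(lam=0.0, sigma_a=1e9, bias=0.0)
        n = len(ds)
        ll = benchmark_log_likelihood("lca", params, ds)
        assert abs(ll - n * np.log(0.5)) < 1e-6 * n

    def test_per_trial_loop_oracle(self, proto):
        params = LCAParams(lam=-1.0, sigma_a=1.5, bias=0.2)
        ds = self._choice_data(
            proto, 80,
            lambda t: lca_choice_probability(params, t), 1,
        )
        ll = benchmark_log_likelihood("lca", params, ds)
        brute = 0.0
        for t in ds.trials:
            p = lca_choice_probability(params, t.train)
            p = min(max(p, 1e-10), 1 - 1e-10)
            brute += np.log(p) if t.choice == "L" else np.log1p(-p)
        assert ll == pytest.approx(brute, abs=1e-9)

    def test_mirror_symmetry_zero_bias(self, proto):
        params = LCAParams(lam=0.7, sigma_a=1.0, bias=0.0)
        ds = self._choice_data(
            proto, 120, lambda t: lca_choice_probability(params, t), 2
        )
        assert benchmark_log_likelihood("lca", params, ds) == pytest.approx(
            benchmark_log_likelihood("lca", params, ds.mirrored()), abs=1e-9
        )

    def test_unknown_tag_rejected(self, proto):
        ds = self._choice_data(proto, 60, lambda t: 0.5, 3)
        with pytest.raises(ValueError):
            benchmark_log_likelihood("nope", LCAParams(0.0, 1.0), ds)
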