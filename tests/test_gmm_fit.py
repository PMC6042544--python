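"""Likelihood, EM machinery and BIC for the mixture of mixed models."""

import math

import numpy as np
import pandas as pd
import pytest

import lctmflow as lf
from lctmflow.data_model import build_design
from lctmflow.gmm_fit import (
    MixtureParams,
    _cov_objective,
    _collect_stats,
    _moment_init,
    _pack_theta,
    marginal_covariance,
)
from lctmflow.synthetic import align_to_truth

IDT = lf.TimeTransform.identity()


def _scalar_dataset(times, ys, ids=None):
    n = len(times)
    frame = pd.DataFrame({"id": ids if ids is not None else [1] * n,
                          "time": times, "y": ys})
    return lf.TrajectoryDataset(frame)


def _params(code, K, beta, pi, sigma2=(1.0,), fixed_degree=0, B=None, omega=None,
            B_by_class=None, tt=IDT):
    from scipy.linalg import cholesky
    structure = lf.ModelStructure(code, K, fixed_degree=fixed_degree, time_transform=tt)
    q = structure.n_random
    L = None if B is None else cholesky(np.asarray(B, dtype=float), lower=True)
    L_by = None if B_by_class is None else np.stack(
        [cholesky(np.asarray(b, dtype=float), lower=True) for b in B_by_class])
    return MixtureParams(structure=structure, beta=np.asarray(beta, dtype=float),
                         pi=np.asarray(pi, dtype=float), L=L,
                         omega=None if omega is None else np.asarray(omega, dtype=float),
                         L_by_class=L_by, sigma2=np.asarray(sigma2, dtype=float))


class TestMarginalCovariance:
    def test_model_A_is_scaled_identity(self):
        p = _params("A", 1, [[0.0]], [1.0], sigma2=(2.0,))
        V = marginal_covariance(p, np.zeros((3, 0)), 0)
        np.testing.assert_allclose(V, 2.0 * np.eye(3))

    def test_random_intercept_hand_product(self):
        p = _params("C", 1, [[0.0]], [1.0], sigma2=(1.5,), B=[[0.7]])
        V = marginal_covariance(p, np.ones((3, 1)), 0)
        np.testing.assert_allclose(V, 1.5 * np.eye(3) + 0.7 * np.ones((3, 3)))

    def test_proportional_with_unit_scales_reduces_to_equal(self):
        B = np.array([[1.0, 0.2, 0.1], [0.2, 0.5, 0.05], [0.1, 0.05, 0.25]])
        Z = np.vander([0.1, 0.5, 1.0], 3, increasing=True)
        beta = [[0, 0, 0], [1, 1, 1]]
        pF = _params("F", 2, beta, [0.5, 0.5], fixed_degree=2, B=B, omega=[1.0, 1.0])
        pE = _params("E", 2, beta, [0.5, 0.5], fixed_degree=2, B=B)
        for k in range(2):
            np.testing.assert_allclose(marginal_covariance(pF, Z, k),
                                       marginal_covariance(pE, Z, k))


class TestLogLikelihood:
    def test_standard_normal_at_its_mode(self):
        ds = _scalar_dataset([0.0], [3.0])
        p = _params("A", 1, [[3.0]], [1.0])
        assert lf.log_likelihood(p, ds, ridge=0.0) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_mixture_of_identical_classes_collapses(self):
        ds = _scalar_dataset([0.0, 1.0, 0.0, 1.0], [1.0, 2.0, 0.5, 1.5], ids=[1, 1, 2, 2])
        p1 = _params("A", 1, [[1.0]], [1.0], sigma2=(2.0,))
        for pi0 in (0.2, 0.5, 0.9):
            p2 = _params("A", 2, [[1.0], [1.0]], [pi0, 1 - pi0], sigma2=(2.0,))
            assert lf.log_likelihood(p2, ds) == pytest.approx(lf.log_likelihood(p1, ds))

    def test_invariant_to_class_relabelling(self):
        ds = _scalar_dataset([0.0, 1.0], [0.3, 1.9], ids=[1, 2])
        p = _params("B", 2, [[0.0], [2.0]], [0.3, 0.7], sigma2=(1.0, 2.0))
        p_swapped = _params("B", 2, [[2.0], [0.0]], [0.7, 0.3], sigma2=(2.0, 1.0))
        assert lf.log_likelihood(p, ds) == pytest.approx(lf.log_likelihood(p_swapped, ds))

    @pytest.mark.parametrize("code", ["C", "D", "E", "F", "G"])
    def test_monte_carlo_oracle_small_instance(self, code):
        """Marginal likelihood equals MC integration over random effects."""
        cfg = lf.two_class_config(n_subjects=2, structure_code=code, seed=21)
        sim = lf.simulate(cfg)
        st = cfg.structure
        design = build_design(sim.dataset, st)
        beta = np.asarray(cfg.beta)
        pi = np.asarray(cfg.pi)
        params = _params(code, 2, beta, pi, sigma2=cfg.sigma2, fixed_degree=2,
                         B=cfg.B, omega=cfg.omega, B_by_class=cfg.B_by_class,
                         tt=st.time_transform)
        ll = lf.log_likelihood(params, design, ridge=0.0)
        rng = np.random.default_rng(99)
        n_draw = 200_000
        tot, var_tot = 0.0, 0.0
        for s in design.subjects:
            mk = np.zeros(2)
            vk = np.zeros(2)
            for k in range(2):
                B = cfg.class_random_cov(k)
                sig = cfg.class_sigma2(k)
                b = rng.multivariate_normal(np.zeros(B.shape[0]), B, size=n_draw,
                                            method="cholesky")
                R = s.y - (s.X @ beta[k] + b @ s.Z.T)
                logd = -0.5 * (s.n_obs * np.log(2 * np.pi * sig) + (R ** 2).sum(1) / sig)
                d = np.exp(logd)
                mk[k] = d.mean()
                vk[k] = d.var() / n_draw
            m = float(pi @ mk)
            tot += np.log(m)
            var_tot += float(pi ** 2 @ vk) / m ** 2
        assert abs(ll - tot) < 3.0 * np.sqrt(var_tot)


class TestEStep:
    def test_identical_classes_return_prior(self):
        ds = _scalar_dataset([0.0, 0.0], [1.0, -1.0], ids=[1, 2])
        p = _params("A", 2, [[0.0], [0.0]], [0.3, 0.7])
        post = lf.e_step(p, ds)
        np.testing.assert_allclose(post, [[0.3, 0.7], [0.3, 0.7]])

    def test_single_class_is_all_ones(self):
        ds = _scalar_dataset([0.0], [1.0])
        post = lf.e_step(_params("A", 1, [[0.0]], [1.0]), ds)
        np.testing.assert_array_equal(post, [[1.0]])

    def test_hand_computed_scalar_posterior(self):
        # one obs y=0; unit-variance classes at means 0 and 2, uniform prior:
        # p_1 = 1 / (1 + exp(-2))
        ds = _scalar_dataset([0.0], [0.0])
        p = _params("A", 2, [[0.0], [2.0]], [0.5, 0.5])
        post = lf.e_step(p, ds, ridge=0.0)
        assert post[0, 0] == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), abs=1e-12)

    def test_rows_sum_to_one(self, two_class_F):
        cfg, sim, model = two_class_F
        np.testing.assert_allclose(model.posterior.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_one_hot_posterior_model_A_gives_per_class_ols(self):
        rng = np.random.default_rng(3)
        times = [0.0, 1.0, 2.0, 3.0]
        rows = []
        for i in range(10):
            slope = 1.0 if i < 5 else -2.0
            for t in times:
                rows.append({"id": i, "time": t, "y": slope * t + rng.normal(0, 0.2)})
        ds = lf.TrajectoryDataset(pd.DataFrame(rows))
        s = lf.ModelStructure("A", 2, fixed_degree=1, time_transform=IDT)
        post = np.zeros((10, 2))
        post[:5, 0] = 1.0
        post[5:, 1] = 1.0
        params = lf.m_step(post, ds, s)
        frame = ds.frame
        sse = 0.0
        for k, ids in enumerate([range(5), range(5, 10)]):
            sub = frame[frame["id"].isin(ids)]
            coef = np.polynomial.polynomial.polyfit(sub["time"], sub["y"], 1)
            np.testing.assert_allclose(params.beta[k], coef, atol=1e-8)
            fitted = np.polynomial.polynomial.polyval(sub["time"].to_numpy(), coef)
            sse += float(((sub["y"].to_numpy() - fitted) ** 2).sum())
        assert params.sigma2[0] == pytest.approx(sse / len(frame))

    def test_uniform_posterior_gives_equal_betas(self):
        ds = _scalar_dataset([0.0, 1.0, 0.0, 1.0], [1.0, 3.0, -1.0, 2.0], ids=[1, 1, 2, 2])
        s = lf.ModelStructure("A", 2, fixed_degree=1, time_transform=IDT)
        params = lf.m_step(np.full((2, 2), 0.5), ds, s)
        np.testing.assert_allclose(params.beta[0], params.beta[1], atol=1e-10)

    def test_pi_update_is_posterior_column_means(self):
        ds = _scalar_dataset([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], ids=[1, 2, 3])
        s = lf.ModelStructure("A", 2, fixed_degree=0, time_transform=IDT)
        post = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        params = lf.m_step(post, ds, s)
        np.testing.assert_allclose(params.pi, [2 / 3, 1 / 3], atol=1e-9)


class TestCovarianceObjectiveGradient:
    @pytest.mark.parametrize("code", ["C", "D", "E", "F", "G"])
    def test_analytic_gradient_matches_finite_differences(self, code):
        from scipy.optimize import approx_fprime
        cfg = lf.two_class_config(n_subjects=40, structure_code=code, seed=3)
        sim = lf.simulate(cfg)
        st = cfg.structure
        design = build_design(sim.dataset, st)
        rng = np.random.default_rng(0)
        post = rng.dirichlet([1, 1], size=design.n_subjects)
        params = _moment_init(design, st, post)
        collapse = st.random_cov_mode == "shared"
        stats = _collect_stats(post, params.beta, design, collapse)
        theta = _pack_theta(params) + 0.1 * rng.standard_normal(_pack_theta(params).size)
        num = approx_fprime(theta, lambda th: _cov_objective(th, stats, st, 1e-8)[0], 1e-6)
        ana = _cov_objective(theta, stats, st, 1e-8)[1]
        np.testing.assert_allclose(ana, num, rtol=1e-3, atol=1e-4)


class TestFit:
    def test_single_class_model_A_equals_polynomial_least_squares(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(30):
            for t in (18.0, 35.0, 50.0, 62.5):
                rows.append({"id": i, "time": t,
                             "y": 20 + 0.1 * t - 0.001 * t ** 2 + rng.normal(0, 1)})
        ds = lf.TrajectoryDataset(pd.DataFrame(rows))
        s = lf.ModelStructure("A", 1)
        model = lf.fit(ds, s, lf.FitConfig(n_starts=1, seed=0))
        t = s.time_transform.apply(ds.frame["time"].to_numpy())
        coef = np.polynomial.polynomial.polyfit(t, ds.frame["y"].to_numpy(), 2)
        np.testing.assert_allclose(model.beta[0], coef, rtol=1e-6)

    def test_two_class_recovery_well_separated(self, two_class_F):
        cfg, sim, model = two_class_F
        assert model.converged
        perm, kappa = align_to_truth(sim.labels, model)
        assert kappa > 0.9
        err = np.abs(model.beta[list(perm)] - np.asarray(cfg.beta))
        assert err.mean() < 0.2  # transformed-time coefficient scale

    def test_refit_same_seed_is_bit_identical(self, two_class_F):
        cfg, sim, model = two_class_F
        again = lf.fit(sim.dataset, cfg.structure, lf.FitConfig(n_starts=2, seed=5))
        assert model.loglik == again.loglik
        assert np.array_equal(model.beta, again.beta)
        assert np.array_equal(model.posterior, again.posterior)

    def test_loglik_non_decreasing_across_iterations(self, two_class_F):
        _, _, model = two_class_F
        trace = model.loglik_trace
        assert trace is not None and trace.size >= 2
        drops = np.diff(trace) < -1e-8 * np.maximum(1.0, np.abs(trace[:-1]))
        assert not drops.any()

    def test_classes_in_descending_pi_order(self, two_class_F):
        _, _, model = two_class_F
        assert np.all(np.diff(model.pi) <= 1e-12)

    def test_model_F_omega_reference_class_is_unity(self, two_class_F):
        _, _, model = two_class_F
        assert model.omega[-1] == pytest.approx(1.0)
        assert np.all(model.omega > 0)

    def test_nesting_of_random_quadratic_structures(self, three_class_sim):
        """E is nested in F is nested in G: max loglik must be ordered."""
        cfg, sim = three_class_sim
        fc = lf.FitConfig(n_starts=2, seed=13)
        lls = {}
        for code in ("E", "F", "G"):
            st = lf.ModelStructure(code, 3)
            lls[code] = lf.fit(sim.dataset, st, fc).loglik
        slack = 1.0  # multi-start optimisation noise
        assert lls["F"] >= lls["E"] - slack
        assert lls["G"] >= lls["F"] - slack

    def test_structure_needing_random_effects_rejects_sparse_subjects(self):
        ds = _scalar_dataset([0.0, 1.0, 0.0, 1.0], [1.0, 2.0, 3.0, 4.0], ids=[1, 1, 2, 2])
        with pytest.raises(lf.DataError):
            lf.fit(ds, lf.ModelStructure("E", 1, time_transform=IDT),
                   lf.FitConfig(n_starts=1, seed=0))


class TestBic:
    def test_direct_formula(self, two_class_F):
        _, _, model = two_class_F
        import dataclasses
        m = dataclasses.replace(model, loglik=-100.0, n_params=2, n_subjects=50)
        assert lf.bic(m) == pytest.approx(200 + 2 * math.log(50))

    def test_undefined_for_non_converged_model(self, two_class_F):
        import dataclasses
        _, _, model = two_class_F
        bad = dataclasses.replace(model, converged=False)
        with pytest.raises(lf.NonConvergenceError):
            lf.bic(bad)

    def test_duplicate_class_raises_bic(self, three_class_sim):
        """More classes than the data support cannot beat the true K's BIC."""
        cfg, sim = three_class_sim
        fc = lf.FitConfig(n_starts=2, seed=31)
        b3 = lf.bic(lf.fit(sim.dataset, cfg.structure.with_classes(3), fc))
        m4 = lf.fit(sim.dataset, cfg.structure.with_classes(4), fc)
        if m4.converged:
            assert lf.bic(m4) > b3

    def test_p_for_model_F_K5_inside_formula(self, two_class_F):
        import dataclasses
        _, _, model = two_class_F
        s5 = lf.ModelStructure("F", 5)
        m = dataclasses.replace(model, structure=s5,
                                n_params=lf.count_parameters(s5))
        assert m.n_params == 30
        expected = -2 * m.loglik + 30 * math.log(m.n_subjects)
        assert lf.bic(m) == pytest.approx(expected)
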