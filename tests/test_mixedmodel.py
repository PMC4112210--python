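import numpy as np
import pytest
from scipy import linalg

import gblupgwas as g
from gblupgwas.mixedmodel import (REMLFit, VarianceComponents, _ll_parts,
                                  _kernels, _projection, pev_ahat, reml_loglik,
                                  var_ahat, vc_standard_errors)


def _fixed_vc_fit(data, G, s_a, s_e):
    """REMLFit shell at user-supplied variance components (no optimization)."""
    from gblupgwas.mixedmodel import _solve_at_optimum
    vc = VarianceComponents(genetic=(s_a,), sigma2_e=s_e)
    ll, beta, terms = _solve_at_optimum(data, [G], vc)
    return REMLFit(vc=vc, beta=beta, ahat_terms=terms, loglik=ll,
                   converged=True, n_iter=0, data=data, grms=[G])


class TestRemlFit:
    def test_identity_grm_null_heritability_reduces_to_ols(self):
        # balanced design: 2 records per animal, independent animal effects,
        # data simulated with sigma2_a = 0
        rng = np.random.default_rng(0)
        q = 40
        obs_idx = np.repeat(np.arange(q), 2)
        n = 2 * q
        X = np.ones((n, 1))
        # antisymmetric record pairs: every animal mean equals the intercept,
        # so the between-animal variance component is exactly at zero
        e = rng.normal(0, 1.5, size=q)
        y = 2.0 + np.column_stack([e, -e]).ravel()
        G = g.GRM(G=np.eye(q))
        fit = g.reml_fit(g.DesignData(y=y, X=X, obs_idx=obs_idx), G,
                         compute_pev=False)
        assert fit.vc.sigma2_a <= 1e-6 * np.var(y)
        ols = linalg.lstsq(X, y)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_fast_and_generic_paths_agree(self, toy_mixed):
        data, G = toy_mixed["data"], toy_mixed["G"]
        f1 = g.reml_fit(data, G, method="eig", compute_pev=False)
        f2 = g.reml_fit(data, G, method="generic", compute_pev=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.vc.sigma2_a == pytest.approx(f2.vc.sigma2_a, rel=1e-3)

    def test_recovers_simulated_heritability_on_average(self):
        h2s = []
        for seed in range(1, 11):
            sim = g.simulate(seed=seed)
            data = sim.design()
            p = sim.geno.dosage.mean(axis=0) / 2
            keep = (p > 0) & (p < 1)
            geno = sim.geno.subset(marker_idx=np.where(keep)[0])
            G = g.compute_grm(g.standardize(geno, p[keep]))
            h2s.append(g.reml_fit(data, G, compute_pev=False).vc.h2)
        assert np.mean(h2s) == pytest.approx(0.42, abs=0.08)

    def test_scale_equivariance(self, toy_mixed):
        data, G = toy_mixed["data"], toy_mixed["G"]
        fit1 = g.reml_fit(data, G, compute_pev=False)
        data2 = g.DesignData(y=3.0 * data.y, X=data.X)
        fit2 = g.reml_fit(data2, G, compute_pev=False)
        assert fit2.vc.sigma2_a == pytest.approx(9 * fit1.vc.sigma2_a, rel=1e-3)
        assert fit2.vc.sigma2_e == pytest.approx(9 * fit1.vc.sigma2_e, rel=1e-3)

    def test_translation_invariance_with_intercept(self, toy_mixed, toy_fit):
        data, G = toy_mixed["data"], toy_mixed["G"]
        data2 = g.DesignData(y=data.y + 100.0, X=data.X)
        fit2 = g.reml_fit(data2, G, compute_pev=False)
        assert fit2.loglik == pytest.approx(toy_fit.loglik, abs=1e-5)

    def test_nested_model_never_beats_full_model(self, toy_mixed, toy_fit):
        data, G, M, p = (toy_mixed["data"], toy_mixed["G"], toy_mixed["M"],
                         toy_mixed["p"])
        Z = toy_mixed["Z"]
        idx = np.arange(5)
        G1 = g.segment_grm(M, p, idx)
        G2 = g.complement_grm(G, Z, idx)
        full = g.reml_fit(data, [G1, G2], compute_pev=False)
        assert full.loglik >= toy_fit.loglik - 1e-6

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            g.reml_fit(g.DesignData(y=np.array([1.0, 2.0]),
                                    X=np.ones((2, 1))), g.GRM(G=np.eye(2)))


class TestBlup:
    def test_perfect_fixed_fit_gives_zero_breeding_values(self):
        n = 10
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0])  # y lies exactly in span(X)
        A = rng.normal(size=(n, n + 3))
        G = g.GRM(G=A @ A.T / (n + 3))
        fit = _fixed_vc_fit(g.DesignData(y=y, X=X), G, 1.0, 1.0)
        np.testing.assert_allclose(fit.ahat, 0.0, atol=1e-10)

    def test_matches_explicit_mme_solution(self):
        # 5-animal toy at fixed variance components against the hand-built
        # Henderson coefficient matrix
        rng = np.random.default_rng(8)
        n = 5
        A = rng.normal(size=(n, n + 4))
        Gmat = A @ A.T / (n + 4)
        G = g.GRM(G=Gmat)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n).astype(float)])
        y = rng.normal(size=n)
        s_a, s_e = 2.0, 1.5
        data = g.DesignData(y=y, X=X)
        fit = _fixed_vc_fit(data, G, s_a, s_e)
        lam = s_e / s_a
        C = np.block([[X.T @ X, X.T], [X, np.eye(n) + lam * linalg.inv(Gmat)]])
        rhs = np.concatenate([X.T @ y, y])
        sol = linalg.solve(C, rhs)
        np.testing.assert_allclose(fit.beta, sol[:2], rtol=1e-8)
        np.testing.assert_allclose(fit.ahat, sol[2:], rtol=1e-8, atol=1e-10)

    def test_projection_orthogonal_to_fixed_effects(self, toy_mixed, toy_fit):
        data, G = toy_mixed["data"], toy_mixed["G"]
        Ks = _kernels(data, [G])
        _, _, _, _, Py = _ll_parts(data.y, data.X, Ks,
                                   np.array(toy_fit.vc.genetic),
                                   toy_fit.vc.sigma2_e)
        np.testing.assert_allclose(data.X.T @ Py, 0.0, atol=1e-8)

    def test_blup_function_matches_fit(self, toy_mixed, toy_fit):
        np.testing.assert_allclose(g.blup(toy_fit), toy_fit.ahat, rtol=1e-12)


class TestPev:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dual_route_equality(self, seed):
        # well-conditioned dense G so the Henderson-inverse route is exact
        rng = np.random.default_rng(seed)
        n = 12
        A = rng.normal(size=(n, 3 * n))
        G = g.GRM(G=A @ A.T / (3 * n))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = _fixed_vc_fit(g.DesignData(y=y, X=X), G, 1.7, 0.9)
        pm = pev_ahat(fit, route="mme")
        pv = pev_ahat(fit, route="vroute")
        scale = np.max(np.abs(pv))
        assert np.max(np.abs(pm - pv)) / scale < 1e-6

    def test_pev_diagonal_bounded_by_prior_variance(self, toy_mixed, toy_fit):
        G = toy_mixed["G"]
        d = np.diag(toy_fit.pev)
        assert np.all(d >= -1e-8)
        assert np.all(d <= np.diag(G.G) * toy_fit.vc.sigma2_a + 1e-8)

    def test_record_shrinks_pev(self):
        # animal 0 unphenotyped vs phenotyped: its PEV diagonal must drop
        rng = np.random.default_rng(17)
        q = 8
        A = rng.normal(size=(q, q + 5))
        G = g.GRM(G=A @ A.T / (q + 5))
        y = rng.normal(size=q)
        X = np.ones((q, 1))
        without = g.DesignData(y=y[1:], X=X[1:], obs_idx=np.arange(1, q))
        with_rec = g.DesignData(y=y, X=X, obs_idx=np.arange(q))
        f0 = _fixed_vc_fit(without, G, 1.0, 1.0)
        f1 = _fixed_vc_fit(with_rec, G, 1.0, 1.0)
        p0 = pev_ahat(f0, data=without, grm=G)
        p1 = pev_ahat(f1, data=with_rec, grm=G)
        assert p1[0, 0] < p0[0, 0]

    def test_var_ahat_equals_projection_brute_force(self, toy_mixed, toy_fit):
        data, G = toy_mixed["data"], toy_mixed["G"]
        P = _projection(data, [G], toy_fit.vc)
        sa = toy_fit.vc.sigma2_a
        brute = sa**2 * G.G @ P @ G.G
        np.testing.assert_allclose(var_ahat(toy_fit), brute,
                                   rtol=1e-6, atol=1e-8)

    def test_trace_bounded_by_prior(self, toy_fit, toy_mixed):
        V = var_ahat(toy_fit)
        assert np.trace(V) <= np.trace(toy_mixed["G"].G) * toy_fit.vc.sigma2_a


class TestModelEquivalence:
    """Animal model (GRM covariance) vs marker-effects ridge model."""

    def test_marker_model_gives_same_beta_fitted_and_blups(self, toy_mixed,
                                                           toy_fit):
        data, G, Z = toy_mixed["data"], toy_mixed["G"], toy_mixed["Z"]
        sa, se = toy_fit.vc.sigma2_a, toy_fit.vc.sigma2_e
        n = data.n_obs
        # direct ridge fit of y = Xb + Z g + e with g ~ N(0, I sa)
        V = sa * Z.Z @ Z.Z.T + se * np.eye(n)
        Vi = linalg.inv(V)
        beta = linalg.solve(data.X.T @ Vi @ data.X, data.X.T @ Vi @ data.y)
        r = data.y - data.X @ beta
        ghat = sa * Z.Z.T @ Vi @ r
        np.testing.assert_allclose(beta, toy_fit.beta, rtol=1e-8)
        np.testing.assert_allclose(Z.Z @ ghat, toy_fit.ahat, rtol=1e-6,
                                   atol=1e-10)

    def test_equal_restricted_loglik_under_both_parameterizations(
            self, toy_mixed, toy_fit):
        data, Z = toy_mixed["data"], toy_mixed["Z"]
        G_marker = g.GRM(G=Z.Z @ Z.Z.T)  # covariance implied by model 2b
        ll = reml_loglik(data, [G_marker], toy_fit.vc)
        assert ll == pytest.approx(toy_fit.loglik, abs=1e-6)


def test_vc_standard_errors_positive(toy_fit):
    se = vc_standard_errors(toy_fit)
    assert se.shape == (2,)
    assert np.all(se > 0)
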