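"""Likelihood layer: predictors, complete-data density, marginal oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from melsjm import (
    ModelSpec,
    Parameters,
    RandomEffects,
    build_design,
    complete_data_logdensity,
    implied_correlations,
    load_dataset,
    marginal_loglik,
    marginal_loglik_bruteforce,
    marginal_loglik_montecarlo,
)
from melsjm.model_core import (
    DefinitenessError,
    log_within_variance,
    mean_predictor,
    outcome_predictor,
)
from melsjm._speed import FastLoglik

from conftest import manual_tables


def _single_visit_design(ages, values, spec=None):
    spec = spec or ModelSpec(mean_terms=("age",), scale_terms=(),
                             outcome_terms=(), levels=2)
    ds = load_dataset(*manual_tables(ages, values))
    return build_design(ds, spec)


def _params(design, beta, alpha=(0.0,), gamma=(0.0,), loadings=(0.0, 0.0, 0.0),
            Sigma=None, sigma_u3=1.0, sigma_eps=None):
    spec = design.spec
    return Parameters(
        beta=np.asarray(beta, float),
        alpha=np.asarray(alpha, float),
        gamma=np.asarray(gamma, float),
        loadings=np.asarray(loadings, float)[: spec.n_loadings],
        Sigma_u=np.eye(3) if Sigma is None else Sigma,
        sigma_u3=sigma_u3,
        sigma_eps=sigma_eps,
    )


class TestPredictors:
    def test_mean_intercept_only(self):
        d = _single_visit_design([10.0, 12.0], [100.0, 104.0])
        p = _params(d, beta=(100.0, 2.0))
        u = RandomEffects(np.zeros((1, 3)))
        # visit 0 has centered age -1
        assert mean_predictor(d, p, u, 0) == pytest.approx(100.0 - 2.0)

    def test_mean_with_random_effects(self):
        # centered ages (-1.5, +1.5); at z=1.5 with u0=3, u1=-1:
        # 100 + 1.5*2 + 3 - 1.5 = 104.5
        d = _single_visit_design([9.5, 12.5], [100.0, 104.0])
        p = _params(d, beta=(100.0, 2.0))
        u = RandomEffects(np.array([[3.0, -1.0, 0.0]]))
        assert mean_predictor(d, p, u, 1) == pytest.approx(104.5)

    def test_wrong_beta_length_raises(self):
        d = _single_visit_design([10.0, 12.0], [100.0, 104.0])
        p = _params(d, beta=(100.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="beta"):
            mean_predictor(d, p, RandomEffects(np.zeros((1, 3))), 0)

    def test_log_variance_identity_and_positivity(self):
        d = _single_visit_design([10.0, 12.0], [100.0, 104.0])
        p = _params(d, beta=(0.0, 0.0), alpha=(np.log(25.0),))
        u = RandomEffects(np.zeros((1, 3)))
        sv = log_within_variance(d, p, u, 0)
        assert sv.var == pytest.approx(25.0)
        # any u2: variance stays positive through the log link
        for u2 in (-8.0, 0.0, 8.0):
            sv = log_within_variance(
                d, p, RandomEffects(np.array([[0.0, 0.0, u2]])), 0
            )
            assert sv.var > 0

    @pytest.mark.parametrize(
        "shared, loadings, u, expected",
        [
            (("log_scale",), (0.5,), (0.0, 0.0, -2.0), 3.3 - 1.0),
            ((), (), (5.0, 5.0, 5.0), 3.3),
            (("location", "slope", "log_scale"), (0.1, 0.2, 0.3),
             (1.0, 1.0, 1.0), 3.3 + 0.6),
        ],
    )
    def test_outcome_predictor_shared_subsets(self, shared, loadings, u, expected):
        spec = ModelSpec(mean_terms=("age",), scale_terms=(), outcome_terms=(),
                         levels=2, shared_effects=shared)
        d = _single_visit_design([10.0, 12.0], [100.0, 104.0], spec)
        p = _params(d, beta=(0.0, 0.0), gamma=(3.3,), loadings=loadings)
        eff = RandomEffects(np.array([u], dtype=float))
        assert outcome_predictor(d, p, eff, 0) == pytest.approx(expected)


class TestImpliedCorrelations:
    def test_identity(self):
        assert implied_correlations(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_printed_example(self):
        S = np.array([[4.0, 2.0, 0.0], [2.0, 4.0, 0.0], [0.0, 0.0, 1.0]])
        assert implied_correlations(S) == pytest.approx((0.5, 0.0, 0.0))

    def test_non_pd_rejected(self):
        S = np.array([[1.0, 1.5, 0.0], [1.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(DefinitenessError):
            implied_correlations(S)


class TestCompleteDataDensity:
    def test_standard_normal_case(self):
        d = _single_visit_design([10.0], [0.0])
        p = _params(d, beta=(0.0, 0.0))  # var = exp(0) = 1
        u = RandomEffects(np.zeros((1, 3)))
        val = complete_data_logdensity(d, p, u)
        # measurement term + MVN(0;0,I3) + outcome Normal(log outcome; 0, 1)
        expected = (
            -0.5 * np.log(2 * np.pi)
            - 1.5 * np.log(2 * np.pi)
            - 0.5 * np.log(2 * np.pi) - 0.5 * np.log(2.0) ** 2
        )
        assert val == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_mvn_construction(self, tiny_cohort):
        """Per-clinic compound symmetry equals a generic MVN evaluation."""
        cfg, dataset, design, truth = tiny_cohort
        p = cfg.true_params
        u = RandomEffects(truth.u)
        mine = complete_data_logdensity(design, p, u)

        direct = 0.0
        mu_visit = design.X_mean @ p.beta + truth.u[design.visit_individual, 0] \
            + truth.u[design.visit_individual, 1] * design.z_age
        log_var = design.X_scale @ p.alpha + truth.u[design.visit_individual, 2]
        for v in range(design.n_visits):
            rows = np.where(design.measurement_visit == v)[0]
            n = len(rows)
            cov = np.exp(log_var[v]) * np.ones((n, n)) \
                + np.diag(p.sigma_eps**2 / design.n_pooled[rows])
            direct += multivariate_normal.logpdf(
                design.y[rows], mean=np.full(n, mu_visit[v]), cov=cov
            )
        direct += multivariate_normal.logpdf(
            truth.u, mean=np.zeros(3), cov=p.Sigma_u
        ).sum()
        g = p.full_loadings(cfg.spec)
        pred = design.X_outcome @ p.gamma + truth.u @ g
        direct += sum(
            multivariate_normal.logpdf(design.y2[j], mean=pred[j],
                                       cov=p.sigma_u3**2)
            for j in range(design.n_individuals)
        )
        assert mine == pytest.approx(direct, abs=1e-10)

    def test_unimodal_in_single_residual(self, tiny_cohort):
        cfg, dataset, design, truth = tiny_cohort
        u = RandomEffects(truth.u)
        base = complete_data_logdensity(design, cfg.true_params, u)
        worse = dataset.measurements.copy()
        worse.loc[0, "value"] += 40.0
        d2 = build_design(
            type(dataset)(worse, dataset.clinics, dataset.individuals),
            cfg.spec,
        )
        assert complete_data_logdensity(d2, cfg.true_params, u) < base

    def test_non_pd_sigma_raises(self, tiny_cohort):
        cfg, _, design, _ = tiny_cohort
        S = np.array([[1.0, 1.5, 0.0], [1.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(DefinitenessError):
            Parameters(
                beta=cfg.true_params.beta, alpha=cfg.true_params.alpha,
                gamma=cfg.true_params.gamma, loadings=cfg.true_params.loadings,
                Sigma_u=S, sigma_u3=0.2, sigma_eps=5.6,
            )


class TestMarginalLikelihood:
    def test_quadrature_self_consistency(self, tiny_cohort):
        cfg, _, design, _ = tiny_cohort
        p = cfg.true_params
        a = marginal_loglik(design, p, quad_order=15)
        b = marginal_loglik(design, p, quad_order=25)
        assert abs(a - b) / abs(b) < 1e-6

    def test_agrees_with_bruteforce_quadrature(self, tiny_cohort):
        cfg, _, design, _ = tiny_cohort
        p = cfg.true_params
        a = marginal_loglik(design, p, quad_order=25)
        b = marginal_loglik_bruteforce(design, p, quad_order=25)
        assert abs(a - b) / abs(b) < 1e-6

    def test_agrees_with_monte_carlo(self, tiny_cohort):
        cfg, _, design, _ = tiny_cohort
        p = cfg.true_params
        a = marginal_loglik(design, p, quad_order=25)
        mc, se = marginal_loglik_montecarlo(design, p, n_draws=100_000, seed=3)
        assert abs(a - mc) < 3 * se

    def test_degenerate_variances_reduce_to_complete_data(self, tiny_cohort):
        cfg, _, design, _ = tiny_cohort
        p = cfg.true_params
        sd = 1e-6
        p0 = Parameters(
            beta=p.beta, alpha=p.alpha, gamma=p.gamma, loadings=p.loadings,
            Sigma_u=np.eye(3) * sd**2, sigma_u3=p.sigma_u3,
            sigma_eps=p.sigma_eps,
        )
        u0 = RandomEffects(np.zeros((design.n_individuals, 3)))
        # remove the (constant) MVN prior factor evaluated at u = 0
        prior_at_zero = design.n_individuals * (
            -1.5 * np.log(2 * np.pi) - 3 * np.log(sd)
        )
        assert marginal_loglik(design, p0, 25) == pytest.approx(
            complete_data_logdensity(design, p0, u0) - prior_at_zero, abs=1e-5
        )

    def test_individual_relabelling_invariance(self, tiny_cohort):
        cfg, dataset, design, _ = tiny_cohort
        relabeled = dataset.measurements.copy()
        mapping = {1: 3, 2: 1, 3: 2}
        relabeled["individual_id"] = relabeled["individual_id"].map(mapping)
        clin = dataset.clinics.copy()
        clin["individual_id"] = clin["individual_id"].map(mapping)
        ind = dataset.individuals.copy()
        ind["individual_id"] = ind["individual_id"].map(mapping)
        d2 = build_design(load_dataset(relabeled, clin, ind), cfg.spec)
        p = cfg.true_params
        assert marginal_loglik(d2, p, 25) == pytest.approx(
            marginal_loglik(design, p, 25), rel=1e-12
        )

    def test_homoskedastic_reduction(self):
        """With no scale covariates and sigma_u2 ~ 0 the likelihood equals a
        directly coded homoskedastic growth-curve MVN density."""
        spec = ModelSpec(mean_terms=("age",), scale_terms=(), outcome_terms=(),
                         shared_effects=(), levels=2, include_outcome=False)
        ds = load_dataset(*manual_tables(
            [8.0, 10.0, 12.0, 14.0], [98.0, 101.0, 103.0, 109.0]))
        design = build_design(ds, spec)
        S = np.diag([4.0, 0.25, 1e-12])
        S[0, 1] = S[1, 0] = -0.3
        p = _params(design, beta=(100.0, 2.0), alpha=(np.log(9.0),), Sigma=S)
        mine = marginal_loglik(design, p, quad_order=31)
        Z = np.column_stack([np.ones(4), design.z_age])
        cov = Z @ S[:2, :2] @ Z.T + 9.0 * np.eye(4)
        direct = multivariate_normal.logpdf(
            design.y, mean=design.X_mean @ p.beta, cov=cov
        )
        assert mine == pytest.approx(direct, rel=1e-6)

    def test_low_quadrature_order_warns(self, tiny_cohort):
        cfg, _, design, _ = tiny_cohort
        with pytest.warns(RuntimeWarning, match="unreliable"):
            marginal_loglik_bruteforce(design, cfg.true_params, quad_order=3)

    def test_fast_path_matches_reference(self, small_cohort):
        cfg, _, design, _ = small_cohort
        f = FastLoglik(design, quad_order=15)
        assert f.verify(cfg.true_params)
        # and at a deliberately extreme parameter point
        p = cfg.true_params
        extreme = Parameters(
            beta=p.beta, alpha=p.alpha, gamma=p.gamma,
            loadings=np.array([0.02, 0.8, 3.0]), Sigma_u=p.Sigma_u,
            sigma_u3=0.03, sigma_eps=p.sigma_eps,
        )
        assert f.verify(extreme, rtol=1e-7)


class TestParameterSerialization:
    def test_dict_roundtrip(self, tiny_cohort):
        cfg, _, _, _ = tiny_cohort
        p = cfg.true_params
        q = Parameters.from_dict(p.to_dict())
        assert np.allclose(q.beta, p.beta)
        assert np.allclose(q.Sigma_u, p.Sigma_u)
        assert q.sigma_eps == pytest.approx(p.sigma_eps)

    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_file_roundtrip(self, tiny_cohort, tmp_path, ext):
        cfg, _, _, _ = tiny_cohort
        p = cfg.true_params
        path = tmp_path / f"params.{ext}"
        p.save(path)
        q = Parameters.load(path)
        assert np.allclose(q.Sigma_u, p.Sigma_u)
        assert np.allclose(q.loadings, p.loadings)
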