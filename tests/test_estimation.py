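"""Sampler machinery: transform, priors, diagnostics, small-fit properties."""

import warnings

import numpy as np
import pytest

from melsjm import (
    FitConfig,
    GeneratorConfig,
    Parameters,
    build_design,
    convergence_report,
    fit_joint,
    marginal_loglik,
    simulate,
)
from melsjm.data_model import ModelSpec
from melsjm.estimation import ParameterTransform, _Posterior, fit_map
from melsjm.synthetic_data import model_a_params, model_a_spec


@pytest.fixture(scope="module")
def small_design():
    cfg = GeneratorConfig(n_individuals=120, spec=model_a_spec(),
                          true_params=model_a_params(), seed=77)
    ds, truth = simulate(cfg)
    return cfg, build_design(ds, cfg.spec), truth


@pytest.fixture(scope="module")
def small_fit(small_design):
    cfg, design, _ = small_design
    return fit_joint(design, FitConfig(seed=3, warmup_draws=2000,
                                       sampling_draws=4000))


class TestFitConfig:
    def test_single_chain_warns(self):
        with pytest.warns(UserWarning, match="R-hat"):
            FitConfig(chains=1)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(chains=0)
        with pytest.raises(ValueError):
            FitConfig(adapt_target=1.5)
        with pytest.raises(ValueError):
            FitConfig(sampling_draws=0)


class TestParameterTransform:
    def test_roundtrip_at_random_points(self, small_design):
        cfg, design, _ = small_design
        t = ParameterTransform(design, FitConfig(seed=0))
        rng = np.random.default_rng(8)
        for _ in range(10):
            sds = np.exp(rng.normal(np.log([6, 0.6, 0.4]), 0.4))
            r = np.tanh(rng.normal(0, 0.6, 3))
            r12 = r[2] * np.sqrt((1 - r[0]**2) * (1 - r[1]**2)) + r[0] * r[1]
            R = np.array([[1, r[0], r[1]], [r[0], 1, r12], [r[1], r12, 1.0]])
            p = Parameters(
                beta=rng.normal(0, 1, t.p_mean),
                alpha=rng.normal(0, 1, t.p_scale),
                gamma=rng.normal(0, 1, t.p_out),
                loadings=rng.normal(0, 0.2, 3),
                Sigma_u=R * np.outer(sds, sds),
                sigma_u3=float(np.exp(rng.normal(-1.6, 0.3))),
                sigma_eps=float(np.exp(rng.normal(1.7, 0.2))),
            )
            q = t.unpack(t.pack(p))
            assert np.allclose(q.beta, p.beta)
            assert np.allclose(q.loadings, p.loadings, atol=1e-10)
            assert np.allclose(q.Sigma_u, p.Sigma_u, atol=1e-10)
            assert q.sigma_eps == pytest.approx(p.sigma_eps)

    def test_log_prior_finite_and_decaying(self, small_design):
        cfg, design, _ = small_design
        t = ParameterTransform(design, FitConfig(seed=0))
        theta0 = t.pack(cfg.true_params)
        lp0 = t.log_prior(theta0)
        assert np.isfinite(lp0)
        far = theta0.copy()
        far[0] += 100 * t.beta_scale[0]
        assert t.log_prior(far) < lp0

    def test_structural_zero_u3(self, small_design):
        """The outcome residual never enters the random-effect covariance:
        no transform coordinate links sigma_u3 to Sigma_u."""
        cfg, design, _ = small_design
        t = ParameterTransform(design, FitConfig(seed=0))
        theta = t.pack(cfg.true_params)
        i_u3 = t.names.index("sigma_u3")
        bumped = theta.copy()
        bumped[i_u3] *= 2.0
        assert np.allclose(t.unpack(bumped).Sigma_u,
                           t.unpack(theta).Sigma_u)


class TestPosteriorEvaluation:
    def test_quadrature_order_invariance(self, small_design):
        cfg, design, _ = small_design
        a = marginal_loglik(design, cfg.true_params, quad_order=15)
        b = marginal_loglik(design, cfg.true_params, quad_order=31)
        assert a == pytest.approx(b, rel=1e-9)

    def test_invalid_region_returns_minus_inf(self, small_design):
        cfg, design, _ = small_design
        post = _Posterior(design, ParameterTransform(design, FitConfig(seed=0)),
                          FitConfig(seed=0))
        theta = post.transform.pack(cfg.true_params)
        theta[-1] = 0.0  # sigma_eps = 0
        assert post(theta) == -np.inf


class TestConvergenceReport:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            convergence_report({"x": np.zeros((1, 100))})

    def test_constant_chains_flagged_degenerate(self):
        draws = {"x": np.ones((2, 100)), "y": np.random.default_rng(0)
                 .normal(size=(2, 100))}
        with pytest.warns(UserWarning, match="degenerate"):
            rep = convergence_report(draws)
        assert "x" in rep["degenerate"]
        assert np.isnan(rep["rhat"]["x"])

    def test_seed_reproducibility(self, small_design):
        cfg, design, _ = small_design
        fc = FitConfig(seed=19, warmup_draws=50, sampling_draws=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_joint(design, fc)
            f2 = fit_joint(design, fc)
        assert np.array_equal(f1.theta_draws, f2.theta_draws)


class TestSmallFit:
    def test_mixing_and_convergence_flag(self, small_fit):
        assert small_fit.convergence["max_rhat"] < 1.3
        assert small_fit.convergence["min_ess"] > 5
        assert set(small_fit.convergence["rhat"]) == set(small_fit.draws)

    def test_posterior_concentrates_near_truth(self, small_design, small_fit):
        """Posterior means of well-identified parameters land within a few
        posterior SDs of the generating values."""
        cfg, design, _ = small_design
        truth = small_fit.transform.natural_values(cfg.true_params)
        for name in ("beta[intercept]", "beta[s2]", "alpha[intercept]",
                     "sigma_eps", "sd_u0"):
            row = small_fit.summary.loc[name]
            assert abs(row["mean"] - truth[name]) < 5 * row["sd"], name

    def test_all_sigma_draws_positive_definite(self, small_fit):
        d = small_fit.draws
        n_pd = 0
        total = 0
        for c in range(d["sd_u0"].shape[0]):
            for i in range(d["sd_u0"].shape[1]):
                sds = np.array([d["sd_u0"][c, i], d["sd_u1"][c, i],
                                d["sd_u2"][c, i]])
                R = np.array([
                    [1, d["corr_u0_u1"][c, i], d["corr_u0_u2"][c, i]],
                    [d["corr_u0_u1"][c, i], 1, d["corr_u1_u2"][c, i]],
                    [d["corr_u0_u2"][c, i], d["corr_u1_u2"][c, i], 1],
                ])
                S = R * np.outer(sds, sds)
                total += 1
                n_pd += int(np.all(np.linalg.eigvalsh(S) > 0))
        assert n_pd == total


class TestPosteriorContraction:
    def test_doubling_cohort_shrinks_fixed_effect_intervals(self):
        """Averaged over 5 replicate pairs, the 95% CrI of every fixed
        effect is narrower at J=200 than at J=100."""
        fc = FitConfig(seed=1, warmup_draws=1000, sampling_draws=2000)
        widths = {100: {}, 200: {}}
        ss = np.random.SeedSequence(555)
        for child in ss.spawn(5):
            seed = int(child.generate_state(1)[0] % (2**31 - 1))
            for J in (100, 200):
                cfg = GeneratorConfig(n_individuals=J, spec=model_a_spec(),
                                      true_params=model_a_params(),
                                      seed=seed)
                ds, _ = simulate(cfg)
                fit = fit_joint(build_design(ds, cfg.spec), fc)
                s = fit.summary
                for name in s.index:
                    if name.startswith(("beta[", "alpha[", "gamma[")):
                        w = s.loc[name, "q97.5"] - s.loc[name, "q2.5"]
                        widths[J].setdefault(name, []).append(w)
        for name in widths[100]:
            assert np.mean(widths[200][name]) < np.mean(widths[100][name]), name


class TestSharedEffectVariants:
    def test_variant_table_aligns_loadings(self, small_design):
        from melsjm import fit_variants

        cfg, design, _ = small_design
        fc = FitConfig(seed=2, warmup_draws=400, sampling_draws=600)
        fits, table = fit_variants(
            design,
            {
                "location_only": ("location",),
                "log_scale_only": ("log_scale",),
                "all": ("location", "slope", "log_scale"),
            },
            fc,
        )
        assert list(table.index) == [
            "gamma_location", "gamma_slope", "gamma_log_scale",
        ]
        assert not np.isnan(table.loc["gamma_location", "all_mean"])
        assert np.isnan(table.loc["gamma_slope", "location_only_mean"])
        # same shared set + same seed reproduces the same summary
        fits2, table2 = fit_variants(design, {"all": ("location", "slope",
                                                      "log_scale")}, fc)
        assert table2.loc["gamma_location", "all_mean"] == pytest.approx(
            table.loc["gamma_location", "all_mean"])

    def test_single_effect_fit_distorted_by_correlated_effects(self):
        """When the location and log-scale effects are positively
        correlated and truly affect the outcome with opposite signs,
        entering the log-scale effect alone flips the sign of its
        estimated loading relative to the all-included fit."""
        from dataclasses import replace

        p = model_a_params()
        loadings = np.array([0.02, 0.04, -0.08])  # strong +u0, negative u2
        p2 = Parameters(beta=p.beta, alpha=p.alpha, gamma=p.gamma,
                        loadings=loadings, Sigma_u=p.Sigma_u,
                        sigma_u3=0.15, sigma_eps=p.sigma_eps)
        cfg = GeneratorConfig(n_individuals=800, spec=model_a_spec(),
                              true_params=p2, seed=91)
        ds, _ = simulate(cfg)
        spec_all = cfg.spec
        spec_u2 = replace(spec_all, shared_effects=("log_scale",))
        d_all = build_design(ds, spec_all)
        d_u2 = build_design(ds, spec_u2)
        fc = FitConfig(seed=6)
        g_all, _, _ = fit_map(d_all, fc)
        g_u2, _, _ = fit_map(d_u2, fc)
        full = g_all.full_loadings(spec_all)[2]
        alone = g_u2.full_loadings(spec_u2)[2]
        assert full < 0
        assert alone > 0  # confounded through the positive u0-u2 correlation


class TestWellMixedFit:
    def test_location_scale_fit_passes_rhat_threshold(self):
        """A location-scale-only fit at J=150 mixes cleanly: split R-hat
        at or below 1.05 for every sampled quantity."""
        from dataclasses import replace

        p = model_a_params()
        spec = replace(model_a_spec(), shared_effects=(),
                       include_outcome=False, outcome_terms=())
        p0 = Parameters(beta=p.beta, alpha=p.alpha, gamma=np.array([0.0]),
                        loadings=np.zeros(0), Sigma_u=p.Sigma_u,
                        sigma_u3=1.0, sigma_eps=p.sigma_eps)
        cfg = GeneratorConfig(n_individuals=150, spec=spec,
                              true_params=p0, seed=42)
        ds, _ = simulate(cfg)
        design = build_design(ds, spec)
        fit = fit_joint(design, FitConfig(seed=4, warmup_draws=2500,
                                          sampling_draws=6000))
        assert fit.convergence["max_rhat"] <= 1.05
        assert fit.convergence["passed"]


class TestFactorization:
    def test_empty_shared_effects_decouple_outcome(self):
        """With no shared effects the longitudinal posterior matches a
        longitudinal-only fit within combined Monte-Carlo error."""
        p = model_a_params()
        spec0 = ModelSpec(
            mean_terms=model_a_spec().mean_terms,
            scale_terms=model_a_spec().scale_terms,
            outcome_terms=model_a_spec().outcome_terms,
            shared_effects=(),
        )
        p0 = Parameters(beta=p.beta, alpha=p.alpha, gamma=p.gamma,
                        loadings=np.zeros(0), Sigma_u=p.Sigma_u,
                        sigma_u3=p.sigma_u3, sigma_eps=p.sigma_eps)
        cfg = GeneratorConfig(n_individuals=100, spec=spec0,
                              true_params=p0, seed=13)
        ds, _ = simulate(cfg)
        design_joint = build_design(ds, spec0)
        from dataclasses import replace
        spec_long = replace(spec0, include_outcome=False, outcome_terms=())
        design_long = build_design(ds, spec_long)
        fc = FitConfig(seed=5, warmup_draws=1500, sampling_draws=3000)
        fit_j = fit_joint(design_joint, fc)
        fit_l = fit_joint(design_long, fc)
        for name in ("beta[intercept]", "alpha[intercept]", "sd_u0",
                     "sd_u2", "sigma_eps"):
            a, b = fit_j.summary.loc[name], fit_l.summary.loc[name]
            mc_se = np.sqrt(a["sd"]**2 / max(a["ess"], 4)
                            + b["sd"]**2 / max(b["ess"], 4))
            assert abs(a["mean"] - b["mean"]) < 4 * mc_se + 0.02 * a["sd"], name
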