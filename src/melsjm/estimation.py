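"""Bayesian estimation of the joint location-scale model.

The sampler works on the *marginal* posterior of the fixed parameters:
random effects are integrated out of the likelihood exactly
(:func:`melsjm.model_core.marginal_loglik`), so the target has a few dozen
dimensions regardless of cohort size and is close to Gaussian at realistic
sample sizes.  Fitting proceeds in three stages:

1. posterior mode (MAP) by quasi-Newton optimization on a well-behaved
   reparameterization (direct-scale SDs through absolute values, atanh
   partial correlations, loadings as the regression on whitened active
   random effects);
2. a Laplace (finite-difference Hessian) approximation at the mode, used
   to precondition the sampler;
3. adaptive preconditioned random-walk Metropolis chains whose proposal
   covariance and step size adapt during warmup and then freeze, so the
   sampling phase is a valid fixed-kernel MCMC.

Priors are weakly informative: zero-centered normals on regression
coefficients with scales from the data's empirical SDs, half-normals on
all SDs, and a uniform-over-correlations (LKJ, shape 1) prior on the
(u0, u1, u2) correlation matrix expressed through partial correlations.
The outcome residual u3 never enters the random-effect covariance — the
structural zeros are enforced by the parameterization itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data_model import DesignMatrices, ModelSpec, SHARED_EFFECTS
from .model_core import CollapsedData, Parameters, collapse

__all__ = [
    "FitConfig",
    "JointFit",
    "ParameterTransform",
    "fit_joint",
    "fit_map",
    "fit_variants",
    "convergence_report",
    "posterior_ranks",
    "coverage_indicators",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    ``warmup_draws`` are discarded (step-size adaptation happens there);
    ``sampling_draws`` are kept per chain.  ``adapt_target`` is the target
    Metropolis acceptance rate.  ``quad_order`` controls the Gauss–Hermite
    order of the u2 integral inside every likelihood evaluation.
    """

    chains: int = 2
    warmup_draws: int = 3000
    sampling_draws: int = 6000
    seed: int = 0
    adapt_target: float = 0.25
    quad_order: int = 9
    map_maxiter: int = 600
    init_jitter: float = 1.0
    prior_scale_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.chains == 1:
            warnings.warn(
                "single-chain runs cannot produce a reliable R-hat",
                UserWarning,
                stacklevel=2,
            )
        if self.sampling_draws <= 0 or self.warmup_draws < 0:
            raise ValueError("draw counts must be positive")
        if not 0.0 < self.adapt_target < 1.0:
            raise ValueError("adapt_target must be in (0, 1)")


# ---------------------------------------------------------------------------
# unconstrained parameterization and priors
# ---------------------------------------------------------------------------

# LKJ(eta=1) on a 3x3 correlation matrix via the partial-correlation vine:
# the two direct correlations carry Beta(1.5, 1.5)-on-(-1,1) densities, the
# conditional one Beta(1, 1); with z = atanh(rho) the tanh Jacobian merges
# into exponents (b) below.
_LKJ_B = np.array([1.5, 1.5, 1.0])


class ParameterTransform:
    """Maps between :class:`Parameters` and an unconstrained vector."""

    def __init__(self, design: DesignMatrices, config: FitConfig):
        spec = design.spec
        self.spec = spec
        self.p_mean = design.X_mean.shape[1]
        self.p_scale = design.X_scale.shape[1]
        self.p_out = design.X_outcome.shape[1]
        self.n_load = spec.n_loadings
        self.levels = spec.levels
        self.dim = (
            self.p_mean + self.p_scale + self.p_out + self.n_load
            + 3 + 3 + 1 + (1 if self.levels == 3 else 0)
        )
        load_names = [f"gamma_{e}" for e in SHARED_EFFECTS if e in spec.shared_effects]
        self.names = (
            [f"beta[{n}]" for n in design.mean_names]
            + [f"alpha[{n}]" for n in design.scale_names]
            + [f"gamma[{n}]" for n in design.outcome_names]
            + load_names
            + ["sd_u0", "sd_u1", "sd_u2",
               "corr_u0_u1", "corr_u0_u2", "corr_u1_u2",
               "sigma_u3"]
            + (["sigma_eps"] if self.levels == 3 else [])
        )
        self._prior_scales(design, config)

    # -- prior scales from empirical SDs ------------------------------------
    def _prior_scales(self, design: DesignMatrices, config: FitConfig) -> None:
        m = config.prior_scale_multiplier
        w = design.n_pooled
        nv = np.bincount(design.measurement_visit, weights=w,
                         minlength=design.n_visits)
        ybar = np.bincount(design.measurement_visit, weights=w * design.y,
                           minlength=design.n_visits) / nv
        sd_y = float(np.std(ybar)) or 1.0
        loc_y = max(sd_y, float(np.abs(np.mean(ybar))))
        sd_z = float(np.std(design.z_age)) or 1.0

        def col_sds(X):
            s = np.std(X, axis=0)
            s[s == 0] = 1.0  # intercept column
            return s

        self.beta_scale = m * sd_y / col_sds(design.X_mean)
        self.beta_scale[0] = m * loc_y
        self.alpha_scale = m / col_sds(design.X_scale)
        self.alpha_scale[0] = m

        if design.outcome_observed.any():
            y2 = design.y2[design.outcome_observed]
            sd_y2 = float(np.std(y2)) or 1.0
            loc_y2 = max(sd_y2, float(np.abs(np.mean(y2))))
        else:
            sd_y2, loc_y2 = 1.0, 1.0
        self.gamma_scale = m * sd_y2 / col_sds(design.X_outcome)
        self.gamma_scale[0] = m * loc_y2
        # loadings are sampled as the outcome regression on *whitened*
        # active random effects (kappa = L_A' lambda_A, with L_A the
        # Cholesky factor of the active block of Sigma_u): this removes
        # both the loading-vs-SD funnel and the loading-vs-correlation
        # ridge, because the data inform kappa directly
        self.load_scale = np.full(self.n_load, m * sd_y2)
        self._active_idx = np.array([
            k for k, e in enumerate(SHARED_EFFECTS)
            if e in self.spec.shared_effects
        ], dtype=int)
        half = m / 2.0
        self.sd_scales = np.array([half * sd_y, half * sd_y / sd_z, half])
        self.sigma_u3_scale = half * sd_y2
        self.sigma_eps_scale = half * sd_y

    # -- packing -------------------------------------------------------------
    def _split(self, theta: np.ndarray):
        i = 0
        parts = []
        for n in (self.p_mean, self.p_scale, self.p_out, self.n_load, 3, 3, 1):
            parts.append(theta[i:i + n])
            i += n
        log_eps = theta[i:i + 1] if self.levels == 3 else None
        return (*parts, log_eps)

    @staticmethod
    def _corr_from_partials(p: np.ndarray) -> tuple[float, float, float]:
        r01, r02 = p[0], p[1]
        r12 = p[2] * np.sqrt((1 - r01**2) * (1 - r02**2)) + r01 * r02
        return float(r01), float(r02), float(r12)

    def _active_chol(self, Sigma: np.ndarray) -> np.ndarray:
        idx = self._active_idx
        return np.linalg.cholesky(Sigma[np.ix_(idx, idx)])

    def unpack(self, theta: np.ndarray) -> Parameters:
        beta, alpha, gamma, kappa, raw_sd, z, raw_u3, raw_eps = self._split(theta)
        sds = np.abs(raw_sd)
        r01, r02, r12 = self._corr_from_partials(np.tanh(z))
        R = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
        Sigma = R * np.outer(sds, sds)
        if self.n_load:
            L = self._active_chol(Sigma)
            load = np.linalg.solve(L.T, kappa)
        else:
            load = kappa
        return Parameters(
            beta=beta.copy(),
            alpha=alpha.copy(),
            gamma=gamma.copy(),
            loadings=load.copy(),
            Sigma_u=R * np.outer(sds, sds),
            sigma_u3=float(np.abs(raw_u3[0])),
            sigma_eps=float(np.abs(raw_eps[0])) if raw_eps is not None else None,
        )

    def pack(self, params: Parameters) -> np.ndarray:
        sds = np.sqrt(np.diag(params.Sigma_u))
        R = params.Sigma_u / np.outer(sds, sds)
        r01, r02, r12 = R[0, 1], R[0, 2], R[1, 2]
        p3 = (r12 - r01 * r02) / np.sqrt((1 - r01**2) * (1 - r02**2))
        z = np.arctanh(np.clip([r01, r02, p3], -0.999999, 0.999999))
        kappa = self._active_chol(params.Sigma_u).T @ params.loadings \
            if self.n_load else params.loadings
        parts = [
            params.beta, params.alpha, params.gamma, kappa,
            sds, z, [params.sigma_u3],
        ]
        if self.levels == 3:
            parts.append([params.sigma_eps])
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    # -- prior ---------------------------------------------------------------
    def log_prior(self, theta: np.ndarray) -> float:
        beta, alpha, gamma, load, raw_sd, z, raw_u3, raw_eps = self._split(theta)
        lp = 0.0
        lp -= 0.5 * np.sum((beta / self.beta_scale) ** 2)
        lp -= 0.5 * np.sum((alpha / self.alpha_scale) ** 2)
        lp -= 0.5 * np.sum((gamma / self.gamma_scale) ** 2)
        if self.n_load:
            lp -= 0.5 * np.sum((load / self.load_scale) ** 2)
        # SDs are sampled on the direct scale through |.| (reflection at
        # zero), so the half-normal prior needs no Jacobian term and the
        # near-zero region stays compact instead of an infinite log tail
        lp -= 0.5 * np.sum((raw_sd / self.sd_scales) ** 2)
        lp -= 0.5 * (raw_u3[0] / self.sigma_u3_scale) ** 2
        if raw_eps is not None:
            lp -= 0.5 * (raw_eps[0] / self.sigma_eps_scale) ** 2
        # LKJ(1) through partial correlations (tanh Jacobian absorbed)
        rho = np.tanh(z)
        lp += float(np.sum(_LKJ_B * np.log1p(-rho**2)))
        return float(lp)

    def bounds(self):
        """Box bounds for the optimizer (SDs positive, tanh well-conditioned)."""
        lo = np.full(self.dim, -np.inf)
        hi = np.full(self.dim, np.inf)
        i = self.p_mean + self.p_scale + self.p_out + self.n_load
        lo[i:i + 3] = 1e-6                            # sds (direct scale)
        lo[i + 3:i + 6], hi[i + 3:i + 6] = -6.0, 6.0  # atanh partials
        lo[i + 6:] = 1e-6                             # sigma_u3 / sigma_eps
        return list(zip(lo, hi))

    def natural_values(self, params: Parameters) -> dict:
        """Named natural-scale values aligned with :attr:`names`."""
        sds = np.sqrt(np.diag(params.Sigma_u))
        R = params.Sigma_u / np.outer(sds, sds)
        vals = np.concatenate([
            params.beta, params.alpha, params.gamma, params.loadings,
            sds, [R[0, 1], R[0, 2], R[1, 2]], [params.sigma_u3],
            [params.sigma_eps] if self.levels == 3 else [],
        ])
        return dict(zip(self.names, vals.tolist()))

    def natural_from_theta(self, theta: np.ndarray) -> np.ndarray:
        """Natural-scale vector (ordering of :attr:`names`) from theta."""
        p = self.unpack(theta)
        return np.array(list(self.natural_values(p).values()))


# ---------------------------------------------------------------------------
# posterior, MAP, Laplace
# ---------------------------------------------------------------------------


class _Posterior:
    def __init__(self, design: DesignMatrices, transform: ParameterTransform,
                 config: FitConfig):
        self.design = design
        self.transform = transform
        self.quad_order = config.quad_order
        self.collapsed: CollapsedData = collapse(design)
        from ._speed import FastLoglik

        self._loglik = FastLoglik(design, config.quad_order, self.collapsed)
        self.n_evals = 0

    def __call__(self, theta: np.ndarray) -> float:
        self.n_evals += 1
        try:
            params = self.transform.unpack(theta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ll = self._loglik(params)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return -np.inf
        lp = ll + self.transform.log_prior(theta)
        # a log posterior beyond any attainable magnitude signals numerical
        # breakdown rather than a good fit; treat it as invalid
        if not np.isfinite(lp) or lp > 1e10:
            return -np.inf
        return lp


def _initial_theta(design: DesignMatrices, transform: ParameterTransform) -> np.ndarray:
    """Method-of-moments starting values from per-individual least squares."""
    w = design.n_pooled
    mv = design.measurement_visit
    nv = np.bincount(mv, weights=w, minlength=design.n_visits)
    ybar = np.bincount(mv, weights=w * design.y, minlength=design.n_visits) / nv
    beta, *_ = np.linalg.lstsq(design.X_mean, ybar, rcond=None)
    resid = ybar - design.X_mean @ beta

    vi = design.visit_individual
    J = design.n_individuals
    ints, slopes, logvars = [], [], []
    for j in range(J):
        rows = np.where(vi == j)[0]
        if len(rows) < 3:
            continue
        z = design.z_age[rows]
        r = resid[rows]
        A = np.column_stack([np.ones(len(rows)), z])
        coef, res_ss, *_ = np.linalg.lstsq(A, r, rcond=None)
        ints.append(coef[0])
        slopes.append(coef[1])
        ss = float(res_ss[0]) if len(res_ss) else float(np.sum((r - A @ coef) ** 2))
        logvars.append(np.log(max(ss / max(len(rows) - 2, 1), 1e-8)))
    sd_u0 = max(float(np.std(ints)) if ints else 1.0, 1e-2)
    sd_u1 = max(float(np.std(slopes)) if slopes else 0.3, 1e-2)
    mean_lv = float(np.mean(logvars)) if logvars else 0.0

    if design.spec.levels == 3:
        c = collapse(design)
        sigma_eps = float(np.sqrt(c.sum_ss / c.n_excess)) if c.n_excess > 0 \
            else 0.3 * max(float(np.std(design.y)), 1.0)
        sigma_eps = max(sigma_eps, 1e-2)
    else:
        sigma_eps = None

    alpha = np.zeros(design.X_scale.shape[1])
    alpha[0] = mean_lv

    # outcome regression
    gamma = np.zeros(design.X_outcome.shape[1])
    sigma_u3 = 1.0
    om = design.outcome_observed & design.spec.include_outcome
    if om.any():
        Xo = design.X_outcome[om]
        yo = design.y2[om]
        gamma, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
        sigma_u3 = max(float(np.std(yo - Xo @ gamma)), 1e-3)

    sds = np.array([sd_u0, sd_u1, 0.5])
    params = Parameters(
        beta=beta,
        alpha=alpha,
        gamma=gamma,
        loadings=np.zeros(transform.n_load),
        Sigma_u=np.diag(sds**2),
        sigma_u3=sigma_u3,
        sigma_eps=sigma_eps,
    )
    return transform.pack(params)


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    d = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    H = np.zeros((d, d))
    f0 = f(theta)

    def fp(i, s_i, j=None, s_j=0.0):
        t = theta.copy()
        t[i] += s_i
        if j is not None:
            t[j] += s_j
        return f(t)

    for i in range(d):
        H[i, i] = (fp(i, h[i]) - 2 * f0 + fp(i, -h[i])) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            v = (
                fp(i, h[i], j, h[j]) - fp(i, h[i], j, -h[j])
                - fp(i, -h[i], j, h[j]) + fp(i, -h[i], j, -h[j])
            ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = v
    return H


def _laplace_covariance(post, theta_map: np.ndarray) -> np.ndarray:
    H = _numerical_hessian(lambda t: -post(t), theta_map)
    H = 0.5 * (H + H.T)
    eigval, eigvec = np.linalg.eigh(H)
    floor = max(np.max(eigval), 1.0) * 1e-8
    eigval = np.clip(eigval, floor, None)
    return (eigvec / eigval) @ eigvec.T


def fit_map(design: DesignMatrices, config: FitConfig | None = None):
    """Posterior mode of the marginal posterior (point estimate).

    Returns ``(params, theta, posterior)`` — the mode as
    :class:`Parameters`, its unconstrained vector, and the posterior
    callable (which caches the collapsed data for reuse).
    """
    config = config or FitConfig()
    transform = ParameterTransform(design, config)
    post = _Posterior(design, transform, config)
    theta0 = _initial_theta(design, transform)
    res = minimize(
        lambda t: -post(t),
        theta0,
        method="L-BFGS-B",
        bounds=transform.bounds(),
        options={"maxiter": config.map_maxiter, "maxfun": 10 * config.map_maxiter},
    )
    theta_map = res.x
    return transform.unpack(theta_map), theta_map, post


@dataclass
class JointFit:
    """Posterior draws plus summaries for one model fit."""

    draws: dict                     # name -> (chains, draws) natural scale
    summary: pd.DataFrame
    convergence: dict
    config: FitConfig
    transform: ParameterTransform
    theta_map: np.ndarray
    map_params: Parameters
    laplace_cov: np.ndarray
    theta_draws: np.ndarray         # (chains, draws, dim) unconstrained
    spec: ModelSpec = None

    def posterior_params(self) -> Parameters:
        """Posterior-mean parameters (natural scale, matrix re-assembled)."""
        means = {k: float(np.mean(v)) for k, v in self.draws.items()}
        t = self.transform
        sds = np.array([means["sd_u0"], means["sd_u1"], means["sd_u2"]])
        r01, r02, r12 = (means["corr_u0_u1"], means["corr_u0_u2"],
                         means["corr_u1_u2"])
        R = np.array([[1, r01, r02], [r01, 1, r12], [r02, r12, 1.0]])
        names = t.names
        beta = [means[n] for n in names if n.startswith("beta[")]
        alpha = [means[n] for n in names if n.startswith("alpha[")]
        gamma = [means[n] for n in names if n.startswith("gamma[")]
        load = [means[n] for n in names if n.startswith("gamma_")]
        return Parameters(
            beta=np.array(beta), alpha=np.array(alpha), gamma=np.array(gamma),
            loadings=np.array(load), Sigma_u=R * np.outer(sds, sds),
            sigma_u3=means["sigma_u3"],
            sigma_eps=means.get("sigma_eps"),
        )


def _run_chain(post, theta0, prop_chol, n_warmup, n_draws, target, rng,
               coord_idx=(), coord_every=10):
    """Adaptive preconditioned random-walk Metropolis.

    During warmup the global step size follows a Robbins–Monro recursion
    towards the target acceptance rate, and the proposal covariance is
    periodically blended with the empirical covariance of the chain's own
    history; both are frozen for the sampling phase, which is therefore a
    fixed-kernel chain.  Every ``coord_every`` iterations the heavy-tailed
    coordinates in ``coord_idx`` (variance, correlation and loading
    parameters) additionally get single-coordinate Metropolis updates,
    which traverse their skewed marginals much faster than joint moves.
    """
    d = len(theta0)
    theta = theta0.copy()
    lp = post(theta)
    draws = np.empty((n_draws, d))
    history = np.empty((n_warmup, d))
    accepted = 0
    log_lam = 0.0
    base_cov = prop_chol @ prop_chol.T
    chol = prop_chol
    coord_sd = np.sqrt(np.diag(base_cov))
    coord_log_lam = np.zeros(len(coord_idx))
    refresh = max(250, n_warmup // 5)
    for it in range(n_warmup + n_draws):
        prop = theta + np.exp(log_lam) * (chol @ rng.standard_normal(d))
        lp_prop = post(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            theta, lp = prop, lp_prop
        if len(coord_idx) and it % coord_every == 0:
            for k, i in enumerate(coord_idx):
                prop = theta.copy()
                prop[i] += 2.4 * np.exp(coord_log_lam[k]) * coord_sd[i] \
                    * rng.standard_normal()
                lp_prop = post(prop)
                ok = np.log(rng.random()) < lp_prop - lp
                if ok:
                    theta, lp = prop, lp_prop
                if it < n_warmup:
                    coord_log_lam[k] += (
                        (1.0 if ok else 0.0) - 0.44
                    ) / (1.0 + it / coord_every) ** 0.6
        if it < n_warmup:
            history[it] = theta
            rate = 1.0 / (1.0 + it) ** 0.6
            log_lam += rate * ((1.0 if accept else 0.0) - target)
            if it >= 2 * refresh and (it + 1) % refresh == 0:
                seg = history[it // 2:it + 1]
                emp = np.cov(seg.T)
                blend = 0.5 * emp + 0.5 * base_cov
                blend += np.eye(d) * (1e-10 + 1e-8 * np.trace(blend) / d)
                try:
                    chol = np.linalg.cholesky(blend * (2.38**2 / d))
                    coord_sd = np.sqrt(np.diag(blend))
                except np.linalg.LinAlgError:
                    pass
        else:
            draws[it - n_warmup] = theta
            accepted += int(accept)
    return draws, accepted / max(n_draws, 1)


def fit_joint(design: DesignMatrices, config: FitConfig | None = None) -> JointFit:
    """Fit the joint model by marginal-posterior MCMC.

    Runs MAP + Laplace preconditioning, then ``config.chains`` adaptive
    Metropolis chains.  Identical design + config (including seed) gives
    identical draws.  A non-converged run (max R-hat above 1.05) completes
    and is flagged in ``convergence['passed']``.
    """
    config = config or FitConfig()
    if design.n_individuals == 0:
        raise ValueError("empty dataset")
    map_params, theta_map, post = fit_map(design, config)
    transform = post.transform
    cov = _laplace_covariance(post, theta_map)
    d = transform.dim
    prop_chol = np.linalg.cholesky(cov * (2.38**2 / d)
                                   + np.eye(d) * 1e-12)

    ss = np.random.SeedSequence(config.seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(config.chains)]
    theta_draws = np.empty((config.chains, config.sampling_draws, d))
    acc_rates = []
    for c, rng in enumerate(chain_rngs):
        jitter = config.init_jitter * (prop_chol @ rng.standard_normal(d))
        start = theta_map + jitter
        if not np.isfinite(post(start)):
            start = theta_map
        draws_c, acc = _run_chain(
            post, start, prop_chol, config.warmup_draws,
            config.sampling_draws, config.adapt_target, rng,
            coord_idx=tuple(range(transform.dim)), coord_every=15,
        )
        theta_draws[c] = draws_c
        acc_rates.append(acc)

    # natural-scale draws per named quantity
    flat = theta_draws.reshape(-1, d)
    nat = np.empty((flat.shape[0], len(transform.names)))
    for i, th in enumerate(flat):
        nat[i] = transform.natural_from_theta(th)
    nat = nat.reshape(config.chains, config.sampling_draws, -1)
    draws = {name: nat[:, :, k] for k, name in enumerate(transform.names)}

    convergence = convergence_report(draws, acc_rates)
    summary = _summarize(draws, convergence)
    return JointFit(
        draws=draws,
        summary=summary,
        convergence=convergence,
        config=config,
        transform=transform,
        theta_map=theta_map,
        map_params=map_params,
        laplace_cov=cov,
        theta_draws=theta_draws,
        spec=design.spec,
    )


def _summarize(draws: dict, convergence: dict) -> pd.DataFrame:
    rows = []
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        rows.append({
            "parameter": name,
            "mean": float(np.mean(flat)),
            "sd": float(np.std(flat, ddof=1)),
            "q2.5": float(np.percentile(flat, 2.5)),
            "q97.5": float(np.percentile(flat, 97.5)),
            "rhat": convergence["rhat"].get(name, np.nan),
            "ess": convergence["ess"].get(name, np.nan),
        })
    return pd.DataFrame(rows).set_index("parameter")


def convergence_report(draws: dict, acceptance_rates: Sequence[float] = ()) -> dict:
    """Split-R-hat and ESS per quantity, with a pass/fail flag.

    Requires at least two chains.  Quantities that are constant across all
    chains (degenerate) get NaN diagnostics and are flagged.
    """
    first = next(iter(draws.values()))
    if first.ndim != 2 or first.shape[0] < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    rhat, ess, degenerate = {}, {}, []
    for name, arr in draws.items():
        if np.ptp(arr) == 0.0:
            rhat[name] = np.nan
            ess[name] = np.nan
            degenerate.append(name)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = az.convert_to_dataset(np.asarray(arr))
            rhat[name] = float(az.rhat(data)["x"].values)
            ess[name] = float(az.ess(data)["x"].values)
    finite = [v for v in rhat.values() if np.isfinite(v)]
    max_rhat = float(np.max(finite)) if finite else np.nan
    min_ess = float(np.min([v for v in ess.values() if np.isfinite(v)])) \
        if finite else np.nan
    if degenerate:
        warnings.warn(
            f"degenerate (constant) sampled quantities: {degenerate}",
            UserWarning,
            stacklevel=2,
        )
    return {
        "rhat": rhat,
        "ess": ess,
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "degenerate": degenerate,
        "acceptance_rates": list(acceptance_rates),
        "divergences": 0,  # not applicable to a random-walk kernel
        "sampler": "laplace-preconditioned adaptive metropolis",
        "passed": bool(np.isfinite(max_rhat) and max_rhat <= RHAT_THRESHOLD),
    }


def fit_variants(
    design: DesignMatrices,
    variants: dict[str, tuple[str, ...]],
    config: FitConfig | None = None,
):
    """Fit one model per shared-effect subset and align the loadings.

    ``variants`` maps a label to a ``shared_effects`` tuple, e.g.
    ``{"location_only": ("location",), "all": ("location", "slope",
    "log_scale")}``.  Returns ``(fits, table)`` where the table has one row
    per loading and one column pair per variant.
    """
    config = config or FitConfig()
    fits: dict[str, JointFit] = {}
    for label, shared in variants.items():
        spec_v = replace(design.spec, shared_effects=tuple(shared))
        design_v = replace(design, spec=spec_v)
        fits[label] = fit_joint(design_v, config)
    rows = []
    for effect in SHARED_EFFECTS:
        row = {"loading": f"gamma_{effect}"}
        for label, fit in fits.items():
            name = f"gamma_{effect}"
            if name in fit.draws:
                s = fit.summary.loc[name]
                row[f"{label}_mean"] = s["mean"]
                row[f"{label}_q2.5"] = s["q2.5"]
                row[f"{label}_q97.5"] = s["q97.5"]
            else:
                row[f"{label}_mean"] = np.nan
                row[f"{label}_q2.5"] = np.nan
                row[f"{label}_q97.5"] = np.nan
        rows.append(row)
    return fits, pd.DataFrame(rows).set_index("loading")


# ---------------------------------------------------------------------------
# calibration utilities
# ---------------------------------------------------------------------------


def posterior_ranks(fit: JointFit, true_params: Parameters, thin: int = 5) -> dict:
    """Rank of each true value among thinned posterior draws (for SBC)."""
    truth = fit.transform.natural_values(true_params)
    ranks = {}
    for name, arr in fit.draws.items():
        flat = arr.reshape(-1)[::thin]
        ranks[name] = (int(np.sum(flat < truth[name])), len(flat))
    return ranks


def coverage_indicators(fit: JointFit, true_params: Parameters) -> dict:
    """Whether each true value lies inside its central 95% interval."""
    truth = fit.transform.natural_values(true_params)
    out = {}
    for name, arr in fit.draws.items():
        lo, hi = np.percentile(arr.reshape(-1), [2.5, 97.5])
        out[name] = bool(lo <= truth[name] <= hi)
    return out
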