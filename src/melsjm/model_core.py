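"""Probability model for the joint mixed-effects location-scale model.

The model links three layers:

* a longitudinal exposure ``y1[h,i,j]`` (reading h, clinic visit i,
  individual j) with mean ``X_mean @ beta + u0j + u1j * z_age`` and a
  visit-level error ``e_ij ~ N(0, sigma2_e_ij)`` plus (three-level form) a
  within-clinic error ``eps ~ N(0, sigma_eps^2)``;
* a log-linear within-individual variance ``log sigma2_e_ij =
  X_scale @ alpha + u2j`` — the "scale" part of the location-scale model;
* a distal outcome ``y2_j = X_outcome @ gamma + gamma1*u0j + gamma2*u1j +
  gamma3*u2j + u3j`` sharing the individual random effects.

``(u0, u1, u2) ~ MVN(0, Sigma_u)`` with ``u3`` independent by construction
(the outcome residual never enters ``Sigma_u``).

The marginal likelihood integrates the random effects out: ``(u0, u1)``
analytically (they enter linearly in a Gaussian model once ``u2`` is
fixed), ``u2`` by one-dimensional Gauss–Hermite quadrature.  Visit-level
errors ``e_ij`` are never sampled: each visit's reading vector is
multivariate normal with a compound-symmetry covariance
``sigma2_e_ij * J + sigma_eps^2 * diag(1/n_pooled)``.

A brute-force three-dimensional quadrature oracle and a Monte-Carlo oracle
are provided for testing; they share no integration machinery with the
production path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

from .data_model import DesignMatrices, ModelSpec, SHARED_EFFECTS

__all__ = [
    "Parameters",
    "RandomEffects",
    "ScaleValue",
    "DefinitenessError",
    "implied_correlations",
    "mean_predictor",
    "log_within_variance",
    "outcome_predictor",
    "complete_data_logdensity",
    "marginal_loglik",
    "marginal_loglik_bruteforce",
    "marginal_loglik_montecarlo",
    "CollapsedData",
    "collapse",
]

LOGVAR_CLIP = 30.0
_LOG2PI = float(np.log(2.0 * np.pi))


class DefinitenessError(ValueError):
    """A covariance matrix that must be positive definite is not."""


def _check_pd(Sigma: np.ndarray, name: str = "Sigma_u") -> np.ndarray:
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (3, 3) or not np.allclose(Sigma, Sigma.T, atol=1e-12):
        raise DefinitenessError(f"{name} must be symmetric 3x3")
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as err:
        raise DefinitenessError(f"{name} is not positive definite") from err
    return Sigma


@dataclass
class Parameters:
    """Model parameters.

    ``beta``, ``alpha`` and ``gamma`` include their intercepts as the first
    entry (aligned with the design matrices).  ``loadings`` holds the
    shared-effect coefficients (gamma1, gamma2, gamma3) for the *active*
    shared effects, in canonical (location, slope, log_scale) order.
    ``sigma_u3`` is the outcome residual SD and ``sigma_eps`` the
    within-clinic SD (three-level model only; may be None for two-level).
    """

    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    loadings: np.ndarray
    Sigma_u: np.ndarray
    sigma_u3: float
    sigma_eps: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.loadings = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        self.Sigma_u = _check_pd(self.Sigma_u)
        if not self.sigma_u3 > 0:
            raise ValueError("sigma_u3 must be positive")
        if self.sigma_eps is not None and not self.sigma_eps > 0:
            raise ValueError("sigma_eps must be positive when present")

    def validate_against(self, design: DesignMatrices) -> None:
        spec = design.spec
        checks = [
            (self.beta, design.X_mean.shape[1], "beta"),
            (self.alpha, design.X_scale.shape[1], "alpha"),
            (self.gamma, design.X_outcome.shape[1], "gamma"),
            (self.loadings, spec.n_loadings, "loadings"),
        ]
        for vec, expected, name in checks:
            if vec.shape != (expected,):
                raise ValueError(
                    f"{name} has length {vec.shape[0]}, expected {expected}"
                )
        if spec.levels == 3 and self.sigma_eps is None:
            raise ValueError("three-level model requires sigma_eps")

    def full_loadings(self, spec: ModelSpec) -> np.ndarray:
        """(gamma1, gamma2, gamma3) with zeros for inactive shared effects."""
        g = np.zeros(3)
        k = 0
        for pos, name in enumerate(SHARED_EFFECTS):
            if name in spec.shared_effects:
                g[pos] = self.loadings[k]
                k += 1
        return g

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        sds = np.sqrt(np.diag(self.Sigma_u))
        corr = implied_correlations(self.Sigma_u)
        return {
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "gamma": self.gamma.tolist(),
            "loadings": self.loadings.tolist(),
            "sd_u": sds.tolist(),
            "corr_u": list(corr),
            "sigma_u3": float(self.sigma_u3),
            "sigma_eps": None if self.sigma_eps is None else float(self.sigma_eps),
        }

    def save(self, path) -> None:
        """Write to a flat named-value file (JSON or YAML by extension),
        with ``Sigma_u`` stored as SDs plus correlations."""
        import json
        from pathlib import Path

        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                import yaml

                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Parameters":
        import json
        from pathlib import Path

        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yml", ".yaml"):
                import yaml

                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Parameters":
        sds = np.asarray(d["sd_u"], dtype=float)
        r01, r02, r12 = d["corr_u"]
        R = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
        Sigma = R * np.outer(sds, sds)
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            Sigma_u=Sigma,
            sigma_u3=float(d["sigma_u3"]),
            sigma_eps=None if d.get("sigma_eps") is None else float(d["sigma_eps"]),
        )


@dataclass
class RandomEffects:
    """Individual random effects, one (u0, u1, u2) triple per individual."""

    u: np.ndarray  # (n_individuals, 3)

    def __post_init__(self) -> None:
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.u.shape[1] != 3:
            raise ValueError("random effects must have three columns (u0, u1, u2)")

    @property
    def u0(self) -> np.ndarray:
        return self.u[:, 0]

    @property
    def u1(self) -> np.ndarray:
        return self.u[:, 1]

    @property
    def u2(self) -> np.ndarray:
        return self.u[:, 2]


@dataclass(frozen=True)
class ScaleValue:
    """Within-individual variance on the log and natural scales."""

    log_var: float
    var: float


def implied_correlations(Sigma_u: np.ndarray):
    """Correlations (location–slope, location–log_scale, slope–log_scale)."""
    Sigma_u = _check_pd(Sigma_u)
    sd = np.sqrt(np.diag(Sigma_u))
    return (
        float(Sigma_u[0, 1] / (sd[0] * sd[1])),
        float(Sigma_u[0, 2] / (sd[0] * sd[2])),
        float(Sigma_u[1, 2] / (sd[1] * sd[2])),
    )


def _clip_logvar(log_var: np.ndarray) -> np.ndarray:
    if np.any(np.abs(log_var) > LOGVAR_CLIP):
        warnings.warn(
            "log within-individual variance clipped to +/-30 during density "
            "evaluation",
            RuntimeWarning,
            stacklevel=3,
        )
        log_var = np.clip(log_var, -LOGVAR_CLIP, LOGVAR_CLIP)
    return log_var


def mean_predictor(
    design: DesignMatrices,
    params: Parameters,
    effects: RandomEffects,
    clinic_index: int,
) -> float:
    """Conditional mean of the exposure at one clinic visit (mm Hg)."""
    params.validate_against(design)
    j = design.visit_individual[clinic_index]
    return float(
        design.X_mean[clinic_index] @ params.beta
        + effects.u0[j]
        + effects.u1[j] * design.z_age[clinic_index]
    )


def log_within_variance(
    design: DesignMatrices,
    params: Parameters,
    effects: RandomEffects,
    clinic_index: int,
) -> ScaleValue:
    """Within-individual (visit-level) variance at one clinic visit."""
    params.validate_against(design)
    j = design.visit_individual[clinic_index]
    log_var = float(design.X_scale[clinic_index] @ params.alpha + effects.u2[j])
    return ScaleValue(log_var=log_var, var=float(np.exp(log_var)))


def outcome_predictor(
    design: DesignMatrices,
    params: Parameters,
    effects: RandomEffects,
    individual_index: int,
) -> float:
    """Conditional mean of the distal outcome for one individual."""
    params.validate_against(design)
    g = params.full_loadings(design.spec)
    return float(
        design.X_outcome[individual_index] @ params.gamma
        + g @ effects.u[individual_index]
    )


# ---------------------------------------------------------------------------
# collapsed sufficient statistics
# ---------------------------------------------------------------------------


@dataclass
class CollapsedData:
    """Per-individual padded arrays of visit-level sufficient statistics.

    Within each clinic visit the readings enter the likelihood only through
    their precision-weighted mean (weights ``n_pooled``), the residual sum
    of squares around it, and the counts; the weighted mean has variance
    ``sigma2_e_ij + sigma_eps^2 / n_tot`` while the within-visit residuals
    depend on ``sigma_eps`` alone and are absorbed into scalar constants.
    """

    ybar: np.ndarray        # (J, C) weighted visit means
    inv_ntot: np.ndarray    # (J, C) 1 / total pooled readings
    z: np.ndarray           # (J, C) centered age
    mask: np.ndarray        # (J, C) True where a visit exists
    X_mean: np.ndarray      # (J, C, p_mean)
    X_scale: np.ndarray     # (J, C, p_scale)
    n_visits: np.ndarray    # (J,)
    # within-visit scalar constants (three-level model)
    sum_ss: float
    n_excess: float
    const_logn: float
    # outcome level
    X_outcome: np.ndarray
    y2: np.ndarray
    outcome_mask: np.ndarray


def collapse(design: DesignMatrices) -> CollapsedData:
    """Precompute the padded per-individual arrays for the likelihood."""
    spec = design.spec
    mv = design.measurement_visit
    n_visits_total = design.n_visits
    w = design.n_pooled.astype(float)
    if spec.levels == 2:
        counts = np.bincount(mv, minlength=n_visits_total)
        if np.any(counts > 1):
            raise ValueError(
                "two-level model allows one reading per clinic visit; "
                "collapse replicates first or use levels=3"
            )
    n_tot = np.bincount(mv, weights=w, minlength=n_visits_total)
    if np.any(n_tot == 0):
        raise ValueError("clinic visits without measurements are not allowed")
    ybar = np.bincount(mv, weights=w * design.y, minlength=n_visits_total) / n_tot
    resid = design.y - ybar[mv]
    sum_ss = float(np.sum(w * resid**2))
    H = np.bincount(mv, minlength=n_visits_total)
    n_excess = float(np.sum(H - 1))
    const_logn = float(0.5 * (np.sum(np.log(w)) - np.sum(np.log(n_tot))))

    vi = design.visit_individual
    J = design.n_individuals
    counts_j = np.bincount(vi, minlength=J)
    C = int(counts_j.max()) if len(counts_j) else 0
    # position of each visit within its individual (canonical order)
    first = np.concatenate(([0], np.cumsum(counts_j)[:-1]))
    pos = np.arange(n_visits_total) - first[vi]

    def pad(values, extra_shape=()):
        out = np.zeros((J, C) + extra_shape)
        out[vi, pos] = values
        return out

    mask = np.zeros((J, C), dtype=bool)
    mask[vi, pos] = True

    return CollapsedData(
        ybar=pad(ybar),
        inv_ntot=pad(1.0 / n_tot),
        z=pad(design.z_age),
        mask=mask,
        X_mean=pad(design.X_mean, (design.X_mean.shape[1],)),
        X_scale=pad(design.X_scale, (design.X_scale.shape[1],)),
        n_visits=counts_j.astype(float),
        sum_ss=sum_ss,
        n_excess=n_excess,
        const_logn=const_logn,
        X_outcome=design.X_outcome,
        y2=np.where(design.outcome_observed, design.y2, 0.0),
        outcome_mask=design.outcome_observed
        & np.full(J, design.spec.include_outcome),
    )


# ---------------------------------------------------------------------------
# complete-data log density
# ---------------------------------------------------------------------------


def _visit_measurement_loglik(
    design: DesignMatrices,
    mu_visit: np.ndarray,
    log_var_visit: np.ndarray,
    sigma_eps: float | None,
) -> float:
    """Sum over visits of the reading-vector log density given (u, visit mean).

    The visit-level error ``e_ij`` is integrated analytically: readings at
    one visit are jointly normal with compound-symmetry covariance
    ``sigma2_e * J + sigma_eps^2 * diag(1/n_pooled)``.
    """
    mv = design.measurement_visit
    n_visits = design.n_visits
    sigma2_e = np.exp(_clip_logvar(log_var_visit))
    r = design.y - mu_visit[mv]
    if design.spec.levels == 2:
        v = sigma2_e[mv]
        return float(-0.5 * np.sum(_LOG2PI + np.log(v) + r**2 / v))
    d = sigma_eps**2 / design.n_pooled
    inv_d = 1.0 / d
    s_inv = np.bincount(mv, weights=inv_d, minlength=n_visits)
    s_r = np.bincount(mv, weights=r * inv_d, minlength=n_visits)
    s_rr = np.bincount(mv, weights=r**2 * inv_d, minlength=n_visits)
    cap = 1.0 + sigma2_e * s_inv
    logdet = np.bincount(mv, weights=np.log(2.0 * np.pi * d), minlength=n_visits) \
        + np.log(cap)
    quad = s_rr - sigma2_e * s_r**2 / cap
    return float(-0.5 * np.sum(logdet + quad))


def complete_data_logdensity(
    design: DesignMatrices,
    params: Parameters,
    effects: RandomEffects,
) -> float:
    """Joint log density of (readings, outcomes, random effects).

    Sums the reading-vector densities per visit (visit-level error
    marginalized analytically), the MVN density of the random effects, and
    the outcome densities for individuals with an observed outcome.
    """
    params.validate_against(design)
    if effects.u.shape[0] != design.n_individuals:
        raise ValueError("one random-effect triple per individual is required")
    vi = design.visit_individual
    mu_visit = design.X_mean @ params.beta + effects.u0[vi] + effects.u1[vi] * design.z_age
    log_var_visit = design.X_scale @ params.alpha + effects.u2[vi]
    total = _visit_measurement_loglik(design, mu_visit, log_var_visit, params.sigma_eps)

    # random effects density
    L = np.linalg.cholesky(params.Sigma_u)
    sol = np.linalg.solve(L, effects.u.T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    J = design.n_individuals
    total += float(-0.5 * (J * (3 * _LOG2PI + logdet) + np.sum(sol**2)))

    # outcome density
    mask = design.outcome_observed & design.spec.include_outcome
    if mask.any():
        g = params.full_loadings(design.spec)
        pred = design.X_outcome @ params.gamma + effects.u @ g
        r = design.y2[mask] - pred[mask]
        v = params.sigma_u3**2
        total += float(-0.5 * np.sum(_LOG2PI + np.log(v) + r**2 / v))
    return total


# ---------------------------------------------------------------------------
# production marginal likelihood (analytic (u0,u1) + 1-D quadrature on u2)
# ---------------------------------------------------------------------------


def marginal_loglik(
    design: DesignMatrices,
    params: Parameters,
    quad_order: int = 21,
    collapsed: CollapsedData | None = None,
    per_individual: bool = False,
):
    """Marginal log likelihood with random effects integrated out.

    ``(u0, u1)`` are integrated analytically conditional on ``u2`` (the
    model is linear-Gaussian in them); ``u2`` is integrated by *adaptive*
    Gauss–Hermite quadrature: for each individual the nodes are centered
    and scaled to a Gaussian approximation of the u2-integrand built from
    the linear channel (which is exact in u2 when the variance channel is
    frozen), so the rule stays accurate even when the outcome loading
    makes the integrand much narrower than the prior.  Per-visit reading
    vectors are collapsed to weighted means beforehand (see
    :func:`collapse`).
    """
    params.validate_against(design)
    c = collapsed if collapsed is not None else collapse(design)
    spec = design.spec

    Sigma = params.Sigma_u
    s2_u2 = Sigma[2, 2]
    s = Sigma[:2, 2]
    cc = s / s2_u2  # E[(u0,u1) | u2] = cc * u2
    Sc = Sigma[:2, :2] - np.outer(s, s) / s2_u2
    detSc = Sc[0, 0] * Sc[1, 1] - Sc[0, 1] ** 2
    if detSc <= 0:
        raise DefinitenessError("conditional covariance of (u0,u1) degenerate")
    P = np.array([[Sc[1, 1], -Sc[0, 1]], [-Sc[0, 1], Sc[0, 0]]]) / detSc
    logdetSc = float(np.log(detSc))

    eta = np.einsum("jcp,p->jc", c.X_scale, params.alpha)
    mu = np.einsum("jcp,p->jc", c.X_mean, params.beta)
    r0 = np.where(c.mask, c.ybar - mu, 0.0)
    g = params.full_loadings(spec)
    om = c.outcome_mask
    vo = params.sigma_u3**2
    coef = g[2] + g[0] * cc[0] + g[1] * cc[1]
    h = np.where(c.mask, cc[0] + cc[1] * c.z, 0.0)  # du(visit mean)/du2

    # ---- Gaussian approximation of the u2 integrand (linear channel) ----
    V0 = np.exp(_clip_logvar(eta))
    if spec.levels == 3:
        V0 = V0 + params.sigma_eps**2 * c.inv_ntot
    Dinv0 = np.where(c.mask, 1.0 / V0, 0.0)
    a00 = np.sum(Dinv0, axis=1)
    a01 = np.sum(c.z * Dinv0, axis=1)
    a11 = np.sum(c.z**2 * Dinv0, axis=1)
    hh = np.sum(h**2 * Dinv0, axis=1)
    hr = np.sum(h * r0 * Dinv0, axis=1)
    u0c = np.sum(h * Dinv0, axis=1)        # A' D^-1 h, first row
    u1c = np.sum(h * c.z * Dinv0, axis=1)  # second row
    t0 = np.sum(r0 * Dinv0, axis=1)
    t1 = np.sum(r0 * c.z * Dinv0, axis=1)
    fvar = np.where(c.mask, np.exp(_clip_logvar(eta)) / V0, 0.0)
    prec_var = 0.5 * np.sum(fvar**2, axis=1)
    M00 = P[0, 0] + a00
    M01 = P[0, 1] + a01
    M11 = P[1, 1] + a11
    detM0 = M00 * M11 - M01**2
    # h' Omega^-1 h and h' Omega^-1 r0 via Woodbury (clinic rows only)
    lik_prec = hh - (M11 * u0c**2 - 2 * M01 * u0c * u1c + M00 * u1c**2) / detM0
    lik_mean = hr - (M11 * u0c * t0 - M01 * (u0c * t1 + u1c * t0)
                     + M00 * u1c * t1) / detM0
    lik_prec = np.maximum(lik_prec, 0.0)
    # outcome row by conditioning on the clinic information: numerically
    # stable for arbitrarily small sigma_u3 / large loadings
    if om.any():
        fixed_o = c.X_outcome @ params.gamma
        ro = np.where(om, c.y2 - fixed_o, 0.0)
        Vc00 = M11 / detM0
        Vc01 = -M01 / detM0
        Vc11 = M00 / detM0
        m0 = Vc00 * t0 + Vc01 * t1
        m1 = Vc01 * t0 + Vc11 * t1
        s2o = vo + g[0] ** 2 * Vc00 + 2 * g[0] * g[1] * Vc01 + g[1] ** 2 * Vc11
        slope = coef - (g[0] * (Vc00 * u0c + Vc01 * u1c)
                        + g[1] * (Vc01 * u0c + Vc11 * u1c))
        r_out0 = ro - (g[0] * m0 + g[1] * m1)
        lik_prec = lik_prec + om * slope**2 / s2o
        lik_mean = lik_mean + om * slope * r_out0 / s2o
    post_prec = 1.0 / s2_u2 + lik_prec + prec_var
    m_j = lik_mean / post_prec
    s_j = 1.2 / np.sqrt(post_prec)

    nodes, weights = hermgauss(quad_order)
    # u2 nodes per individual: m_j + sqrt(2) s_j x_q
    u2 = m_j[:, None] + np.sqrt(2.0) * s_j[:, None] * nodes  # (J, Q)
    logw = (np.log(weights) + nodes**2)[None, :] \
        + 0.5 * np.log(2.0) + np.log(s_j)[:, None] \
        - 0.5 * (np.log(2.0 * np.pi * s2_u2) + u2**2 / s2_u2)

    log_var = _clip_logvar(eta[..., None] + u2[:, None, :])
    V = np.exp(log_var)
    if spec.levels == 3:
        V = V + params.sigma_eps**2 * c.inv_ntot[..., None]
    Dinv = np.where(c.mask[..., None], 1.0 / V, 0.0)
    logdetD = np.sum(np.where(c.mask[..., None], np.log(V), 0.0), axis=1)

    R = np.where(c.mask[..., None], r0[..., None] - h[..., None] * u2[:, None, :], 0.0)

    S_rr = np.sum(R**2 * Dinv, axis=1)
    b0 = np.sum(R * Dinv, axis=1)
    zc = c.z[..., None]
    b1 = np.sum(R * zc * Dinv, axis=1)
    a00 = np.sum(Dinv, axis=1)
    a01 = np.sum(zc * Dinv, axis=1)
    a11 = np.sum(zc**2 * Dinv, axis=1)
    d_eff = c.n_visits.copy()

    M00 = P[0, 0] + a00
    M01 = P[0, 1] + a01
    M11 = P[1, 1] + a11
    detM = M00 * M11 - M01**2
    bMb = (M11 * b0**2 - 2.0 * M01 * b0 * b1 + M00 * b1**2) / detM

    logdens = -0.5 * (
        d_eff[:, None] * _LOG2PI
        + logdetD
        + np.log(detM)
        + logdetSc
        + S_rr
        - bMb
    )
    if om.any():
        # outcome | clinic information: conditional Gaussian per node
        Vc00 = M11 / detM
        Vc01 = -M01 / detM
        Vc11 = M00 / detM
        m0 = Vc00 * b0 + Vc01 * b1
        m1 = Vc01 * b0 + Vc11 * b1
        s2o = vo + g[0] ** 2 * Vc00 + 2 * g[0] * g[1] * Vc01 + g[1] ** 2 * Vc11
        r_oc = np.where(om[:, None],
                        ro[:, None] - coef * u2 - (g[0] * m0 + g[1] * m1), 0.0)
        logdens = logdens + np.where(
            om[:, None],
            -0.5 * (_LOG2PI + np.log(s2o) + r_oc**2 / s2o),
            0.0,
        )
    ll_j = logsumexp(logdens + logw, axis=1)

    const = 0.0
    if spec.levels == 3:
        const = (
            c.const_logn
            - 0.5 * c.n_excess * np.log(2.0 * np.pi * params.sigma_eps**2)
            - c.sum_ss / (2.0 * params.sigma_eps**2)
        )
    if per_individual:
        return ll_j, const
    return float(np.sum(ll_j) + const)


# ---------------------------------------------------------------------------
# testing oracles
# ---------------------------------------------------------------------------


def _individual_data_loglik(
    design: DesignMatrices, params: Parameters, j: int, U: np.ndarray
) -> np.ndarray:
    """log p(data_j | u) for a batch of random-effect triples U (n, 3).

    Direct per-visit compound-symmetry densities; no collapsing, no shared
    code with the production path beyond the model definition itself.
    """
    U = np.atleast_2d(U)
    n = U.shape[0]
    out = np.zeros(n)
    visit_rows = np.where(design.visit_individual == j)[0]
    for v in visit_rows:
        rows = np.where(design.measurement_visit == v)[0]
        y = design.y[rows]
        npool = design.n_pooled[rows]
        mu = design.X_mean[v] @ params.beta + U[:, 0] + U[:, 1] * design.z_age[v]
        log_var = np.clip(
            design.X_scale[v] @ params.alpha + U[:, 2], -LOGVAR_CLIP, LOGVAR_CLIP
        )
        s2e = np.exp(log_var)
        r = y[None, :] - mu[:, None]  # (n, H)
        if design.spec.levels == 2:
            out += -0.5 * (_LOG2PI + log_var + r[:, 0] ** 2 / s2e)
            continue
        d = params.sigma_eps**2 / npool
        s_inv = np.sum(1.0 / d)
        s_r = r @ (1.0 / d)
        s_rr = (r**2) @ (1.0 / d)
        cap = 1.0 + s2e * s_inv
        logdet = np.sum(np.log(2.0 * np.pi * d)) + np.log(cap)
        out += -0.5 * (logdet + s_rr - s2e * s_r**2 / cap)
    if design.outcome_observed[j] and design.spec.include_outcome:
        g = params.full_loadings(design.spec)
        pred = design.X_outcome[j] @ params.gamma + U @ g
        v2 = params.sigma_u3**2
        out += -0.5 * (_LOG2PI + np.log(v2) + (design.y2[j] - pred) ** 2 / v2)
    return out


def marginal_loglik_bruteforce(
    design: DesignMatrices, params: Parameters, quad_order: int = 25
) -> float:
    """Marginal log likelihood by full 3-D Gauss–Hermite quadrature.

    Integrates (u0, u1, u2) jointly on a tensor-product grid after a
    Cholesky rotation of ``Sigma_u``; cost is ``quad_order**3`` per
    individual, so this is a small-instance testing oracle only.
    """
    params.validate_against(design)
    if quad_order < 5:
        warnings.warn("quadrature order < 5 is unreliable", RuntimeWarning)
    if design.n_individuals > 50:
        warnings.warn(
            "brute-force quadrature on > 50 individuals will be slow",
            RuntimeWarning,
        )
    L = np.linalg.cholesky(params.Sigma_u)
    nodes, weights = hermgauss(quad_order)
    grid = np.stack(np.meshgrid(nodes, nodes, nodes, indexing="ij"), axis=-1)
    X = grid.reshape(-1, 3)
    U = np.sqrt(2.0) * X @ L.T
    logw = (
        np.log(weights)[:, None, None]
        + np.log(weights)[None, :, None]
        + np.log(weights)[None, None, :]
    ).reshape(-1) - 1.5 * np.log(np.pi)
    total = 0.0
    for j in range(design.n_individuals):
        ll = _individual_data_loglik(design, params, j, U)
        total += logsumexp(ll + logw)
    return float(total)


def marginal_loglik_montecarlo(
    design: DesignMatrices,
    params: Parameters,
    n_draws: int = 100_000,
    seed: int = 0,
):
    """Monte-Carlo estimate of the marginal log likelihood with its SE.

    Draws ``u ~ MVN(0, Sigma_u)`` and averages the conditional data
    density per individual; the standard error of each log-mean is by the
    delta method and errors are combined across individuals in quadrature.
    """
    params.validate_against(design)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(params.Sigma_u)
    total = 0.0
    var_sum = 0.0
    for j in range(design.n_individuals):
        U = rng.standard_normal((n_draws, 3)) @ L.T
        ll = _individual_data_loglik(design, params, j, U)
        m = np.max(ll)
        w = np.exp(ll - m)
        mean_w = np.mean(w)
        total += m + np.log(mean_w)
        var_sum += np.var(w, ddof=1) / (n_draws * mean_w**2)
    return float(total), float(np.sqrt(var_sum))
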