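"""Optional numba-accelerated marginal likelihood.

Same quantity as :func:`melsjm.model_core.marginal_loglik`, restructured
as explicit loops for JIT compilation.  The estimation module uses this
path when numba is importable and silently falls back to the reference
numpy implementation otherwise; the two are cross-checked on first use.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss

from .data_model import DesignMatrices
from .model_core import CollapsedData, LOGVAR_CLIP, Parameters, collapse, marginal_loglik

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = ["FastLoglik", "HAVE_NUMBA"]


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _kernel(
        ybar, inv_ntot, z, mask, Xm, Xs, nvis,
        Xout, y2, omask,
        beta, alpha, gamma, g0, g1, g2,
        cc0, cc1, P00, P01, P11, logdetSc,
        sigma_u3_sq, sigma_eps_sq, levels, s2_u2,
        nodes, lw_base,
    ):
        J, C = ybar.shape
        Q = nodes.shape[0]
        log2pi = np.log(2.0 * np.pi)
        sqrt2 = np.sqrt(2.0)
        total = 0.0
        eta = np.empty(C)
        r0 = np.empty(C)
        hv = np.empty(C)
        logn = np.empty(Q)
        coef = g2 + g0 * cc0 + g1 * cc1
        for j in range(J):
            # ---- adaptive prepass: Gaussian fit of the u2 integrand -----
            a00 = 0.0; a01 = 0.0; a11 = 0.0
            hh = 0.0; hr = 0.0
            u0c = 0.0; u1c = 0.0; t0 = 0.0; t1 = 0.0
            prec_var = 0.0
            for c_i in range(C):
                if not mask[j, c_i]:
                    continue
                e = 0.0
                m = 0.0
                for p in range(alpha.shape[0]):
                    e += Xs[j, c_i, p] * alpha[p]
                for p in range(beta.shape[0]):
                    m += Xm[j, c_i, p] * beta[p]
                if e > LOGVAR_CLIP:
                    e = LOGVAR_CLIP
                elif e < -LOGVAR_CLIP:
                    e = -LOGVAR_CLIP
                eta[c_i] = e
                r = ybar[j, c_i] - m
                r0[c_i] = r
                zi = z[j, c_i]
                h = cc0 + cc1 * zi
                hv[c_i] = h
                ve = np.exp(e)
                v0 = ve
                if levels == 3:
                    v0 += sigma_eps_sq * inv_ntot[j, c_i]
                dinv = 1.0 / v0
                a00 += dinv
                a01 += zi * dinv
                a11 += zi * zi * dinv
                hh += h * h * dinv
                hr += h * r * dinv
                u0c += h * dinv
                u1c += h * zi * dinv
                t0 += r * dinv
                t1 += r * zi * dinv
                f = ve * dinv
                prec_var += 0.5 * f * f
            M00 = P00 + a00
            M01 = P01 + a01
            M11 = P11 + a11
            detM0 = M00 * M11 - M01 * M01
            lik_prec = hh - (M11 * u0c * u0c - 2.0 * M01 * u0c * u1c
                             + M00 * u1c * u1c) / detM0
            if lik_prec < 0.0:
                lik_prec = 0.0
            lik_mean = hr - (M11 * u0c * t0 - M01 * (u0c * t1 + u1c * t0)
                             + M00 * u1c * t1) / detM0
            fo = 0.0
            ro = 0.0
            if omask[j]:
                # outcome row conditioned on clinic information (stable
                # for tiny sigma_u3 / large loadings)
                for p in range(gamma.shape[0]):
                    fo += Xout[j, p] * gamma[p]
                ro = y2[j] - fo
                Vc00 = M11 / detM0
                Vc01 = -M01 / detM0
                Vc11 = M00 / detM0
                m0 = Vc00 * t0 + Vc01 * t1
                m1 = Vc01 * t0 + Vc11 * t1
                s2o = sigma_u3_sq + g0 * g0 * Vc00 \
                    + 2.0 * g0 * g1 * Vc01 + g1 * g1 * Vc11
                slope = coef - (g0 * (Vc00 * u0c + Vc01 * u1c)
                                + g1 * (Vc01 * u0c + Vc11 * u1c))
                r_out0 = ro - (g0 * m0 + g1 * m1)
                lik_prec += slope * slope / s2o
                lik_mean += slope * r_out0 / s2o
            post_prec = 1.0 / s2_u2 + lik_prec + prec_var
            m_j = lik_mean / post_prec
            s_j = 1.2 / np.sqrt(post_prec)
            log_s = np.log(s_j)
            # ---- adapted quadrature pass --------------------------------
            for q in range(Q):
                u2 = m_j + sqrt2 * s_j * nodes[q]
                s_rr = 0.0
                b0 = 0.0
                b1 = 0.0
                a00 = 0.0
                a01 = 0.0
                a11 = 0.0
                logdetD = 0.0
                for c_i in range(C):
                    if not mask[j, c_i]:
                        continue
                    lv = eta[c_i] + u2
                    if lv > LOGVAR_CLIP:
                        lv = LOGVAR_CLIP
                    elif lv < -LOGVAR_CLIP:
                        lv = -LOGVAR_CLIP
                    v = np.exp(lv)
                    if levels == 3:
                        v += sigma_eps_sq * inv_ntot[j, c_i]
                    zi = z[j, c_i]
                    r = r0[c_i] - hv[c_i] * u2
                    dinv = 1.0 / v
                    s_rr += r * r * dinv
                    b0 += r * dinv
                    b1 += r * zi * dinv
                    a00 += dinv
                    a01 += zi * dinv
                    a11 += zi * zi * dinv
                    logdetD += np.log(v)
                d_eff = nvis[j]
                M00 = P00 + a00
                M01 = P01 + a01
                M11 = P11 + a11
                detM = M00 * M11 - M01 * M01
                bMb = (M11 * b0 * b0 - 2.0 * M01 * b0 * b1
                       + M00 * b1 * b1) / detM
                extra = 0.0
                if omask[j]:
                    Vc00 = M11 / detM
                    Vc01 = -M01 / detM
                    Vc11 = M00 / detM
                    m0 = Vc00 * b0 + Vc01 * b1
                    m1 = Vc01 * b0 + Vc11 * b1
                    s2o = sigma_u3_sq + g0 * g0 * Vc00 \
                        + 2.0 * g0 * g1 * Vc01 + g1 * g1 * Vc11
                    r_oc = ro - coef * u2 - (g0 * m0 + g1 * m1)
                    extra = -0.5 * (log2pi + np.log(s2o) + r_oc * r_oc / s2o)
                logn[q] = lw_base[q] + 0.5 * np.log(2.0) + log_s \
                    - 0.5 * (np.log(2.0 * np.pi * s2_u2) + u2 * u2 / s2_u2) \
                    - 0.5 * (
                        d_eff * log2pi + logdetD + np.log(detM) + logdetSc
                        + s_rr - bMb
                    ) + extra
            mx = logn[0]
            for q in range(1, Q):
                if logn[q] > mx:
                    mx = logn[q]
            acc = 0.0
            for q in range(Q):
                acc += np.exp(logn[q] - mx)
            total += mx + np.log(acc)
        return total


class FastLoglik:
    """Callable ``params -> marginal log likelihood`` bound to one design.

    Prefers the JIT kernel; verified against the reference implementation
    at construction (tolerance 1e-8 relative) and falls back to it when
    numba is unavailable.
    """

    def __init__(self, design: DesignMatrices, quad_order: int = 15,
                 collapsed: CollapsedData | None = None):
        self.design = design
        self.quad_order = quad_order
        self.c = collapsed if collapsed is not None else collapse(design)
        nodes, weights = hermgauss(quad_order)
        self._nodes = nodes
        self._lw_base = np.log(weights) + nodes**2
        self._use_numba = HAVE_NUMBA
        if self._use_numba:
            c = self.c
            self._args = (
                c.ybar, c.inv_ntot, c.z, c.mask,
                np.ascontiguousarray(c.X_mean), np.ascontiguousarray(c.X_scale),
                c.n_visits, np.ascontiguousarray(c.X_outcome),
                c.y2, c.outcome_mask,
            )

    def _reference(self, params: Parameters) -> float:
        return marginal_loglik(self.design, params, self.quad_order, self.c)

    def __call__(self, params: Parameters) -> float:
        if not self._use_numba:
            return self._reference(params)
        spec = self.design.spec
        S = params.Sigma_u
        s2_u2 = S[2, 2]
        sd_u2 = np.sqrt(s2_u2)
        s = S[:2, 2]
        cc = s / s2_u2
        Sc = S[:2, :2] - np.outer(s, s) / s2_u2
        detSc = Sc[0, 0] * Sc[1, 1] - Sc[0, 1] ** 2
        if detSc <= 0:
            raise np.linalg.LinAlgError("degenerate conditional covariance")
        P00 = Sc[1, 1] / detSc
        P01 = -Sc[0, 1] / detSc
        P11 = Sc[0, 0] / detSc
        g = params.full_loadings(spec)
        sigma_eps_sq = params.sigma_eps**2 if spec.levels == 3 else 0.0
        total = _kernel(
            *self._args,
            params.beta, params.alpha, params.gamma,
            g[0], g[1], g[2],
            cc[0], cc[1], P00, P01, P11, float(np.log(detSc)),
            params.sigma_u3**2, sigma_eps_sq, spec.levels, s2_u2,
            self._nodes, self._lw_base,
        )
        if spec.levels == 3:
            total += (
                self.c.const_logn
                - 0.5 * self.c.n_excess * np.log(2.0 * np.pi * sigma_eps_sq)
                - self.c.sum_ss / (2.0 * sigma_eps_sq)
            )
        return float(total)

    def verify(self, params: Parameters, rtol: float = 1e-8) -> bool:
        a, b = self(params), self._reference(params)
        return bool(abs(a - b) <= rtol * max(1.0, abs(b)))
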