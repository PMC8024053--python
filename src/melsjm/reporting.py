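"""Posterior post-processing: percentage transforms, outlier screening,
and human-readable results tables.

Coefficients acting on a log-scale quantity (the log within-individual
variance, the log outcome) are easier to read as percentage changes:

* per 1-unit increase in a covariate: ``(exp(b) - 1) * 100``;
* per 10% increase in a log-transformed covariate (or in the variance
  itself, for the log-variance loading): ``(1.10**b - 1) * 100``.

Both transforms are applied draw-wise and then summarized, never to the
summary statistics — they are monotone, so the credible-interval
endpoints commute with the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset, DesignMatrices
from .model_core import Parameters

__all__ = [
    "TransformedEstimate",
    "OutlierReport",
    "percent_change_per_unit",
    "percent_change_per_10pct",
    "screen_outliers",
    "results_table",
    "render_text",
    "qq_plot",
]


@dataclass(frozen=True)
class TransformedEstimate:
    """A posterior summary on a reporting scale.

    Both the mean and the median of the transformed draws are kept: for a
    heavy-tailed posterior (e.g. a weakly identified loading) the mean of
    exponentially transformed draws can be dominated by a few extreme
    draws, while the median and the interval endpoints are stable (they
    commute with the monotone transform).
    """

    name: str
    scale: str  # raw | percent_per_unit | percent_per_10pct
    mean: float
    median: float
    q2_5: float
    q97_5: float


def _summarize(name: str, scale: str, draws: np.ndarray) -> TransformedEstimate:
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if not np.all(np.isfinite(draws)):
        raise ValueError(f"non-finite draws for {name}")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return TransformedEstimate(name, scale, float(np.mean(draws)),
                               float(med), float(lo), float(hi))


def percent_change_per_unit(draws, name: str = "") -> TransformedEstimate:
    """Percentage change per 1-unit covariate increase: (exp(b) - 1) * 100."""
    draws = np.asarray(draws, dtype=float)
    return _summarize(name, "percent_per_unit", (np.exp(draws) - 1.0) * 100.0)


def percent_change_per_10pct(draws, name: str = "") -> TransformedEstimate:
    """Percentage change per 10% covariate increase: (1.10**b - 1) * 100."""
    draws = np.asarray(draws, dtype=float)
    return _summarize(name, "percent_per_10pct",
                      (np.power(1.10, draws) - 1.0) * 100.0)


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    """Standardized-residual screen at three levels of the hierarchy."""

    threshold: float
    individual_flags: pd.DataFrame   # individual_id, residual
    clinic_flags: pd.DataFrame       # individual_id, clinic_id, residual
    measurement_flags: pd.DataFrame  # individual_id, clinic_id, occasion, residual
    counts: dict


def _empirical_bayes_effects(design: DesignMatrices, params: Parameters):
    """Posterior-mean (u0, u1) per individual given u2 = 0.

    A fast shrinkage estimate good enough for residual screening: each
    individual's clinic-mean residuals are combined by GLS with the
    random-effect prior as ridge penalty.
    """
    w = design.n_pooled
    mv = design.measurement_visit
    nv = np.bincount(mv, weights=w, minlength=design.n_visits)
    ybar = np.bincount(mv, weights=w * design.y, minlength=design.n_visits) / nv
    r0 = ybar - design.X_mean @ params.beta
    v = np.exp(design.X_scale @ params.alpha)
    if design.spec.levels == 3:
        v = v + params.sigma_eps**2 / nv
    P = np.linalg.inv(params.Sigma_u[:2, :2])
    u_hat = np.zeros((design.n_individuals, 2))
    vi = design.visit_individual
    for j in range(design.n_individuals):
        idx = np.where(vi == j)[0]
        A = np.column_stack([np.ones(len(idx)), design.z_age[idx]])
        W = A.T / v[idx]
        u_hat[j] = np.linalg.solve(P + W @ A, W @ r0[idx])
    return u_hat, ybar, nv, r0, v


def screen_outliers(
    dataset: Dataset,
    design: DesignMatrices,
    params: Parameters,
    threshold: float = 4.0,
):
    """Flag and remove records with extreme standardized residuals.

    Residuals are computed at three levels from a preliminary parameter
    estimate: within-clinic deviations from the visit mean (measurement
    level, exactly standard normal under the model), visit-mean residuals
    around the individual's shrunken trajectory (clinic level), and the
    shrunken individual intercepts (individual level).  Flagged
    measurements are removed; flagged visits lose all their measurements;
    flagged individuals lose all their rows.  Returns
    ``(report, filtered_dataset)``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    params.validate_against(design)

    u_hat, ybar, nv, r0, v = _empirical_bayes_effects(design, params)
    vi = design.visit_individual
    meas = dataset.measurements
    clin = dataset.clinics

    # measurement level: within-clinic contrasts
    mv = design.measurement_visit
    if design.spec.levels == 3:
        dev = design.y - ybar[mv]
        var_dev = params.sigma_eps**2 * (
            1.0 / design.n_pooled - 1.0 / nv[mv]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z_meas = np.where(var_dev > 0, dev / np.sqrt(np.maximum(var_dev, 1e-300)), 0.0)
    else:
        z_meas = np.zeros(len(meas))
    flag_m = np.abs(z_meas) > threshold

    # clinic level: visit-mean residuals around the shrunken trajectory
    e_hat = r0 - u_hat[vi, 0] - u_hat[vi, 1] * design.z_age
    z_clin = e_hat / np.sqrt(v)
    flag_c = np.abs(z_clin) > threshold

    # individual level: shrunken intercepts on the prior SD scale
    z_ind = u_hat[:, 0] / np.sqrt(params.Sigma_u[0, 0])
    flag_i = np.abs(z_ind) > threshold

    ind_ids = design.individual_ids[flag_i]
    clinic_keys = clin.iloc[np.where(flag_c)[0]][["individual_id", "clinic_id"]]
    meas_flags = meas.iloc[np.where(flag_m)[0]][
        ["individual_id", "clinic_id", "occasion"]
    ].copy()
    meas_flags["residual"] = z_meas[flag_m]
    clinic_flags = clinic_keys.copy()
    clinic_flags["residual"] = z_clin[flag_c]
    ind_flags = pd.DataFrame({
        "individual_id": ind_ids, "residual": z_ind[flag_i],
    })

    report = OutlierReport(
        threshold=float(threshold),
        individual_flags=ind_flags,
        clinic_flags=clinic_flags,
        measurement_flags=meas_flags,
        counts={
            "individual": int(flag_i.sum()),
            "clinic": int(flag_c.sum()),
            "measurement": int(flag_m.sum()),
        },
    )

    # filter: individuals entirely; flagged visits entirely; then measurements
    bad_ind = set(ind_ids.tolist())
    bad_visits = set(map(tuple, clinic_keys.itertuples(index=False)))
    m = meas.copy()
    keep_m = (
        ~m["individual_id"].isin(bad_ind)
        & ~pd.MultiIndex.from_frame(m[["individual_id", "clinic_id"]]).isin(bad_visits)
    )
    keep_m &= ~pd.MultiIndex.from_frame(
        m[["individual_id", "clinic_id", "occasion"]]
    ).isin(set(map(tuple, meas_flags[["individual_id", "clinic_id", "occasion"]]
                   .itertuples(index=False))))
    m = m[keep_m]
    c = clin[
        ~clin["individual_id"].isin(bad_ind)
        & ~pd.MultiIndex.from_frame(clin[["individual_id", "clinic_id"]]).isin(bad_visits)
    ]
    # visits that lost all measurements disappear too
    left = set(map(tuple, m[["individual_id", "clinic_id"]].itertuples(index=False)))
    c = c[pd.MultiIndex.from_frame(c[["individual_id", "clinic_id"]]).isin(left)]
    i = dataset.individuals[~dataset.individuals["individual_id"].isin(bad_ind)]
    # individuals with no remaining visits are dropped entirely
    left_ind = set(m["individual_id"])
    i = i[i["individual_id"].isin(left_ind)]

    filtered = Dataset(m.reset_index(drop=True), c.reset_index(drop=True),
                       i.reset_index(drop=True),
                       {**dataset.report, "outliers_removed": report.counts})
    return report, filtered


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------


def _scale_for(term: str, context: str) -> str:
    """Reporting scale for a coefficient, mirroring the footnote rules.

    Coefficients in the log-variance and log-outcome functions are shown
    as percentage change; those of log-transformed covariates (and the
    log-variance loading) per 10% covariate increase, all others per unit.
    Mean-function coefficients and intercepts stay on the raw scale.
    """
    if context == "mean" or term == "intercept":
        return "raw"
    if term.startswith("log_") or term == "gamma_log_scale":
        return "percent_per_10pct"
    return "percent_per_unit"


def results_table(fit) -> pd.DataFrame:
    """Sectioned results table from a :class:`~melsjm.estimation.JointFit`.

    Sections: exposure mean fixed effects (raw), random-effect SDs and
    correlations, log-variance fixed effects (percent scales), outcome
    fixed effects and shared-random-effect loadings (percent scales).
    """
    draws = fit.draws
    rows = []

    def add(section: str, name: str, label: str, scale: str) -> None:
        if name not in draws:
            raise KeyError(f"required row '{name}' missing from the fit")
        d = draws[name].reshape(-1)
        if scale == "percent_per_unit":
            est = percent_change_per_unit(d, label)
        elif scale == "percent_per_10pct":
            est = percent_change_per_10pct(d, label)
        else:
            est = _summarize(label, "raw", d)
        rows.append({
            "section": section, "parameter": label, "scale": est.scale,
            "mean": est.mean, "median": est.median,
            "q2.5": est.q2_5, "q97.5": est.q97_5,
        })

    names = fit.transform.names
    for n in names:
        if n.startswith("beta["):
            add("exposure mean", n, n[5:-1], "raw")
    for n in ("sd_u0", "sd_u1", "sd_u2",
              "corr_u0_u1", "corr_u0_u2", "corr_u1_u2"):
        add("random effects", n, n, "raw")
    for n in names:
        if n.startswith("alpha["):
            term = n[6:-1]
            add("within-individual variance", n, term, _scale_for(term, "scale"))
    if "sigma_eps" in draws:
        add("within-individual variance", "sigma_eps", "sigma_eps", "raw")
    for n in names:
        if n.startswith("gamma["):
            term = n[6:-1]
            add("outcome", n, term, _scale_for(term, "outcome"))
    for n in names:
        if n.startswith("gamma_"):
            add("outcome", n, n, _scale_for(n, "outcome"))
    add("outcome", "sigma_u3", "sigma_u3", "raw")
    return pd.DataFrame(rows)


def render_text(table: pd.DataFrame) -> str:
    """Plain-text rendering of a results table, one block per section.

    Prints the posterior median with the 95% interval; the table itself
    also carries the mean.
    """
    lines = []
    for section, grp in table.groupby("section", sort=False):
        lines.append(section)
        lines.append("-" * len(section))
        for _, r in grp.iterrows():
            unit = {"raw": "", "percent_per_unit": " %/unit",
                    "percent_per_10pct": " %/10%"}[r["scale"]]
            lines.append(
                f"  {r['parameter']:<22} {r['median']:9.3f} "
                f"({r['q2.5']:9.3f}, {r['q97.5']:9.3f}){unit}"
            )
        lines.append("")
    return "\n".join(lines)


def qq_plot(residuals, path) -> None:
    """Normal quantile-quantile plot of standardized residuals (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    residuals = np.sort(np.asarray(residuals, dtype=float))
    n = len(residuals)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(theo, residuals, ".", ms=3)
    lim = [min(theo[0], residuals[0]), max(theo[-1], residuals[-1])]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("observed quantile")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
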