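"""Domain types, table loading/validation, and design-matrix construction.

The data layout mirrors a multi-clinic longitudinal study: repeated exposure
readings (e.g. systolic blood pressure in mm Hg) nested in clinic visits,
nested in individuals, with a single later individual-level outcome (e.g.
left-ventricular mass index, modelled on the log scale).

Three long-format tables describe a study:

``measurements``
    one row per reading: ``individual_id, clinic_id, occasion, value,
    n_pooled`` (``n_pooled`` > 1 marks a stored mean of that many readings).
``clinics``
    one row per (individual, clinic) visit: ``individual_id, clinic_id,
    age`` plus visit-level covariates such as ``weight`` (kg) and ``height``.
``individuals``
    one row per individual: ``individual_id, outcome`` plus static
    covariates (``female`` 0/1, maternal characteristics, outcome-model
    covariates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "LinkageError",
    "ValidationError",
    "TransformError",
    "ModelSpec",
    "Dataset",
    "DesignMatrices",
    "load_dataset",
    "spline_basis",
    "build_design",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class LinkageError(ValueError):
    """A child row references a parent key that does not exist."""


class ValidationError(ValueError):
    """A table violates a uniqueness or range invariant."""


class TransformError(ValueError):
    """A variable transform (log) received an invalid value."""


#: canonical column names for each table
MEASUREMENT_COLUMNS = ("individual_id", "clinic_id", "occasion", "value")
CLINIC_COLUMNS = ("individual_id", "clinic_id", "age")
INDIVIDUAL_COLUMNS = ("individual_id",)

#: shared-random-effect labels, in canonical order (u0, u1, u2)
SHARED_EFFECTS = ("location", "slope", "log_scale")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter each submodel and which random effects are shared.

    Parameters
    ----------
    mean_terms
        Design columns for the exposure mean function (an intercept is
        always prepended).  Spline columns ``s1``/``s2`` are generated from
        age with a knot at :attr:`knot`.
    scale_terms
        Design columns for the log within-individual variance function
        (intercept prepended).
    outcome_terms
        Individual-level design columns for the distal-outcome mean
        (intercept prepended).  Shared random effects are added on top
        according to :attr:`shared_effects`.
    knot
        Spline knot in years (change point of the age slope).
    shared_effects
        Subset of ``("location", "slope", "log_scale")`` whose individual
        random effects (u0, u1, u2) enter the outcome model with loadings
        (gamma1, gamma2, gamma3).  Empty tuple = location-scale model with a
        decoupled outcome.
    levels
        3 = readings nested in clinic visits nested in individuals, with a
        within-clinic error layer; 2 = one reading per visit, no
        within-clinic layer.
    include_outcome
        If False the outcome rows are excluded entirely (longitudinal
        submodel only).
    outcome_log
        Log-transform the outcome before analysis (the default, matching a
        positive, right-skewed outcome such as LVMI).
    """

    mean_terms: tuple[str, ...] = ("s1", "s2")
    scale_terms: tuple[str, ...] = ("age",)
    outcome_terms: tuple[str, ...] = ()
    knot: float = 12.0
    shared_effects: tuple[str, ...] = SHARED_EFFECTS
    levels: int = 3
    include_outcome: bool = True
    outcome_log: bool = True

    def __post_init__(self) -> None:
        if self.levels not in (2, 3):
            raise ValidationError(f"levels must be 2 or 3, got {self.levels}")
        unknown = set(self.shared_effects) - set(SHARED_EFFECTS)
        if unknown:
            raise ValidationError(f"unknown shared effects: {sorted(unknown)}")
        if not np.isfinite(self.knot):
            raise ValidationError("knot must be finite")

    @property
    def shares(self) -> tuple[bool, bool, bool]:
        """Booleans (location, slope, log_scale) for active loadings."""
        return tuple(e in self.shared_effects for e in SHARED_EFFECTS)

    @property
    def n_loadings(self) -> int:
        return len(self.shared_effects)


@dataclass
class Dataset:
    """Validated, linked study tables in canonical order.

    Rows are sorted by ``(individual_id, clinic_id, occasion)`` so that all
    downstream computation is invariant to the input row order.
    """

    measurements: pd.DataFrame
    clinics: pd.DataFrame
    individuals: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.measurements = self.measurements.reset_index(drop=True)
        self.clinics = self.clinics.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_clinic_visits(self) -> int:
        return len(self.clinics)

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    def write(self, directory: str | Path) -> None:
        """Serialize the three tables (CSV) plus the validation report."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(directory / "measurements.csv", index=False)
        self.clinics.to_csv(directory / "clinics.csv", index=False)
        self.individuals.to_csv(directory / "individuals.csv", index=False)
        with open(directory / "validation_report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, default=str)

    @classmethod
    def read(cls, directory: str | Path) -> "Dataset":
        directory = Path(directory)
        return load_dataset(
            directory / "measurements.csv",
            directory / "clinics.csv",
            directory / "individuals.csv",
        )


def _read_table(path_or_frame, role_map: Mapping[str, str] | None) -> pd.DataFrame:
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep=None, engine="python")
    if role_map:
        df = df.rename(columns=dict(role_map))
    return df


def _require(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {missing}")


def load_dataset(
    measurement_table,
    clinic_table,
    individual_table,
    config: str | Path | Mapping | None = None,
    require: Sequence[str] | None = None,
) -> Dataset:
    """Read, link and validate the three study tables.

    Parameters
    ----------
    measurement_table, clinic_table, individual_table
        CSV/TSV paths (header row required, delimiter sniffed) or
        already-loaded DataFrames.
    config
        Optional YAML/JSON path or mapping with per-table ``{role: column}``
        renamings under keys ``measurements``, ``clinics``, ``individuals``,
        e.g. ``{"measurements": {"value": "sbp"}}`` maps column ``sbp`` onto
        the canonical ``value`` role (mapping direction is canonical-name ->
        source column).
    require
        Individual-table columns that must be non-missing; individuals
        lacking any are dropped (complete-case) and counted in the report.

    Returns
    -------
    Dataset
        Canonically sorted tables with a validation report recording drop
        counts.
    """
    if config is not None and not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = config or {}
    inverse = {
        table: {src: canon for canon, src in mapping.items()}
        for table, mapping in config.items()
        if isinstance(mapping, Mapping)
    }

    meas = _read_table(measurement_table, inverse.get("measurements"))
    clin = _read_table(clinic_table, inverse.get("clinics"))
    indiv = _read_table(individual_table, inverse.get("individuals"))

    _require(meas, MEASUREMENT_COLUMNS, "measurement")
    _require(clin, CLINIC_COLUMNS, "clinic")
    _require(indiv, INDIVIDUAL_COLUMNS, "individual")
    if "n_pooled" not in meas.columns:
        meas["n_pooled"] = 1

    report: dict = {}

    # -- uniqueness ---------------------------------------------------------
    key = ["individual_id", "clinic_id", "occasion"]
    if meas.duplicated(key).any():
        dups = meas.loc[meas.duplicated(key), key].head(5).to_dict("records")
        raise ValidationError(f"duplicate measurement keys, e.g. {dups}")
    if clin.duplicated(["individual_id", "clinic_id"]).any():
        raise ValidationError("duplicate (individual_id, clinic_id) in clinic table")
    if indiv.duplicated(["individual_id"]).any():
        raise ValidationError("duplicate individual_id in individual table")

    # -- ranges -------------------------------------------------------------
    if not np.isfinite(meas["value"].to_numpy(float)).all():
        raise ValidationError("non-finite measurement values present")
    if (meas["n_pooled"].to_numpy() < 1).any():
        raise ValidationError("n_pooled must be >= 1")
    if (meas["occasion"].to_numpy() < 1).any():
        raise ValidationError("occasion index must be >= 1")
    if not np.isfinite(clin["age"].to_numpy(float)).all():
        raise ValidationError("non-finite ages in clinic table")

    # -- linkage ------------------------------------------------------------
    clinic_keys = set(map(tuple, clin[["individual_id", "clinic_id"]].itertuples(index=False)))
    meas_keys = set(map(tuple, meas[["individual_id", "clinic_id"]].itertuples(index=False)))
    orphans = sorted(meas_keys - clinic_keys)
    if orphans:
        raise LinkageError(f"measurements reference unknown clinic visits: {orphans[:10]}")
    known = set(indiv["individual_id"])
    orphan_clin = sorted(set(clin["individual_id"]) - known)
    if orphan_clin:
        raise LinkageError(f"clinic rows reference unknown individuals: {orphan_clin[:10]}")

    # -- complete-case drop on required individual columns ------------------
    if require:
        _require(indiv, require, "individual")
        keep = indiv[list(require)].notna().all(axis=1)
        report["individuals_dropped_incomplete"] = int((~keep).sum())
        dropped_ids = set(indiv.loc[~keep, "individual_id"])
        indiv = indiv[keep]
        clin = clin[~clin["individual_id"].isin(dropped_ids)]
        meas = meas[~meas["individual_id"].isin(dropped_ids)]

    meas = meas.sort_values(key, kind="mergesort")
    clin = clin.sort_values(["individual_id", "clinic_id"], kind="mergesort")
    indiv = indiv.sort_values("individual_id", kind="mergesort")

    report.update(
        n_individuals=len(indiv),
        n_clinic_visits=len(clin),
        n_measurements=len(meas),
    )
    return Dataset(meas, clin, indiv, report)


def spline_basis(age, knot: float):
    """Linear spline basis with a single knot.

    ``s1 = min(age, knot)`` carries the slope up to the knot and
    ``s2 = max(age - knot, 0)`` the slope beyond it, so ``s1 + s2 = age``
    for every age and the two coefficients read as per-year change below
    and above the knot.
    """
    age = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age)) or not np.isfinite(knot):
        raise ValidationError("age and knot must be finite")
    s1 = np.minimum(age, knot)
    s2 = np.maximum(age - knot, 0.0)
    return s1, s2


@dataclass
class DesignMatrices:
    """Aligned design matrices and index maps for one analysis sample.

    All continuous columns are grand-mean centered on the analysis sample
    (so intercepts read as values at the sample means), weight-type columns
    are log-transformed before centering, and sex is coded female=1.
    Interaction columns are products of the centered spline columns with
    the female indicator.
    """

    spec: ModelSpec
    # measurement level, canonical order
    y: np.ndarray                 # readings (mm Hg)
    n_pooled: np.ndarray          # readings pooled into each stored value
    measurement_visit: np.ndarray  # row index into the visit level
    # clinic-visit level
    X_mean: np.ndarray            # (n_visits, 1 + len(mean_terms))
    X_scale: np.ndarray           # (n_visits, 1 + len(scale_terms))
    z_age: np.ndarray             # centered age (random-slope design)
    visit_individual: np.ndarray  # row index into the individual level
    # individual level
    X_outcome: np.ndarray         # (n_individuals, 1 + len(outcome_terms))
    y2: np.ndarray                # outcome (log scale), NaN where missing
    outcome_observed: np.ndarray  # bool mask
    individual_ids: np.ndarray
    # bookkeeping
    mean_names: tuple[str, ...] = ()
    scale_names: tuple[str, ...] = ()
    outcome_names: tuple[str, ...] = ()
    centers: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_visits(self) -> int:
        return self.X_mean.shape[0]


_BINARY_PREFIXES = ("female", "edu_")


def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _resolve_term(frame: pd.DataFrame, term: str, centers: dict) -> np.ndarray:
    """Fetch one design column, applying log transforms and centering."""
    if term.startswith("log_"):
        base = term[4:]
        if base not in frame.columns:
            raise SchemaError(f"term '{term}' needs column '{base}'")
        raw = frame[base].to_numpy(float)
        bad = np.where(raw <= 0)[0]
        if bad.size:
            ids = frame.iloc[bad[:10]]["individual_id"].tolist()
            raise TransformError(
                f"nonpositive values in '{base}' cannot be log-transformed "
                f"(individuals {ids})"
            )
        col = np.log(raw)
    elif term in frame.columns:
        col = frame[term].to_numpy(float)
    else:
        raise SchemaError(f"unknown design term '{term}'")
    if _is_binary(pd.Series(col)) or any(term.startswith(p) for p in _BINARY_PREFIXES):
        return col
    center = float(np.mean(col))
    centers[term] = center
    return col - center


def build_design(dataset: Dataset, spec: ModelSpec) -> DesignMatrices:
    """Assemble design matrices for a model specification.

    Individuals missing any covariate required by ``spec`` (or the outcome,
    when the outcome submodel is active) are dropped, and the drop count is
    recorded — the analysis sample is complete-case per specification.
    Spline columns are computed on raw age, then grand-mean centered on the
    analysis sample; the random-slope age column is the same centered age.
    """
    meas = dataset.measurements
    clin = dataset.clinics.copy()
    indiv = dataset.individuals.copy()

    # visit frame with static covariates broadcast to visits
    visits = clin.merge(indiv.drop(columns=["outcome"], errors="ignore"),
                        on="individual_id", how="left")

    s1, s2 = spline_basis(visits["age"].to_numpy(float), spec.knot)
    visits["s1"], visits["s2"] = s1, s2

    # determine which raw columns each spec term needs, for complete-case
    def raw_needed(term: str) -> str:
        if term.startswith("log_"):
            return term[4:]
        if term.startswith("female_x_"):
            return "female"
        return term

    visit_terms = [t for t in (*spec.mean_terms, *spec.scale_terms)]
    need_visit = {raw_needed(t) for t in visit_terms
                  if raw_needed(t) in visits.columns or raw_needed(t) in ("s1", "s2", "age")}
    need_ind = {raw_needed(t) for t in spec.outcome_terms}

    ok_visit = visits.groupby("individual_id", sort=False)[sorted(need_visit)].apply(
        lambda g: g.notna().all().all()
    ) if need_visit else pd.Series(True, index=indiv["individual_id"])
    missing_cols = [c for c in sorted(need_ind) if c not in indiv.columns]
    if missing_cols:
        raise SchemaError(f"individual table is missing column(s): {missing_cols}")
    ok_ind = indiv.set_index("individual_id")[sorted(need_ind)].notna().all(axis=1) \
        if need_ind else pd.Series(True, index=indiv.set_index("individual_id").index)
    if spec.include_outcome and "outcome" not in indiv.columns:
        raise SchemaError("individual table is missing column(s): ['outcome']")

    keep_index = ok_ind.reindex(indiv["individual_id"]).fillna(True).to_numpy() & \
        ok_visit.reindex(indiv["individual_id"]).fillna(True).to_numpy()
    n_dropped = int((~keep_index).sum())
    kept_ids = indiv.loc[keep_index, "individual_id"]

    indiv = indiv[indiv["individual_id"].isin(set(kept_ids))].reset_index(drop=True)
    visits = visits[visits["individual_id"].isin(set(kept_ids))].reset_index(drop=True)
    meas = meas[meas["individual_id"].isin(set(kept_ids))].reset_index(drop=True)

    if len(indiv) == 0:
        raise ValidationError("no individuals remain after complete-case filtering")

    centers: dict = {}
    # centered age (used for the random slope and as a scale/mean term)
    age = visits["age"].to_numpy(float)
    age_center = float(np.mean(age))
    centers["age"] = age_center
    z_age = age - age_center

    column_cache: dict[str, np.ndarray] = {"age": z_age}

    def visit_column(term: str) -> np.ndarray:
        if term in column_cache:
            return column_cache[term]
        if term.startswith("female_x_"):
            base = term[len("female_x_"):]
            col = visits["female"].to_numpy(float) * visit_column(base)
        else:
            col = _resolve_term(visits, term, centers)
        column_cache[term] = col
        return col

    X_mean = np.column_stack(
        [np.ones(len(visits))] + [visit_column(t) for t in spec.mean_terms]
    )
    X_scale = np.column_stack(
        [np.ones(len(visits))] + [visit_column(t) for t in spec.scale_terms]
    )

    out_cache: dict[str, np.ndarray] = {}

    def outcome_column(term: str) -> np.ndarray:
        if term not in out_cache:
            out_cache[term] = _resolve_term(indiv, term, centers)
        return out_cache[term]

    X_outcome = np.column_stack(
        [np.ones(len(indiv))] + [outcome_column(t) for t in spec.outcome_terms]
    )

    # outcome on the log scale
    if spec.include_outcome:
        raw = indiv["outcome"].to_numpy(float)
        observed = np.isfinite(raw)
        if spec.outcome_log:
            bad = observed & (raw <= 0)
            if bad.any():
                ids = indiv.loc[bad, "individual_id"].head(10).tolist()
                raise TransformError(f"nonpositive outcome values for individuals {ids}")
            y2 = np.where(observed, np.log(np.where(observed, raw, 1.0)), np.nan)
        else:
            y2 = np.where(observed, raw, np.nan)
    else:
        y2 = np.full(len(indiv), np.nan)
        observed = np.zeros(len(indiv), dtype=bool)

    # index maps (canonical order is guaranteed by Dataset sorting)
    visit_key = pd.MultiIndex.from_frame(visits[["individual_id", "clinic_id"]])
    visit_individual = pd.Categorical(
        visits["individual_id"], categories=indiv["individual_id"]
    ).codes.astype(np.int64)
    meas_key = pd.MultiIndex.from_frame(meas[["individual_id", "clinic_id"]])
    measurement_visit = visit_key.get_indexer(meas_key).astype(np.int64)
    if (measurement_visit < 0).any():
        raise LinkageError("measurement rows without a clinic visit after filtering")

    report = dict(dataset.report)
    report["individuals_dropped_incomplete_spec"] = n_dropped
    report["analysis_n_individuals"] = len(indiv)
    report["analysis_n_visits"] = len(visits)
    report["analysis_n_measurements"] = len(meas)

    return DesignMatrices(
        spec=spec,
        y=meas["value"].to_numpy(float),
        n_pooled=meas["n_pooled"].to_numpy(float),
        measurement_visit=measurement_visit,
        X_mean=X_mean,
        X_scale=X_scale,
        z_age=z_age,
        visit_individual=visit_individual,
        X_outcome=X_outcome,
        y2=y2,
        outcome_observed=observed,
        individual_ids=indiv["individual_id"].to_numpy(),
        mean_names=("intercept", *spec.mean_terms),
        scale_names=("intercept", *spec.scale_terms),
        outcome_names=("intercept", *spec.outcome_terms),
        centers=centers,
        report=report,
    )
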