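import warnings

import numpy as np
import pandas as pd
import pytest

from melsjm import GeneratorConfig, build_design, simulate
from melsjm.synthetic_data import model_a_params, model_a_spec

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three individuals, two clinics of two readings each, reduced model."""
    cfg = GeneratorConfig(
        n_individuals=3,
        clinic_ages=(8.0, 12.0),
        reps_per_clinic=(2, 2),
        attendance=False,
        attendance_logit=(5.0, 5.0),
        spec=model_a_spec(),
        true_params=model_a_params(),
        seed=7,
    )
    dataset, truth = simulate(cfg)
    design = build_design(dataset, cfg.spec)
    return cfg, dataset, design, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Fifty individuals under the reduced (age + sex) specification."""
    cfg = GeneratorConfig(
        n_individuals=50,
        spec=model_a_spec(),
        true_params=model_a_params(),
        seed=21,
    )
    dataset, truth = simulate(cfg)
    design = build_design(dataset, cfg.spec)
    return cfg, dataset, design, truth


def manual_tables(ages, values, age_center_target=None, outcome=2.0):
    """One-individual tables with one reading per clinic at given ages."""
    n = len(ages)
    meas = pd.DataFrame({
        "individual_id": [1] * n,
        "clinic_id": list(range(1, n + 1)),
        "occasion": [1] * n,
        "value": values,
    })
    clin = pd.DataFrame({
        "individual_id": [1] * n,
        "clinic_id": list(range(1, n + 1)),
        "age": ages,
    })
    indiv = pd.DataFrame({"individual_id": [1], "outcome": [outcome]})
    return meas, clin, indiv
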