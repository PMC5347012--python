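"""Shared fixtures: schemas, synthetic cohorts, and a fitted reference model."""

import numpy as np
import pytest

from dsindex import default_schema, fit_severity_model
from dsindex.schema import ROISchema
from dsindex.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_schema():
    """A 6-feature schema for hand-checkable examples."""
    return ROISchema.from_rows([
        ("lh_entorhinal_thickness", "thickness", "left"),
        ("rh_entorhinal_thickness", "thickness", "right"),
        ("lh_precuneus_volume", "volume", "left"),
        ("rh_precuneus_volume", "volume", "right"),
        ("Left-Hippocampus", "volume", "left"),
        ("Right-Hippocampus", "volume", "right"),
    ])


@pytest.fixture(scope="session")
def cohort_seed1(schema):
    """Default-condition synthetic cohort (69/86/45/38, |d| = 2.5), seed 1."""
    return generate_cohort(SimulationConfig(seed=1), schema)


@pytest.fixture(scope="session")
def fitted_seed1(schema, cohort_seed1):
    """Discriminant model and CV result trained on the seed-1 cohort."""
    return fit_severity_model(cohort_seed1, schema, disease="AD", control="HC",
                              folds=7, n_orth="auto", seed=1)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
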