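"""Shared fixtures.

The expensive artifacts — the trained model bundle and the evaluation
cohorts — are session-scoped and shared across module and acceptance
tests so the suite stays within a desk-scale runtime.
"""

import warnings

import numpy as np
import pytest

from emibrain.core import (AntennaArray, FrequencySweep, ImageGrid,
                           PropagationModel)
from emibrain.pipeline import PipelineConfig, train_models
from emibrain.synthetic import forward_scatter, generate_cohort, make_phantom

warnings.filterwarnings("ignore", category=UserWarning)

BALANCED_MIX = {"healthy": 1 / 3, "ICH": 1 / 3, "IS": 1 / 3}


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def array(config):
    return config.array


@pytest.fixture(scope="session")
def sweep(config):
    return config.sweep


@pytest.fixture(scope="session")
def grid(config):
    return config.grid


@pytest.fixture(scope="session")
def prop(config):
    return config.prop


@pytest.fixture(scope="session")
def models(config):
    """Trained bundle at the default study size (seeded)."""
    return train_models(seed=1, config=config)


@pytest.fixture(scope="session")
def default_cohort(config):
    """Held-out default cohort: n=60 balanced, 20 scans, SNR 30 dB."""
    cohort, manifest = generate_cohort(
        60, BALANCED_MIX, seed=5000, sweep=config.sweep, grid=config.grid,
        array=config.array, prop=config.prop)
    return cohort, manifest


@pytest.fixture(scope="session")
def localization_cohort(config):
    """50 phantoms, balanced, SNR 30 dB, inclusion radius >= 10 mm."""
    cohort, _ = generate_cohort(
        50, BALANCED_MIX, seed=1000, sweep=config.sweep, grid=config.grid,
        array=config.array, prop=config.prop,
        radius_range=(0.010, 0.025))
    return cohort


@pytest.fixture(scope="session")
def default_cohort_workups(default_cohort, models, config):
    """Per-patient workups of the held-out default cohort (feature
    vectors plus the pipeline inputs the DMM typing check needs)."""
    from emibrain.pipeline import patient_workup

    cohort, _ = default_cohort
    return [(p, patient_workup(p, models.boundary, config))
            for p in cohort]


@pytest.fixture(scope="session")
def healthy_forward(config):
    """Noise-free healthy phantom and its forward dataset."""
    ph = make_phantom(11, "healthy", grid=config.grid, prop=config.prop)
    ds = forward_scatter(ph, config.array, config.sweep, config.prop)
    return ph, ds


@pytest.fixture(scope="session")
def ich_forward(config):
    """Noise-free hemorrhagic phantom and its forward dataset."""
    ph = make_phantom(5, "ICH", grid=config.grid, prop=config.prop)
    ds = forward_scatter(ph, config.array, config.sweep, config.prop)
    return ph, ds
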