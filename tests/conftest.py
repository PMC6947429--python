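"""Shared fixtures: small simulated cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from pkrrf.cohort import PopulationConfig, generate_validation_fixture, simulate_cohort
from pkrrf.kinetics import DialysisPrescription, KineticParameters


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 240-patient simulated cohort shared across model tests."""
    cfg = PopulationConfig(cohort_size=240, seed=20240)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def validation_fixture() -> pd.DataFrame:
    """A 120-row synthetic external-validation table (complete rows only)."""
    fx = generate_validation_fixture(n=120, seed=977,
                                     postb2m_available_fraction=1.0)
    return fx.reset_index(drop=True)


@pytest.fixture
def typical_params() -> KineticParameters:
    return KineticParameters(
        generation_rate=0.16, total_volume=15.0, plasma_fraction=0.33,
        intercompartmental_clearance=60.0, extrarenal_clearance=3.0,
        residual_renal_clearance=2.0, body_weight=75.0)


@pytest.fixture
def typical_rx() -> DialysisPrescription:
    return DialysisPrescription(modality="HD", dialyzer_clearance=40.0,
                                session_duration=240.0, uf_volume=2.5)


def random_params(rng: np.random.Generator) -> KineticParameters:
    """A random physically valid parameter set for property tests."""
    return KineticParameters(
        generation_rate=float(rng.uniform(0.05, 0.4)),
        total_volume=float(rng.uniform(8.0, 25.0)),
        plasma_fraction=float(rng.uniform(0.2, 0.5)),
        intercompartmental_clearance=float(rng.uniform(20.0, 150.0)),
        extrarenal_clearance=float(rng.uniform(0.5, 8.0)),
        residual_renal_clearance=float(rng.uniform(0.0, 10.0)),
        body_weight=float(rng.uniform(45.0, 120.0)))
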