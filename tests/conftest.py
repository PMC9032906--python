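import numpy as np
import pytest

from linezolid_mipd import (
    DoseEvent,
    PatientCovariates,
    PopulationParameters,
    RandomEffects,
    derive_individual_parameters,
)


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    return PopulationParameters()


@pytest.fixture(scope="session")
def typical_cov() -> PatientCovariates:
    return PatientCovariates(WT=70.0, SEX=0, HIV=0, PGP=0, MIC=0.25)


@pytest.fixture(scope="session")
def typical_ind(pop, typical_cov):
    return derive_individual_parameters(pop, typical_cov, RandomEffects())


@pytest.fixture()
def qd600_doses():
    """600 mg once daily for 15 days."""
    return [DoseEvent(24.0 * k, 600.0) for k in range(15)]


def random_individual(rng: np.random.Generator, pop: PopulationParameters):
    """A plausible random parameter draw for oracle comparisons."""
    cov = PatientCovariates(
        WT=float(rng.uniform(36.0, 88.0)),
        SEX=int(rng.integers(0, 2)),
        HIV=int(rng.random() < 0.1),
        PGP=int(rng.random() < 0.1),
        MIC=0.25,
    )
    re = RandomEffects(
        eta_CL=float(rng.normal(0.0, pop.omega_CL)),
        eta_MTT=float(rng.normal(0.0, pop.omega_MTT)),
        kappa={
            "CL": (float(rng.normal(0.0, pop.pi_CL)),),
            "V": (float(rng.normal(0.0, pop.pi_V)),),
            "ka": (float(rng.normal(0.0, pop.pi_ka)),),
            "MTT": (float(rng.normal(0.0, pop.pi_MTT)),),
        },
    )
    return derive_individual_parameters(pop, cov, re, occasion=1), cov, re
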