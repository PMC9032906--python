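"""Virtual patient cohorts: covariates, MIC values and true random effects.

The generator stands in for resampling a real TDM population whose
individual-level data are unavailable.  Covariate marginals emulate the
original cohort summaries: bodyweight truncated-normal with mean 61.2 kg
on [35.3, 88.9] kg, 54.5% male, 7.1% HIV co-infected.  Two quantities the
source population never reported are documented assumptions and fully
configurable: P-gp-inhibitor co-medication prevalence (default 10%) and
the MIC distribution over two-fold dilution steps (default centred so a
typical patient on 600 mg QD meets the efficacy target at MIC <= 0.5 mg/L).
Covariates are sampled independently (no joint structure is recoverable
from the published summaries).

Alternatively, ``generate_cohort`` bootstraps rows from a user-supplied
covariate table — the mechanism used in the original analysis — when real
patient-level data are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .params import IOV_PARAMETERS, PatientCovariates, PopulationParameters, \
    RandomEffects

__all__ = ["CohortConfig", "VirtualPatient", "generate_cohort",
           "sample_random_effects", "cohort_table"]

#: Assumed MIC distribution over two-fold dilutions (configurable; the
#: source population's MIC distribution was never reported).
DEFAULT_MIC_DISTRIBUTION: dict[float, float] = {
    0.125: 0.10, 0.25: 0.40, 0.5: 0.40, 1.0: 0.10,
}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 1000
    weight_mean: float = 61.2
    weight_sd: float = 12.0
    weight_bounds: tuple[float, float] = (35.3, 88.9)
    male_fraction: float = 0.545
    hiv_fraction: float = 0.071
    pgp_fraction: float = 0.10
    mic_distribution: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MIC_DISTRIBUTION))
    n_occasions: int = 3

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        lo, hi = self.weight_bounds
        if not (0 < lo < hi):
            raise ValueError("invalid weight bounds")
        if self.weight_sd <= 0:
            raise ValueError("weight SD must be > 0")
        for name in ("male_fraction", "hiv_fraction", "pgp_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        w = self.mic_distribution
        if not w or any(p < 0 for p in w.values()) or any(m <= 0 for m in w):
            raise ValueError("MIC distribution needs positive MICs and "
                             "nonnegative weights")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("MIC weights must sum to 1")


@dataclass(frozen=True)
class VirtualPatient:
    patient_id: int
    covariates: PatientCovariates
    effects: RandomEffects


def sample_random_effects(
    pop: PopulationParameters,
    n_occasions: int,
    rng: np.random.Generator | int,
) -> RandomEffects:
    """Draw IIV etas and per-occasion IOV kappas, all independent normals
    on the log scale (exponential random-effect model)."""
    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    eta_CL = rng.normal(0.0, pop.omega_CL)
    eta_MTT = rng.normal(0.0, pop.omega_MTT)
    pis = {"CL": pop.pi_CL, "V": pop.pi_V, "ka": pop.pi_ka, "MTT": pop.pi_MTT}
    kappa = {name: tuple(rng.normal(0.0, pis[name], n_occasions))
             for name in IOV_PARAMETERS}
    return RandomEffects(eta_CL=eta_CL, eta_MTT=eta_MTT, kappa=kappa)


def _sample_covariates(config: CohortConfig, rng: np.random.Generator
                       ) -> PatientCovariates:
    lo, hi = config.weight_bounds
    a = (lo - config.weight_mean) / config.weight_sd
    b = (hi - config.weight_mean) / config.weight_sd
    wt = float(truncnorm.rvs(a, b, loc=config.weight_mean,
                             scale=config.weight_sd, random_state=rng))
    sex = int(rng.random() >= config.male_fraction)  # 1 = female
    hiv = int(rng.random() < config.hiv_fraction)
    pgp = int(rng.random() < config.pgp_fraction)
    mics = sorted(config.mic_distribution)
    probs = np.array([config.mic_distribution[m] for m in mics])
    mic = float(rng.choice(mics, p=probs / probs.sum()))
    return PatientCovariates(WT=wt, SEX=sex, HIV=hiv, PGP=pgp, MIC=mic)


def generate_cohort(
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
    covariate_table: pd.DataFrame | None = None,
    pop: PopulationParameters | None = None,
) -> list[VirtualPatient]:
    """Generate ``config.n_patients`` virtual patients, reproducibly.

    With ``covariate_table`` given (columns WT, SEX, HIV, PGP, MIC, one row
    per patient), covariate vectors are bootstrapped jointly from its rows
    instead of sampled from the parametric marginals; random effects are
    always drawn fresh.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(int(seed)))
    pop = pop or PopulationParameters()
    if covariate_table is not None:
        required = ["WT", "SEX", "HIV", "PGP", "MIC"]
        missing = [c for c in required if c not in covariate_table.columns]
        if missing:
            raise ValueError(f"covariate table lacks columns {missing}")
        rows = covariate_table[required].to_numpy(dtype=float)
    patients = []
    for i in range(config.n_patients):
        if covariate_table is None:
            cov = _sample_covariates(config, rng)
        else:
            r = rows[rng.integers(0, len(rows))]
            cov = PatientCovariates(WT=float(r[0]), SEX=int(r[1]),
                                    HIV=int(r[2]), PGP=int(r[3]),
                                    MIC=float(r[4]))
        effects = sample_random_effects(pop, config.n_occasions, rng)
        patients.append(VirtualPatient(patient_id=i, covariates=cov,
                                       effects=effects))
    return patients


def cohort_table(patients: list[VirtualPatient]) -> pd.DataFrame:
    """Covariate table (one row per patient) for export or bootstrapping."""
    return pd.DataFrame(
        {
            "ID": [p.patient_id for p in patients],
            "WT": [p.covariates.WT for p in patients],
            "SEX": [p.covariates.SEX for p in patients],
            "HIV": [p.covariates.HIV for p in patients],
            "PGP": [p.covariates.PGP for p in patients],
            "MIC": [p.covariates.MIC for p in patients],
        }
    )
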