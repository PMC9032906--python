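"""Population and individual pharmacokinetic parameters.

The structural model is a one-compartment disposition model with transit
absorption (five transit compartments feeding an absorption compartment)
and concentration- and time-dependent auto-inhibition of clearance driven
by an empirical inhibition compartment.  Population values default to the
final model estimates for linezolid in adults treated for drug-resistant
tuberculosis: apparent clearance and volume are allometrically scaled to
70 kg (exponents 0.75 and 1), HIV co-infection raises CL/F by 43%, female
sex raises ka by 95%, and P-gp inhibitor co-medication raises the mean
transit time by 96%.  Inter-individual variability (IIV) acts on CL and
MTT, inter-occasion variability (IOV) on CL, V, ka and MTT; both are
exponential (log-normal individual parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "PopulationParameters",
    "PatientCovariates",
    "RandomEffects",
    "IndividualParameters",
    "derive_individual_parameters",
    "transit_rate",
    "clearance_multiplier",
]

# Names of the four parameters carrying inter-occasion variability.
IOV_PARAMETERS = ("CL", "V", "ka", "MTT")


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variance components and constants of the model.

    Units: clearances L/h, volumes L, rate constants 1/h, times h,
    concentrations mg/L.  ``CL_pop`` and ``V_pop`` refer to a 70 kg
    reference patient; random-effect magnitudes are standard deviations
    on the log scale (exponential model).
    """

    CL_pop: float = 6.3          # apparent uninhibited clearance, L/h/70 kg
    V_pop: float = 50.6          # apparent central volume, L/70 kg
    ka_pop: float = 1.8          # absorption rate constant, 1/h
    MTT_pop: float = 0.53        # mean transit time, h
    NN: int = 5                  # number of transit compartments
    kIC: float = 0.0005          # rate constant into inhibition compartment, 1/h (fixed)
    IC50: float = 0.38           # inhibition-compartment conc at half-max inhibition, mg/L (fixed)
    RCLF: float = 0.798          # remaining clearance fraction at full inhibition
    beta_HIV_CL: float = 0.43    # fractional increase of CL/F with HIV co-infection
    beta_SEX_ka: float = 0.95    # fractional increase of ka for females
    beta_PGP_MTT: float = 0.96   # fractional increase of MTT with P-gp inhibitors
    allo_CL: float = 0.75        # allometric exponent on CL (fixed)
    allo_V: float = 1.0          # allometric exponent on V (fixed)
    WT_ref: float = 70.0         # reference bodyweight, kg
    omega_CL: float = 0.26       # IIV SD on CL
    omega_MTT: float = 0.62      # IIV SD on MTT
    pi_CL: float = 0.27          # IOV SD on CL
    pi_V: float = 0.26           # IOV SD on V
    pi_ka: float = 0.93          # IOV SD on ka
    pi_MTT: float = 0.69         # IOV SD on MTT
    sigma_prop: float = 0.054    # proportional residual SD (fraction)
    sigma_add: float = 0.53      # additive residual SD, mg/L
    fu: float = 0.69             # unbound fraction
    LLOQ: float = 0.05           # lower limit of quantification, mg/L

    def __post_init__(self) -> None:
        positive = (
            "CL_pop", "V_pop", "ka_pop", "MTT_pop", "kIC", "IC50", "WT_ref",
            "sigma_add", "fu", "LLOQ",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0 < self.RCLF <= 1):
            raise ValueError(f"RCLF must lie in (0, 1], got {self.RCLF}")
        if not (0 < self.fu <= 1):
            raise ValueError(f"fu must lie in (0, 1], got {self.fu}")
        if self.NN < 1 or int(self.NN) != self.NN:
            raise ValueError(f"NN must be a positive integer, got {self.NN}")
        for name in ("omega_CL", "omega_MTT", "pi_CL", "pi_V", "pi_ka",
                     "pi_MTT", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes) -> "PopulationParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class PatientCovariates:
    """Covariates entering the final model, plus the pathogen MIC.

    ``SEX`` is the female indicator (1 = female), ``HIV`` the co-infection
    indicator and ``PGP`` the P-gp-inhibitor co-medication indicator.
    """

    WT: float
    SEX: int = 0
    HIV: int = 0
    PGP: int = 0
    MIC: float = 0.25

    def __post_init__(self) -> None:
        if self.WT <= 0:
            raise ValueError(f"bodyweight must be > 0, got {self.WT}")
        if self.MIC <= 0:
            raise ValueError(f"MIC must be > 0, got {self.MIC}")
        for name in ("SEX", "HIV", "PGP"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class RandomEffects:
    """IIV etas and per-occasion IOV kappas (log-scale deviates).

    ``kappa[name]`` is a tuple with one entry per occasion, occasion
    indices starting at 1 (``kappa['CL'][occ-1]``).  Occasions beyond the
    stored tuples take the population-typical value kappa = 0.
    """

    eta_CL: float = 0.0
    eta_MTT: float = 0.0
    kappa: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.eta_CL, self.eta_MTT):
            if not math.isfinite(v):
                raise ValueError("etas must be finite")
        for name, vals in self.kappa.items():
            if name not in IOV_PARAMETERS:
                raise ValueError(f"unknown IOV parameter {name!r}")
            if not all(math.isfinite(v) for v in vals):
                raise ValueError(f"kappa[{name!r}] contains non-finite values")

    def kappa_for(self, name: str, occasion: int) -> float:
        """Kappa of ``name`` at 1-based ``occasion`` (0 when unavailable)."""
        vals = self.kappa.get(name, ())
        if occasion < 1:
            raise ValueError("occasion indices start at 1")
        return float(vals[occasion - 1]) if occasion <= len(vals) else 0.0

    @property
    def n_occasions(self) -> int:
        return max((len(v) for v in self.kappa.values()), default=0)


@dataclass(frozen=True)
class IndividualParameters:
    """Realized parameters of one patient on one occasion."""

    CL: float
    V: float
    ka: float
    MTT: float
    ktr: float

    def __post_init__(self) -> None:
        for name in ("CL", "V", "ka", "MTT", "ktr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def transit_rate(MTT: float, NN: int) -> float:
    """Transit rate constant k_tr = (NN + 1) / MTT (1/h)."""
    if MTT <= 0:
        raise ValueError(f"MTT must be > 0, got {MTT}")
    return (NN + 1) / MTT


def clearance_multiplier(Ci: float, RCLF: float, IC50: float) -> float:
    """Fractional clearance remaining at inhibition-compartment conc ``Ci``.

    RCLF + (1 - RCLF) * (1 - Ci / (IC50 + Ci)): equals 1 with no drug in
    the inhibition compartment and falls monotonically to RCLF as Ci grows.
    """
    if Ci < 0:
        raise ValueError(f"Ci must be >= 0, got {Ci}")
    return RCLF + (1.0 - RCLF) * (1.0 - Ci / (IC50 + Ci))


def derive_individual_parameters(
    pop: PopulationParameters,
    cov: PatientCovariates,
    re: RandomEffects | None = None,
    occasion: int = 1,
) -> IndividualParameters:
    """Combine fixed effects, covariates and random effects for one occasion.

    CL  = CL_pop * (WT/70)^0.75 * (1 + 0.43*HIV) * exp(eta_CL + kappa_CL)
    V   = V_pop  * (WT/70)^1                     * exp(kappa_V)
    ka  = ka_pop * (1 + 0.95*SEX)                * exp(kappa_ka)
    MTT = MTT_pop* (1 + 0.96*PGP)                * exp(eta_MTT + kappa_MTT)
    ktr = (NN + 1) / MTT

    Occasions without stored kappas use kappa = 0 (population-typical
    occasion), the convention used for forecasting future occasions.
    """
    re = re or RandomEffects()
    wt_frac = cov.WT / pop.WT_ref
    CL = (pop.CL_pop * wt_frac ** pop.allo_CL * (1 + pop.beta_HIV_CL * cov.HIV)
          * math.exp(re.eta_CL + re.kappa_for("CL", occasion)))
    V = pop.V_pop * wt_frac ** pop.allo_V * math.exp(re.kappa_for("V", occasion))
    ka = (pop.ka_pop * (1 + pop.beta_SEX_ka * cov.SEX)
          * math.exp(re.kappa_for("ka", occasion)))
    MTT = (pop.MTT_pop * (1 + pop.beta_PGP_MTT * cov.PGP)
           * math.exp(re.eta_MTT + re.kappa_for("MTT", occasion)))
    return IndividualParameters(CL=CL, V=V, ka=ka, MTT=MTT,
                                ktr=transit_rate(MTT, pop.NN))
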