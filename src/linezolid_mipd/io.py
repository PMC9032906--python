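"""Dataset and configuration IO.

TDM datasets follow the NONMEM rectangular convention, the de facto
interoperability format of the field: one row per dose or observation,
columns ID, TIME (h), AMT (mg, dose rows), DV (mg/L, observation rows),
EVID (1 = dose, 0 = observation), MDV (1 = missing DV), OCC (sampling
occasion) plus the covariate columns WT, SEX, HIV, PGP and MIC.  Time is
in hours, concentrations in mg/L and doses in mg throughout.

``RunConfig`` validates a structured YAML/dict configuration (unknown keys
rejected) and materializes the population, cohort, workflow and target
objects for a reproducible run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .cohort import CohortConfig
from .exposure import DosingRegimen, ObservationRecord
from .forecast import ObservationSet
from .mipd import TargetSpec, WorkflowConfig
from .model import DoseEvent
from .params import PatientCovariates, PopulationParameters

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "observation_set_from_dataset",
    "dataset_from_observation_set",
    "RunConfig",
]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV", "OCC",
                    "WT", "SEX", "HIV", "PGP", "MIC")


def validate_dataset(df: pd.DataFrame) -> None:
    """Schema validation; error messages name the offending rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset lacks required columns {missing}")
    problems: list[str] = []
    numeric = df[list(REQUIRED_COLUMNS)].apply(
        lambda c: pd.to_numeric(c, errors="coerce"))
    may_be_nan = {"DV", "AMT"}
    for col in REQUIRED_COLUMNS:
        bad = numeric[col].isna() & ~(df[col].isna() & (col in may_be_nan))
        for i in df.index[bad]:
            problems.append(f"row {i}: non-numeric {col}={df.at[i, col]!r}")
    if not problems:
        for pid, grp in numeric.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                where = grp.index[1:][np.diff(t) < 0]
                problems.append(
                    f"ID {pid:g}: TIME not sorted at row(s) {list(where)}")
        dose_rows = numeric["EVID"] == 1
        for i in df.index[dose_rows & ~(numeric["AMT"] > 0)]:
            problems.append(f"row {i}: dose row needs AMT > 0")
        for i in df.index[dose_rows & numeric["DV"].notna()]:
            problems.append(f"row {i}: dose row must not carry a DV")
        obs_rows = numeric["EVID"] == 0
        bad_obs = obs_rows & ~((numeric["DV"] >= 0) | (numeric["MDV"] == 1))
        for i in df.index[bad_obs]:
            problems.append(f"row {i}: observation needs DV >= 0 or MDV = 1")
    if problems:
        raise ValueError("invalid TDM dataset:\n  " + "\n  ".join(problems))


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a NONMEM-convention TDM CSV."""
    df = pd.read_csv(path, comment="#")
    validate_dataset(df)
    return df


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a TDM dataset; round-trips losslessly."""
    validate_dataset(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _infer_occasion_windows(obs: pd.DataFrame) -> dict[int, tuple[float, float]]:
    """Each occasion spans from its first record to the next occasion's
    first record; the last occasion's window closes just after its last
    record (kappa = 0 applies beyond, the forecasting convention)."""
    starts = obs.groupby("OCC")["TIME"].min().sort_index()
    ends = obs.groupby("OCC")["TIME"].max().sort_index()
    occs = list(starts.index)
    windows = {}
    for i, occ in enumerate(occs):
        start = float(starts.iloc[i])
        end = (float(starts.iloc[i + 1]) if i + 1 < len(occs)
               else float(ends.iloc[i]) + 1e-6)
        windows[int(occ)] = (start, end)
    return windows


def observation_set_from_dataset(
    df: pd.DataFrame,
    pop: PopulationParameters,
    patient_id: float | None = None,
) -> ObservationSet:
    """Build one patient's ``ObservationSet`` from a validated dataset.

    Below-LLOQ observations get the LLOQ/2 substitution; samples at or
    before the first dose are flagged unusable.  MDV = 1 observation rows
    are dropped.
    """
    validate_dataset(df)
    ids = df["ID"].unique()
    if patient_id is None:
        if len(ids) > 1:
            raise ValueError(f"dataset holds {len(ids)} patients; pass "
                             "patient_id")
        patient_id = ids[0]
    sub = df[df["ID"] == patient_id]
    if sub.empty:
        raise ValueError(f"no rows for ID {patient_id}")
    doses = tuple(DoseEvent(float(r.TIME), float(r.AMT))
                  for r in sub[sub["EVID"] == 1].itertuples())
    if not doses:
        raise ValueError(f"ID {patient_id}: no dose rows")
    first_dose = min(d.time for d in doses)
    obs = sub[(sub["EVID"] == 0) & (sub["MDV"] != 1)]
    records = []
    for r in obs.itertuples():
        value = float(r.DV)
        blq = value < pop.LLOQ
        records.append(ObservationRecord(
            time_h=float(r.TIME), value=value, occasion=int(r.OCC),
            blq_flag=blq,
            value_for_fit=pop.LLOQ / 2.0 if blq else value,
            usable=float(r.TIME) > first_dose))
    row = sub.iloc[0]
    cov = PatientCovariates(WT=float(row["WT"]), SEX=int(row["SEX"]),
                            HIV=int(row["HIV"]), PGP=int(row["PGP"]),
                            MIC=float(row["MIC"]))
    windows = (_infer_occasion_windows(obs) if len(obs) else {})
    return ObservationSet(records=tuple(records), doses=doses,
                          covariates=cov, occasion_windows=windows)


def dataset_from_observation_set(obs: ObservationSet,
                                 patient_id: int = 1) -> pd.DataFrame:
    """Serialize one patient's doses and observations to dataset rows."""
    cov = obs.covariates
    base = dict(ID=patient_id, WT=cov.WT, SEX=cov.SEX, HIV=cov.HIV,
                PGP=cov.PGP, MIC=cov.MIC)
    rows = []
    for d in obs.doses:
        rows.append(dict(base, TIME=d.time, AMT=d.amount, DV=np.nan,
                         EVID=1, MDV=1, OCC=0))
    for r in obs.records:
        rows.append(dict(base, TIME=r.time_h, AMT=np.nan, DV=r.value,
                         EVID=0, MDV=0, OCC=r.occasion))
    df = pd.DataFrame(rows, columns=["ID", "TIME", "AMT", "DV", "EVID",
                                     "MDV", "OCC", "WT", "SEX", "HIV",
                                     "PGP", "MIC"])
    df = df.sort_values(["TIME", "EVID"], kind="stable",
                        ascending=[True, False]).reset_index(drop=True)
    # dose rows carry OCC of the enclosing occasion only for readability
    return df


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationBlock(_Block):
    """Optional overrides of the default population parameters."""

    CL_pop: float | None = None
    V_pop: float | None = None
    ka_pop: float | None = None
    MTT_pop: float | None = None
    NN: int | None = None
    kIC: float | None = None
    IC50: float | None = None
    RCLF: float | None = None
    beta_HIV_CL: float | None = None
    beta_SEX_ka: float | None = None
    beta_PGP_MTT: float | None = None
    allo_CL: float | None = None
    allo_V: float | None = None
    WT_ref: float | None = None
    omega_CL: float | None = None
    omega_MTT: float | None = None
    pi_CL: float | None = None
    pi_V: float | None = None
    pi_ka: float | None = None
    pi_MTT: float | None = None
    sigma_prop: float | None = None
    sigma_add: float | None = None
    fu: float | None = None
    LLOQ: float | None = None


class CohortBlock(_Block):
    n_patients: int = 1000
    weight_mean: float = 61.2
    weight_sd: float = 12.0
    weight_bounds: tuple[float, float] = (35.3, 88.9)
    male_fraction: float = 0.545
    hiv_fraction: float = 0.071
    pgp_fraction: float = 0.10
    mic_distribution: dict[float, float] = {0.125: 0.10, 0.25: 0.40,
                                            0.5: 0.40, 1.0: 0.10}
    n_occasions: int = 3


class RegimenBlock(_Block):
    dose_mg: float = 600.0
    interval_h: float = 24.0


class WorkflowBlock(_Block):
    initial_regimen: RegimenBlock = RegimenBlock()
    occasion_days: tuple[int, ...] = (1, 8, 15)
    sparse_times: tuple[float, ...] = (0.0, 2.0, 5.0)
    rich_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0,
                                     12.0, 24.0)
    dose_change_lag_days: int = 7
    window_start_day: int = 28


class TargetBlock(_Block):
    efficacy_threshold: float = 119.0
    safety_threshold: float = 1.38


class RunConfig(_Block):
    """Validated run configuration (unknown keys rejected)."""

    seed: int = 0
    population: PopulationBlock = PopulationBlock()
    cohort: CohortBlock = CohortBlock()
    workflow: WorkflowBlock = WorkflowBlock()
    targets: TargetBlock = TargetBlock()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def population_parameters(self) -> PopulationParameters:
        overrides = {k: v for k, v in self.population.model_dump().items()
                     if v is not None}
        if "NN" in overrides:
            overrides["NN"] = int(overrides["NN"])
        return PopulationParameters(**overrides)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**self.cohort.model_dump())

    def workflow_config(self) -> WorkflowConfig:
        wf = self.workflow
        return WorkflowConfig(
            initial_regimen=DosingRegimen(wf.initial_regimen.dose_mg,
                                          wf.initial_regimen.interval_h),
            occasion_days=wf.occasion_days,
            sparse_times=wf.sparse_times,
            rich_times=wf.rich_times,
            dose_change_lag_days=wf.dose_change_lag_days,
            window_start=(wf.window_start_day - 1) * 24.0,
            targets=TargetSpec(self.targets.efficacy_threshold,
                               self.targets.safety_threshold),
        )
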