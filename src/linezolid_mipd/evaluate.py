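"""Cohort-level evaluation: accuracy metrics, attainment, study orchestration.

Predicted exposure (from the MAP forecast that chose each dose) is judged
against the truth-model exposure under the same regimen with the relative
bias and relative root-mean-squared error

    rBias  = mean( (pred - obs) / ((pred + obs)/2) ) * 100
    rRMSE  = sqrt(mean( ((pred - obs) / ((pred + obs)/2))^2 )) * 100

and dose selection against the true individual dose with the relative
dose prediction error rDPE = (predicted_DD - true_DD) / true_DD * 100,
where DD is the total daily dose.  Attainment classifies each patient's
truth-model exposure into {both, efficacy_only, safety_only, neither}
under the strict-threshold targets, per dosing policy (flat 600 mg QD and
the MIPD recommendation after one, two or three sampling occasions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort
from .exposure import ExposureMetrics
from .mipd import (
    DoseDecision,
    PatientTrajectory,
    TargetSpec,
    WorkflowConfig,
    derive_true_dose,
    run_adaptive_workflow,
)
from .params import PopulationParameters

__all__ = [
    "rbias",
    "rrmse",
    "rdpe",
    "classify_attainment",
    "AccuracyMetrics",
    "AttainmentSummary",
    "EvaluationReport",
    "summarize_cohort",
    "run_cohort_study",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("both", "efficacy_only", "safety_only", "neither")


def _relative_errors(predicted, observed) -> np.ndarray:
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("predicted and observed must be equal-length "
                         "1-d vectors with at least one entry")
    mean = (pred + obs) / 2.0
    bad = mean == 0.0
    if np.any(bad):
        logger.warning("dropping %d pair(s) with zero pair-mean", bad.sum())
        if np.all(bad):
            raise ValueError("all pairs have zero pair-mean")
    return (pred[~bad] - obs[~bad]) / mean[~bad]


def rbias(predicted, observed) -> float:
    """Relative bias in percent (antisymmetric in pred/obs)."""
    return float(np.mean(_relative_errors(predicted, observed)) * 100.0)


def rrmse(predicted, observed) -> float:
    """Relative root-mean-squared error in percent (>= |rbias|)."""
    return float(np.sqrt(np.mean(_relative_errors(predicted, observed) ** 2))
                 * 100.0)


def rdpe(predicted_dd: float, true_dd: float) -> float:
    """Relative dose prediction error in percent of the true daily dose."""
    if true_dd <= 0:
        raise ValueError(f"true daily dose must be > 0, got {true_dd}")
    return (predicted_dd - true_dd) / true_dd * 100.0


def classify_attainment(metrics: ExposureMetrics,
                        targets: TargetSpec | None = None) -> str:
    """One of 'both', 'efficacy_only', 'safety_only', 'neither'."""
    targets = targets or TargetSpec()
    eff = targets.efficacy_met(metrics)
    safe = targets.safety_met(metrics)
    if eff and safe:
        return "both"
    if eff:
        return "efficacy_only"
    if safe:
        return "safety_only"
    return "neither"


@dataclass(frozen=True)
class AccuracyMetrics:
    """rBias/rRMSE (%) of one predicted metric at one occasion count."""

    metric: str
    occasions: int
    rbias: float
    rrmse: float

    def __post_init__(self) -> None:
        if self.rrmse < 0 or self.rrmse + 1e-9 < abs(self.rbias):
            raise ValueError("rRMSE must be >= |rBias| >= 0")


@dataclass(frozen=True)
class AttainmentSummary:
    """Fractions of the cohort per attainment category for one policy."""

    policy: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.fractions) != set(CATEGORIES):
            raise ValueError(f"fractions must cover {CATEGORIES}")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")

    @property
    def both(self) -> float:
        return self.fractions["both"]


@dataclass(frozen=True)
class EvaluationReport:
    """Cohort study outcome plus the metadata needed to regenerate it."""

    attainment: tuple[AttainmentSummary, ...]
    accuracy: tuple[AccuracyMetrics, ...]
    rdpe_by_occasions: dict[int, tuple[float, ...]]
    qd_fraction: float
    n_patients: int
    seed: int
    config_hash: str
    patient_table: pd.DataFrame = field(repr=False)

    def attainment_both(self, policy: str) -> float:
        for a in self.attainment:
            if a.policy == policy:
                return a.both
        raise KeyError(policy)

    def accuracy_for(self, metric: str, occasions: int) -> AccuracyMetrics:
        for a in self.accuracy:
            if a.metric == metric and a.occasions == occasions:
                return a
        raise KeyError((metric, occasions))

    def to_dict(self) -> dict:
        """JSON-ready summary (fractions/metrics rounded to 0.1 display
        precision; the patient table carries full precision)."""
        return {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "attainment_pct": {
                a.policy: {c: round(100.0 * v, 1)
                           for c, v in sorted(a.fractions.items())}
                for a in self.attainment
            },
            "accuracy_pct": [
                {"metric": a.metric, "occasions": a.occasions,
                 "rbias": round(a.rbias, 1), "rrmse": round(a.rrmse, 1)}
                for a in self.accuracy
            ],
            "rdpe_pct": {str(k): [round(x, 1) for x in v]
                         for k, v in sorted(self.rdpe_by_occasions.items())},
            "qd_fraction": round(self.qd_fraction, 4),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _policy_rows(traj: PatientTrajectory, true_dose: DoseDecision,
                 targets: TargetSpec) -> list[dict]:
    rows = []
    base = {"ID": traj.patient_id, "true_dd": true_dose.daily_dose_mg}
    rows.append(dict(
        base, policy="flat", occasions=0,
        selected_dd=600.0, interval_h=24.0,
        true_ratio=traj.flat_truth_metrics.ratio,
        true_fcmin=traj.flat_truth_metrics.fCmin,
        pred_ratio=np.nan, pred_fcmin=np.nan,
        category=classify_attainment(traj.flat_truth_metrics, targets)))
    for occ in traj.occasions:
        rows.append(dict(
            base, policy=f"occ{occ.occasion}", occasions=occ.occasion,
            selected_dd=occ.decision.daily_dose_mg,
            interval_h=occ.decision.regimen.interval_h,
            true_ratio=occ.truth_metrics.ratio,
            true_fcmin=occ.truth_metrics.fCmin,
            pred_ratio=occ.predicted_metrics.ratio,
            pred_fcmin=occ.predicted_metrics.fCmin,
            category=classify_attainment(occ.truth_metrics, targets)))
    return rows


def summarize_cohort(
    trajectories: Sequence[PatientTrajectory],
    true_doses: Sequence[DoseDecision],
    targets: TargetSpec | None = None,
    *,
    seed: int = 0,
    config_hash: str = "",
) -> EvaluationReport:
    """Aggregate per-patient trajectories into the cohort report."""
    if len(trajectories) != len(true_doses):
        raise ValueError("trajectories and true doses must align")
    targets = targets or TargetSpec()
    rows = []
    for traj, td in zip(trajectories, true_doses):
        rows.extend(_policy_rows(traj, td, targets))
    table = pd.DataFrame(rows)

    attainment = []
    for policy, grp in table.groupby("policy", sort=True):
        counts = grp["category"].value_counts()
        n = len(grp)
        attainment.append(AttainmentSummary(
            policy=str(policy),
            fractions={c: float(counts.get(c, 0)) / n for c in CATEGORIES}))

    accuracy = []
    rdpe_by = {}
    mipd = table[table["occasions"] > 0]
    for k, grp in mipd.groupby("occasions", sort=True):
        accuracy.append(AccuracyMetrics(
            metric="fAUC0_24/MIC", occasions=int(k),
            rbias=rbias(grp["pred_ratio"], grp["true_ratio"]),
            rrmse=rrmse(grp["pred_ratio"], grp["true_ratio"])))
        accuracy.append(AccuracyMetrics(
            metric="fCmin", occasions=int(k),
            rbias=rbias(grp["pred_fcmin"], grp["true_fcmin"]),
            rrmse=rrmse(grp["pred_fcmin"], grp["true_fcmin"])))
        rdpe_by[int(k)] = tuple(
            rdpe(p, t) for p, t in zip(grp["selected_dd"], grp["true_dd"]))

    qd = mipd["interval_h"].eq(24.0)
    return EvaluationReport(
        attainment=tuple(attainment),
        accuracy=tuple(accuracy),
        rdpe_by_occasions=rdpe_by,
        qd_fraction=float(qd.mean()) if len(qd) else float("nan"),
        n_patients=len(trajectories),
        seed=seed,
        config_hash=config_hash,
        patient_table=table,
    )


def _config_hash(cohort_config: CohortConfig, workflow: WorkflowConfig,
                 pop: PopulationParameters) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        raise TypeError(type(o))

    blob = json.dumps({"cohort": asdict(cohort_config),
                       "workflow": asdict(workflow),
                       "population": asdict(pop)},
                      sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_cohort_study(
    n_patients: int = 1000,
    seed: int = 0,
    *,
    cohort_config: CohortConfig | None = None,
    workflow: WorkflowConfig | None = None,
    pop: PopulationParameters | None = None,
    progress: bool = False,
) -> EvaluationReport:
    """Full virtual-cohort evaluation of the MIPD algorithm.

    Generates the cohort, runs the adaptive workflow and the true-dose
    derivation for every patient, and aggregates the report.  All
    randomness (covariates, random effects, observation noise) descends
    from ``seed`` via per-patient child streams, so reports with the same
    seed and configuration are bit-identical regardless of batching.
    """
    cohort_config = cohort_config or CohortConfig(n_patients=n_patients)
    if cohort_config.n_patients != n_patients:
        cohort_config = CohortConfig(**{**asdict(cohort_config),
                                        "n_patients": n_patients})
    workflow = workflow or WorkflowConfig()
    pop = pop or PopulationParameters()
    root = np.random.SeedSequence(seed)
    cohort_ss, noise_ss = root.spawn(2)
    patients = generate_cohort(cohort_config, np.random.default_rng(cohort_ss),
                               pop=pop)
    noise_streams = noise_ss.spawn(len(patients))
    trajectories = []
    true_doses = []
    for patient, ss in zip(patients, noise_streams):
        trajectories.append(run_adaptive_workflow(
            patient, pop, workflow, np.random.default_rng(ss)))
        true_doses.append(derive_true_dose(patient, pop, workflow))
        if progress and (patient.patient_id + 1) % 25 == 0:
            logger.info("processed %d/%d patients", patient.patient_id + 1,
                        len(patients))
    return summarize_cohort(
        trajectories, true_doses, workflow.targets, seed=seed,
        config_hash=_config_hash(cohort_config, workflow, pop))
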