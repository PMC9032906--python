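"""Dose individualization: candidate grid, decision table, adaptive workflow.

The candidate grid spans 150-1200 mg once daily and 150-600 mg twice
daily in 150 mg increments (12 regimens).  Each candidate is judged
against the efficacy target fAUC0-24h/MIC > 119 and the safety target
fCmin < 1.38 mg/L (both strict), and the decision table is:

1. candidates meeting both targets exist: the lowest daily dose among
   them; within a daily-dose tie the regimen with the lower predicted
   fCmin (QD beats BID at equal daily dose since its trough is lower);
2. only efficacious candidates: the lowest efficacious daily dose, with
   a safety warning;
3. only safe candidates: the highest-daily-dose safe regimen, with an
   efficacy warning;
4. neither: 1200 mg QD with both warnings.

The adaptive workflow starts every patient on 600 mg QD, samples sparsely
(0, 2, 5 h post dose) on days 1, 8 and 15, refits the MAP estimates after
each occasion on all data so far, and applies each recommendation one
week after its sampling occasion.  Exposure is evaluated on day 28.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exposure import (
    DEFAULT_WINDOW_START,
    DosingRegimen,
    ExposureMetrics,
    ObservationRecord,
    compute_exposure,
    simulate_observations,
)
from .forecast import (
    MAPEstimator,
    MAPResults,
    ObservationSet,
    build_parameter_segments,
    predict_exposure,
)
from .model import DoseEvent, solve_profile
from .params import PatientCovariates, PopulationParameters, RandomEffects

__all__ = [
    "TargetSpec",
    "CandidateResult",
    "DoseDecision",
    "WorkflowConfig",
    "OccasionOutcome",
    "PatientTrajectory",
    "default_dose_grid",
    "evaluate_candidates",
    "select_dose",
    "run_adaptive_workflow",
    "derive_true_dose",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSpec:
    """Efficacy (fAUC0-24/MIC strictly above) and safety (fCmin strictly
    below) thresholds."""

    efficacy_threshold: float = 119.0
    safety_threshold: float = 1.38

    def __post_init__(self) -> None:
        if self.efficacy_threshold <= 0 or self.safety_threshold <= 0:
            raise ValueError("thresholds must be > 0")

    def efficacy_met(self, metrics: ExposureMetrics) -> bool:
        return metrics.ratio > self.efficacy_threshold

    def safety_met(self, metrics: ExposureMetrics) -> bool:
        return metrics.fCmin < self.safety_threshold


def default_dose_grid() -> tuple[DosingRegimen, ...]:
    """150-1200 mg QD and 150-600 mg BID in 150 mg steps (12 regimens)."""
    qd = [DosingRegimen(d, 24.0) for d in range(150, 1201, 150)]
    bid = [DosingRegimen(d, 12.0) for d in range(150, 601, 150)]
    return tuple(qd + bid)


@dataclass(frozen=True)
class CandidateResult:
    regimen: DosingRegimen
    metrics: ExposureMetrics
    efficacy_met: bool
    safety_met: bool


@dataclass(frozen=True)
class DoseDecision:
    """Selected regimen with target flags; warnings mirror unmet targets."""

    regimen: DosingRegimen
    metrics: ExposureMetrics
    efficacy_met: bool
    safety_met: bool
    warnings: tuple[str, ...]

    def __post_init__(self) -> None:
        expect = tuple(w for w, met in (("efficacy", self.efficacy_met),
                                        ("safety", self.safety_met)) if not met)
        if tuple(sorted(self.warnings)) != tuple(sorted(expect)):
            raise ValueError("warnings inconsistent with target flags")

    @property
    def daily_dose_mg(self) -> float:
        return self.regimen.daily_dose_mg


@dataclass(frozen=True)
class WorkflowConfig:
    """Timing, sampling and selection settings of the adaptive workflow."""

    initial_regimen: DosingRegimen = DosingRegimen(600.0, 24.0)
    occasion_days: tuple[int, ...] = (1, 8, 15)
    sparse_times: tuple[float, ...] = (0.0, 2.0, 5.0)
    rich_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    dose_change_lag_days: int = 7
    window_start: float = DEFAULT_WINDOW_START
    grid: tuple[DosingRegimen, ...] = field(default_factory=default_dose_grid)
    targets: TargetSpec = field(default_factory=TargetSpec)
    fit_rtol: float = 1e-5
    sim_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if list(self.occasion_days) != sorted(set(self.occasion_days)):
            raise ValueError("occasion days must be strictly increasing")
        if not self.grid:
            raise ValueError("dose grid must be non-empty")
        iv = self.initial_regimen.interval_h
        if any(t < 0 or t >= iv for t in self.sparse_times):
            raise ValueError("sparse sampling times must fall within one "
                             "dosing interval")

    def occasion_start(self, k: int) -> float:
        """Start (h) of 1-based sampling occasion k (day d -> (d-1)*24)."""
        return (self.occasion_days[k - 1] - 1) * 24.0

    def effect_time(self, k: int) -> float:
        """Time at which the decision from occasion k takes effect."""
        return self.occasion_start(k) + self.dose_change_lag_days * 24.0

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_days)

    def occasion_windows(self) -> dict[int, tuple[float, float]]:
        """IOV windows: occasion k runs from its start to the next occasion
        start (last occasion: to its dose-change time); kappa = 0 after."""
        out = {}
        for k in range(1, self.n_occasions + 1):
            start = self.occasion_start(k)
            end = (self.occasion_start(k + 1) if k < self.n_occasions
                   else self.effect_time(k))
            out[k] = (start, end)
        return out


def evaluate_candidates(
    post: MAPResults | RandomEffects,
    cov: PatientCovariates,
    pop: PopulationParameters,
    grid: Sequence[DosingRegimen] | None = None,
    targets: TargetSpec | None = None,
    *,
    prior_doses: Sequence[DoseEvent] = (),
    effect_time: float = 0.0,
    window_start: float = DEFAULT_WINDOW_START,
    occasion_windows: Mapping[int, tuple[float, float]] | None = None,
    rtol: float = 1e-8,
) -> list[CandidateResult]:
    """Predict exposure for every grid regimen and flag target attainment.

    A candidate whose prediction fails numerically is excluded with a
    logged warning rather than aborting the whole selection.
    """
    grid = tuple(grid) if grid is not None else default_dose_grid()
    if not grid:
        raise ValueError("candidate grid must be non-empty")
    targets = targets or TargetSpec()
    results = []
    for regimen in grid:
        try:
            m = predict_exposure(
                post, regimen, cov, pop, window_start=window_start,
                prior_doses=prior_doses, effect_time=effect_time,
                occasion_windows=occasion_windows, rtol=rtol)
        except Exception as exc:  # noqa: BLE001 - per-candidate isolation
            logger.warning("candidate %s failed: %s", regimen.label, exc)
            continue
        results.append(CandidateResult(
            regimen=regimen, metrics=m,
            efficacy_met=targets.efficacy_met(m),
            safety_met=targets.safety_met(m)))
    if not results:
        raise RuntimeError("every candidate regimen failed to evaluate")
    return results


def _lowest(cands: list[CandidateResult]) -> CandidateResult:
    # lowest daily dose; ties by lower predicted trough, then QD over BID
    return min(cands, key=lambda c: (c.regimen.daily_dose_mg,
                                     c.metrics.fCmin,
                                     c.regimen.interval_h != 24.0))


def _highest(cands: list[CandidateResult]) -> CandidateResult:
    return min(cands, key=lambda c: (-c.regimen.daily_dose_mg,
                                     c.metrics.fCmin,
                                     c.regimen.interval_h != 24.0))


def select_dose(candidates: Sequence[CandidateResult],
                targets: TargetSpec | None = None) -> DoseDecision:
    """Apply the four-rule decision table to evaluated candidates."""
    cands = list(candidates)
    if not cands:
        raise ValueError("select_dose needs at least one candidate")
    both = [c for c in cands if c.efficacy_met and c.safety_met]
    efficacious = [c for c in cands if c.efficacy_met]
    safe = [c for c in cands if c.safety_met]
    if both:
        chosen, warn = _lowest(both), ()
    elif efficacious:
        chosen, warn = _lowest(efficacious), ("safety",)
    elif safe:
        chosen, warn = _highest(safe), ("efficacy",)
    else:
        chosen, warn = _highest(cands), ("efficacy", "safety")
    return DoseDecision(
        regimen=chosen.regimen, metrics=chosen.metrics,
        efficacy_met=chosen.efficacy_met, safety_met=chosen.safety_met,
        warnings=warn)


# --------------------------------------------------------------------------
# adaptive workflow over a virtual patient (truth model known)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OccasionOutcome:
    """Everything produced at one sampling occasion."""

    occasion: int
    sample_times: tuple[float, ...]
    observations: tuple[ObservationRecord, ...]
    posterior: MAPResults
    decision: DoseDecision
    predicted_metrics: ExposureMetrics
    truth_metrics: ExposureMetrics


@dataclass(frozen=True)
class PatientTrajectory:
    """Adaptive-workflow record for one virtual patient."""

    patient_id: int
    occasions: tuple[OccasionOutcome, ...]
    flat_truth_metrics: ExposureMetrics
    administered: tuple[DoseEvent, ...]

    @property
    def final_decision(self) -> DoseDecision:
        return self.occasions[-1].decision


def _regimen_events(plan: list[tuple[DosingRegimen, float, float]],
                    include_final_end: bool = False):
    """Expand (regimen, start, end) pieces, end exclusive for dose times.

    With ``include_final_end`` the last piece also doses exactly at its end
    time, so a pre-dose trough exists at an evaluation-window boundary.
    """
    events: list[DoseEvent] = []
    for i, (regimen, start, end) in enumerate(plan):
        limit = end + (1e-9 if include_final_end and i == len(plan) - 1
                       else -1e-9)
        t = start
        while t < limit:
            events.append(DoseEvent(t, regimen.dose_mg))
            t += regimen.interval_h
    return events


def _truth_exposure(truth_re, windows, cov, pop, events, window_start, MIC,
                    rtol):
    segments = build_parameter_segments(truth_re, windows, pop, cov)
    t0, t1 = window_start, window_start + 24.0
    eval_times = {t0, t1}
    eval_times.update(d.time for d in events if t0 < d.time <= t1)
    profile = solve_profile(segments, events, sorted(eval_times), pop,
                            rtol=rtol)
    return compute_exposure(profile, window_start, pop.fu, MIC)


def run_adaptive_workflow(
    truth,
    pop: PopulationParameters,
    config: WorkflowConfig | None = None,
    rng: np.random.Generator | int = 0,
) -> PatientTrajectory:
    """Simulate the full sparse-sampling MIPD workflow for one patient.

    ``truth`` is a virtual patient (covariates + true random effects for at
    least as many occasions as the workflow samples).  Observation noise is
    drawn from ``rng``; everything downstream of the observations is
    deterministic.  For every occasion count k the returned trajectory also
    records the truth-model exposure the patient would experience if
    adaptation stopped after decision k (and under flat dosing), evaluated
    at the day-28 window.
    """
    config = config or WorkflowConfig()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cov = truth.covariates
    truth_re = truth.effects
    if truth_re.n_occasions < config.n_occasions:
        raise ValueError(
            f"truth carries kappas for {truth_re.n_occasions} occasions; "
            f"workflow needs {config.n_occasions}")
    windows = config.occasion_windows()
    window_end = config.window_start + 24.0
    truth_segments = build_parameter_segments(truth_re, windows, pop, cov)

    # administered plan: (regimen, start, end) pieces, extended as decided
    plan: list[tuple[DosingRegimen, float, float]] = [
        (config.initial_regimen, 0.0, config.effect_time(1))]
    all_records: list[ObservationRecord] = []
    outcomes: list[OccasionOutcome] = []

    for k in range(1, config.n_occasions + 1):
        occ_start = config.occasion_start(k)
        sample_times = tuple(occ_start + t for t in config.sparse_times)
        admin_events = _regimen_events(plan)
        history = [d for d in admin_events if d.time <= max(sample_times)]
        profile = solve_profile(
            truth_segments, history,
            sorted(set(sample_times) | {max(sample_times)}), pop,
            rtol=config.sim_rtol)
        obs_k = simulate_observations(profile, sample_times, pop, rng,
                                      occasions=k, first_dose_time=0.0)
        all_records.extend(obs_k)

        obs_set = ObservationSet(records=tuple(all_records),
                                 doses=tuple(admin_events),
                                 covariates=cov, occasion_windows=windows)
        post = MAPEstimator(obs_set, pop, rtol=config.fit_rtol).fit()
        if not post.converged:
            logger.warning("patient %s occasion %d: MAP non-converged, "
                           "using population-typical forecast",
                           getattr(truth, "patient_id", "?"), k)

        effect = config.effect_time(k)
        prior = [d for d in admin_events if d.time < effect]
        cands = evaluate_candidates(
            post, cov, pop, config.grid, config.targets,
            prior_doses=prior, effect_time=effect,
            window_start=config.window_start, rtol=config.sim_rtol)
        decision = select_dose(cands, config.targets)

        # truth exposure if adaptation stopped here
        policy_plan = plan + [(decision.regimen, effect, window_end)]
        truth_m = _truth_exposure(truth_re, windows, cov, pop,
                                  _regimen_events(policy_plan, True),
                                  config.window_start, cov.MIC,
                                  config.sim_rtol)
        outcomes.append(OccasionOutcome(
            occasion=k, sample_times=sample_times, observations=tuple(obs_k),
            posterior=post, decision=decision,
            predicted_metrics=decision.metrics, truth_metrics=truth_m))

        next_end = (config.effect_time(k + 1) if k < config.n_occasions
                    else window_end)
        plan.append((decision.regimen, effect, next_end))

    flat_plan = [(config.initial_regimen, 0.0, window_end)]
    flat_m = _truth_exposure(truth_re, windows, cov, pop,
                             _regimen_events(flat_plan, True),
                             config.window_start, cov.MIC, config.sim_rtol)
    return PatientTrajectory(
        patient_id=getattr(truth, "patient_id", -1),
        occasions=tuple(outcomes), flat_truth_metrics=flat_m,
        administered=tuple(_regimen_events(plan, True)))


def derive_true_dose(
    truth,
    pop: PopulationParameters,
    config: WorkflowConfig | None = None,
) -> DoseDecision:
    """The dose the algorithm would pick knowing the true random effects.

    Candidates are evaluated with the patient's true etas (kappa = 0,
    the population-typical occasion) under the candidate regimen from
    treatment start to the day-28 window, so the result is independent of
    the observation-noise path.
    """
    config = config or WorkflowConfig()
    re = RandomEffects(eta_CL=truth.effects.eta_CL,
                       eta_MTT=truth.effects.eta_MTT)
    cands = evaluate_candidates(
        re, truth.covariates, pop, config.grid, config.targets,
        effect_time=0.0, window_start=config.window_start,
        occasion_windows={}, rtol=config.sim_rtol)
    return select_dose(cands, config.targets)
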