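"""Empirical-Bayes (MAP) forecasting from sparse TDM concentrations.

``MAPEstimator`` is a model object built from one patient's observations,
dosing history and covariates; its ``fit()`` minimizes minus twice the log
posterior of the individual random effects

    sum_j [ (y_j - f_j)^2 / v_j + ln v_j ]            (data, v = sp^2 f^2 + sa^2)
  + sum_k (eta_k / omega_k)^2                          (IIV prior)
  + sum_occ sum_m (kappa_m,occ / pi_m,occ)^2           (IOV prior)

over the IIV etas (CL, MTT) and the IOV kappas (CL, V, ka, MTT) of every
*observed* occasion, and returns a ``MAPResults`` carrying the estimates,
the objective at the optimum and convergence diagnostics.  Forecasts for
future occasions use kappa = 0, the population-typical occasion.

Estimation is deterministic: a fixed three-point multi-start (all zero;
eta_CL = +/-0.5) feeds an L-BFGS-B quasi-Newton search, the best objective
wins and ties go to the smallest random-effect vector.  Below-LLOQ samples
enter as LLOQ/2; pre-first-dose samples are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from ._integrate import NSTATE, integrate_breakpoints
from .exposure import DosingRegimen, ExposureMetrics, ObservationRecord, \
    build_schedule, compute_exposure, DEFAULT_WINDOW_START
from .model import DoseEvent, SolverError, solve_profile
from .params import (
    IOV_PARAMETERS,
    PatientCovariates,
    PopulationParameters,
    RandomEffects,
    derive_individual_parameters,
)

__all__ = [
    "ObservationSet",
    "MAPEstimator",
    "MAPResults",
    "map_objective",
    "estimate_map",
    "predict_exposure",
    "build_parameter_segments",
]

logger = logging.getLogger(__name__)

#: Fixed multi-start points, expressed as eta_CL offsets (deviate scale).
MULTISTART_ETA_CL = (0.0, 0.5, -0.5)


@dataclass(frozen=True)
class ObservationSet:
    """One patient's TDM records, dosing history and covariates.

    ``occasion_windows`` maps 1-based occasion indices to the [start, end)
    time span over which that occasion's IOV kappas apply; outside every
    window the population-typical occasion (kappa = 0) is assumed.
    """

    records: tuple[ObservationRecord, ...]
    doses: tuple[DoseEvent, ...]
    covariates: PatientCovariates
    occasion_windows: Mapping[int, tuple[float, float]]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.usable and r.occasion not in self.occasion_windows:
                raise ValueError(f"record at t={r.time_h} has unknown occasion "
                                 f"{r.occasion}")
        first_dose = min((d.time for d in self.doses), default=np.inf)
        for r in self.records:
            if r.usable and r.time_h < first_dose:
                raise ValueError(f"usable record at t={r.time_h} precedes the "
                                 "dosing history")

    @property
    def usable_records(self) -> tuple[ObservationRecord, ...]:
        return tuple(r for r in self.records if r.usable)

    @property
    def observed_occasions(self) -> tuple[int, ...]:
        return tuple(sorted({r.occasion for r in self.usable_records}))

    def restricted_to(self, occasions: Sequence[int]) -> "ObservationSet":
        keep = set(occasions)
        return ObservationSet(
            records=tuple(r for r in self.records if r.occasion in keep),
            doses=self.doses,
            covariates=self.covariates,
            occasion_windows=self.occasion_windows,
        )


def build_parameter_segments(
    re: RandomEffects,
    occasion_windows: Mapping[int, tuple[float, float]],
    pop: PopulationParameters,
    cov: PatientCovariates,
    t0: float = 0.0,
):
    """Piecewise-constant individual parameters over occasion windows.

    Within occasion k's window the parameters use that occasion's kappas;
    everywhere else kappa = 0.  The IIV etas apply throughout.
    """
    typical = RandomEffects(eta_CL=re.eta_CL, eta_MTT=re.eta_MTT)
    bounds = {t0}
    for start, end in occasion_windows.values():
        if start > t0:
            bounds.add(float(start))
        if np.isfinite(end):
            bounds.add(float(end))
    segs = []
    for b in sorted(bounds):
        occ = next((k for k, (s, e) in occasion_windows.items() if s <= b < e),
                   None)
        if occ is None:
            p = derive_individual_parameters(pop, cov, typical, occasion=1)
        else:
            p = derive_individual_parameters(pop, cov, re, occasion=occ)
        segs.append((b, p))
    return segs


class MAPEstimator:
    """MAP model for one patient's random effects given sparse samples."""

    def __init__(
        self,
        obs: ObservationSet,
        pop: PopulationParameters,
        *,
        rtol: float = 1e-5,
        atol: float = 1e-7,
        estimate_iov: bool = True,
    ) -> None:
        """``estimate_iov=False`` fixes all occasion kappas at zero and
        estimates the IIV etas only.  Joint estimation is the default; note
        that eta_CL and the occasion kappa_CLs are aliased (the data pin
        only their sum per occasion), so the MAP split attributes a share
        pi^2-vs-omega^2 of the signal to eta even with perfect data.  Pure
        eta-recovery experiments therefore disable IOV estimation."""
        self.obs = obs
        self.pop = pop
        self.rtol = rtol
        self.atol = atol
        self.estimate_iov = estimate_iov
        self._prepare()

    # -- construction of the fixed integration skeleton ------------------

    def _prepare(self) -> None:
        pop, obs = self.pop, self.obs
        usable = [r for r in obs.usable_records]
        usable.sort(key=lambda r: r.time_h)
        self._y = np.array([r.value_for_fit for r in usable])
        self._obs_times = np.array([r.time_h for r in usable])
        self._occs = (list(obs.observed_occasions) if self.estimate_iov
                      else [])
        # deviate vector layout: eta_CL, eta_MTT, then per observed occasion
        # kappa_CL, kappa_V, kappa_ka, kappa_MTT
        sds = [pop.omega_CL, pop.omega_MTT]
        names = ["eta_CL", "eta_MTT"]
        for occ in self._occs:
            sds += [pop.pi_CL, pop.pi_V, pop.pi_ka, pop.pi_MTT]
            names += [f"kappa_{p}[{occ}]" for p in IOV_PARAMETERS]
        self._sd = np.array(sds)
        self._free = self._sd > 0
        self.param_names = names
        self.nparams = len(names)
        if len(usable) == 0:
            return
        horizon = float(self._obs_times[-1])
        doses = [d for d in obs.doses if d.time <= horizon]
        # slot 0 = population-typical occasion, slot i = self._occs[i-1]
        windows = {k: obs.occasion_windows[k] for k in self._occs}
        ts = {min(0.0, doses[0].time if doses else 0.0)}
        ts.update(d.time for d in doses)
        ts.update(float(t) for t in self._obs_times)
        for s, e in windows.values():
            if s <= horizon:
                ts.add(float(s))
            if np.isfinite(e) and e <= horizon:
                ts.add(float(e))
        break_ts = np.array(sorted(t for t in ts if t <= horizon))
        dose_amts = np.zeros_like(break_ts)
        for d in doses:
            dose_amts[np.searchsorted(break_ts, d.time)] += d.amount

        def slot_at(t: float) -> int:
            for i, occ in enumerate(self._occs):
                s, e = windows[occ]
                if s <= t < e:
                    return i + 1
            return 0

        self._interval_slot = np.array(
            [slot_at(0.5 * (break_ts[i] + break_ts[i + 1]))
             for i in range(len(break_ts) - 1)], dtype=np.int64)
        self._obs_slot = np.array([slot_at(t) for t in self._obs_times])
        self._eval_idx = np.searchsorted(break_ts, self._obs_times)
        self._break_ts = break_ts
        self._dose_amts = dose_amts

    # -- objective --------------------------------------------------------

    def _unpack(self, dev: np.ndarray) -> RandomEffects:
        kap = {}
        for j, p in enumerate(IOV_PARAMETERS):
            vals = {}
            for i, occ in enumerate(self._occs):
                vals[occ] = dev[2 + 4 * i + j]
            if vals:
                n = max(vals)
                kap[p] = tuple(vals.get(o, 0.0) for o in range(1, n + 1))
        return RandomEffects(eta_CL=dev[0], eta_MTT=dev[1], kappa=kap)

    def _pack(self, re: RandomEffects) -> np.ndarray:
        dev = np.zeros(self.nparams)
        dev[0], dev[1] = re.eta_CL, re.eta_MTT
        for i, occ in enumerate(self._occs):
            for j, p in enumerate(IOV_PARAMETERS):
                dev[2 + 4 * i + j] = re.kappa_for(p, occ)
        return dev

    def _predict(self, dev: np.ndarray) -> np.ndarray:
        """Model concentrations at the usable observation times."""
        pop, cov = self.pop, self.obs.covariates
        re = self._unpack(dev)
        rows = np.empty((len(self._occs) + 1, 4))
        typ = derive_individual_parameters(
            pop, cov, RandomEffects(eta_CL=dev[0], eta_MTT=dev[1]), occasion=1)
        rows[0] = (typ.CL, typ.V, typ.ka, typ.ktr)
        for i, occ in enumerate(self._occs):
            p = derive_individual_parameters(pop, cov, re, occasion=occ)
            rows[i + 1] = (p.CL, p.V, p.ka, p.ktr)
        theta = rows[self._interval_slot]
        Y, status = integrate_breakpoints(
            self._break_ts, self._dose_amts, theta, np.zeros(NSTATE),
            pop.kIC, pop.IC50, pop.RCLF, True, self.rtol, self.atol)
        if status != 0:
            raise SolverError("integration failed during MAP objective")
        V_obs = rows[self._obs_slot, 1]
        return Y[self._eval_idx, 6] / V_obs

    def objective(self, dev: np.ndarray) -> float:
        """-2 log posterior (additive constant dropped) at deviates ``dev``."""
        dev = np.asarray(dev, dtype=float)
        prior = float(np.sum((dev[self._free] / self._sd[self._free]) ** 2))
        if np.any(dev[~self._free] != 0.0):
            raise ValueError("deviates with zero prior SD must be 0")
        if len(self._y) == 0:
            return prior
        f = self._predict(dev)
        v = self.pop.sigma_prop ** 2 * f ** 2 + self.pop.sigma_add ** 2
        return float(np.sum((self._y - f) ** 2 / v + np.log(v)) + prior)

    def objective_from_effects(self, re: RandomEffects) -> float:
        return self.objective(self._pack(re))

    # -- fitting ----------------------------------------------------------

    def fit(self, maxiter: int = 300) -> "MAPResults":
        if len(self._y) == 0 or not np.any(self._free):
            dev = np.zeros(self.nparams)
            return MAPResults(self, dev, self.objective(dev), True,
                              len(self._y), "prior mode (no usable data)")
        free = np.where(self._free)[0]
        sd_f = self._sd[free]

        def fun(z: np.ndarray) -> float:
            dev = np.zeros(self.nparams)
            dev[free] = z * sd_f
            return self.objective(dev)

        candidates = []
        for eta0 in MULTISTART_ETA_CL:
            z0 = np.zeros(len(free))
            if self._sd[0] > 0:
                z0[0] = eta0 / self._sd[0]
            res = minimize(fun, z0, method="L-BFGS-B",
                           bounds=[(-4.0, 4.0)] * len(free),
                           options={"maxiter": maxiter})
            dev = np.zeros(self.nparams)
            dev[free] = res.x * sd_f
            candidates.append((res.fun, float(np.linalg.norm(dev)),
                               bool(res.success), dev, res))
        ok = [c for c in candidates if c[2]]
        pool = ok if ok else candidates
        best = min(pool, key=lambda c: (round(c[0], 9), c[1]))
        if not ok:
            logger.warning("MAP estimation failed to converge from all "
                           "starts: %s", best[4].message)
            dev = np.zeros(self.nparams)
            return MAPResults(self, dev, self.objective(dev), False,
                              len(self._y),
                              f"non-converged: {best[4].message}")
        return MAPResults(self, best[3], float(best[0]), True, len(self._y),
                          str(best[4].message))


@dataclass(frozen=True)
class MAPResults:
    """MAP estimates of one patient's random effects."""

    model: MAPEstimator
    deviates: np.ndarray
    objective: float
    converged: bool
    n_obs: int
    message: str = ""

    @property
    def eta_CL(self) -> float:
        return float(self.deviates[0])

    @property
    def eta_MTT(self) -> float:
        return float(self.deviates[1])

    def random_effects(self) -> RandomEffects:
        return self.model._unpack(self.deviates)

    def kappa(self, name: str, occasion: int) -> float:
        return self.random_effects().kappa_for(name, occasion)

    def individual_parameters(self, occasion: int):
        """Realized parameters on ``occasion`` (kappa = 0 if unobserved)."""
        return derive_individual_parameters(
            self.model.pop, self.model.obs.covariates, self.random_effects(),
            occasion=occasion)

    def predict_exposure(self, regimen: DosingRegimen, **kwargs) -> ExposureMetrics:
        return predict_exposure(self, regimen, self.model.obs.covariates,
                                self.model.pop, **kwargs)

    def summary(self) -> str:
        lines = [
            "MAP empirical-Bayes estimates",
            "=" * 46,
            f"{'n usable observations':<30}{self.n_obs:>12}",
            f"{'occasions used':<30}{str(self.model._occs):>12}",
            f"{'-2 log posterior':<30}{self.objective:>12.4f}",
            f"{'converged':<30}{str(self.converged):>12}",
            "-" * 46,
            f"{'parameter':<18}{'estimate':>12}{'prior SD':>12}",
            "-" * 46,
        ]
        for name, val, sd in zip(self.model.param_names, self.deviates,
                                 self.model._sd):
            lines.append(f"{name:<18}{val:>12.4f}{sd:>12.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)


def map_objective(
    re: RandomEffects,
    obs: ObservationSet,
    pop: PopulationParameters,
    cov: PatientCovariates | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """-2 log posterior at ``re`` (constant dropped), reference path.

    sum_j [(y_j - f_j)^2 / v_j + ln v_j] over usable records, with
    v = sigma_prop^2 f^2 + sigma_add^2 and f from the patient's actual
    dosing history, plus the standardized squares of every deviate carried
    by ``re``.  With no usable records only the prior term remains.
    """
    if cov is not None and cov != obs.covariates:
        raise ValueError("covariates disagree with the observation set")
    cov = obs.covariates

    def penalty(value: float, sd: float, name: str) -> float:
        if sd == 0.0:
            if value != 0.0:
                raise ValueError(f"{name} has zero prior SD but is nonzero")
            return 0.0
        return (value / sd) ** 2

    pis = {"CL": pop.pi_CL, "V": pop.pi_V, "ka": pop.pi_ka, "MTT": pop.pi_MTT}
    prior = penalty(re.eta_CL, pop.omega_CL, "eta_CL")
    prior += penalty(re.eta_MTT, pop.omega_MTT, "eta_MTT")
    for name, vals in re.kappa.items():
        for occ0, v in enumerate(vals):
            prior += penalty(v, pis[name], f"kappa_{name}[{occ0 + 1}]")
    usable = sorted(obs.usable_records, key=lambda r: r.time_h)
    if not usable:
        return prior
    times = [r.time_h for r in usable]
    horizon = times[-1]
    segs = build_parameter_segments(re, obs.occasion_windows, pop, cov)
    profile = solve_profile(segs, [d for d in obs.doses if d.time <= horizon],
                            sorted(set(times)), pop, rtol=rtol, atol=atol)
    f = np.array([profile.value_at(t) for t in times])
    y = np.array([r.value_for_fit for r in usable])
    v = pop.sigma_prop ** 2 * f ** 2 + pop.sigma_add ** 2
    return float(np.sum((y - f) ** 2 / v + np.log(v)) + prior)


def estimate_map(obs: ObservationSet, pop: PopulationParameters,
                 **options) -> MAPResults:
    """Convenience wrapper: build a ``MAPEstimator`` and fit it."""
    return MAPEstimator(obs, pop, **options).fit()


def predict_exposure(
    post: "MAPResults | RandomEffects",
    regimen: DosingRegimen,
    cov: PatientCovariates,
    pop: PopulationParameters,
    *,
    window_start: float = DEFAULT_WINDOW_START,
    prior_doses: Sequence[DoseEvent] = (),
    effect_time: float | None = None,
    occasion_windows: Mapping[int, tuple[float, float]] | None = None,
    MIC: float | None = None,
    inhibition: bool = True,
    rtol: float = 1e-8,
) -> ExposureMetrics:
    """Exposure metrics under a candidate regimen for an individual.

    The candidate takes over at ``effect_time`` (default: treatment start),
    with any ``prior_doses`` before it retained so the slowly accumulating
    inhibition state reflects the actual history.  Occasions with
    estimated kappas keep them over their windows; everywhere else
    (including the evaluation window) kappa = 0.
    """
    if isinstance(post, MAPResults):
        re = post.random_effects()
        if occasion_windows is None:
            occasion_windows = post.model.obs.occasion_windows
    else:
        re = post
        occasion_windows = occasion_windows or {}
    if effect_time is None:
        effect_time = regimen.start_time_h
    window_end = window_start + 24.0
    if effect_time > window_start:
        raise ValueError("candidate regimen must start at or before the "
                         "evaluation window")
    events = [d for d in prior_doses if d.time < effect_time]
    events += list(build_schedule(regimen.with_times(effect_time, window_end)))
    segments = build_parameter_segments(re, occasion_windows, pop, cov,
                                        t0=min([0.0] + [d.time for d in events]))
    eval_times = {window_start, window_end}
    eval_times.update(d.time for d in events
                      if window_start < d.time <= window_end)
    profile = solve_profile(segments, events, sorted(eval_times), pop,
                            inhibition=inhibition, rtol=rtol)
    return compute_exposure(profile, window_start, pop.fu,
                            cov.MIC if MIC is None else MIC)
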