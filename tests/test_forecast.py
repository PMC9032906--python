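"""MAP objective, estimation and individualized exposure prediction."""

import math

import numpy as np
import pytest

from linezolid_mipd import (
    DoseEvent,
    DosingRegimen,
    MAPEstimator,
    ObservationSet,
    PatientCovariates,
    PopulationParameters,
    RandomEffects,
    build_schedule,
    derive_individual_parameters,
    estimate_map,
    map_objective,
    predict_exposure,
    simulate_observations,
    solve_profile,
)
from linezolid_mipd.exposure import ObservationRecord
from linezolid_mipd.forecast import build_parameter_segments


def _empty_obs(cov):
    return ObservationSet(records=(), doses=(DoseEvent(0.0, 600.0),),
                          covariates=cov, occasion_windows={1: (0.0, 24.0)})


def _noise_free_obs(pop, cov, re, times, doses, windows):
    """Records equal to the truth-model prediction (no residual noise)."""
    segs = build_parameter_segments(re, windows, pop, cov)
    prof = solve_profile(segs, doses, sorted(set(times)), pop, rtol=1e-10,
                         atol=1e-12)
    occ_of = {t: next(k for k, (s, e) in windows.items() if s <= t < e)
              for t in times}
    recs = tuple(
        ObservationRecord(time_h=t, value=prof.value_at(t),
                          occasion=occ_of[t], blq_flag=False,
                          value_for_fit=prof.value_at(t), usable=t > 0.0)
        for t in times)
    return ObservationSet(records=recs, doses=tuple(doses), covariates=cov,
                          occasion_windows=windows)


class TestMapObjective:
    def test_prior_mode_is_zero(self, pop, typical_cov):
        assert map_objective(RandomEffects(), _empty_obs(typical_cov), pop) == 0.0

    def test_prior_penalty_is_standardized_square(self, pop, typical_cov):
        val = map_objective(RandomEffects(eta_CL=pop.omega_CL),
                            _empty_obs(typical_cov), pop)
        assert val == pytest.approx(1.0)
        val2 = map_objective(
            RandomEffects(eta_CL=pop.omega_CL, eta_MTT=2 * pop.omega_MTT,
                          kappa={"ka": (pop.pi_ka,)}),
            _empty_obs(typical_cov), pop)
        assert val2 == pytest.approx(1.0 + 4.0 + 1.0)

    def test_perfect_fit_leaves_log_variance_term(self, pop, typical_cov):
        doses = (DoseEvent(0.0, 600.0),)
        est0 = MAPEstimator(
            _noise_free_obs(pop, typical_cov, RandomEffects(), [2.0], doses,
                            {1: (0.0, 24.0)}), pop, rtol=1e-10, atol=1e-12)
        f = est0._predict(np.zeros(est0.nparams))[0]
        v = pop.sigma_prop ** 2 * f ** 2 + pop.sigma_add ** 2
        assert est0.objective(np.zeros(est0.nparams)) == pytest.approx(
            math.log(v), abs=1e-6)

    def test_log_variance_value_at_two_mg_per_l(self):
        # hand check of the variance term for f = y = 2.0 mg/L
        v = 0.054 ** 2 * 4.0 + 0.53 ** 2
        assert math.log(v) == pytest.approx(-1.229, abs=1e-3)


class TestEstimateMap:
    def test_no_observations_returns_prior_mode(self, pop, typical_cov):
        res = estimate_map(_empty_obs(typical_cov), pop)
        assert res.converged
        assert res.objective == 0.0
        assert np.all(res.deviates == 0.0)
        assert res.n_obs == 0

    def test_estimation_is_deterministic(self, pop, typical_cov):
        doses = tuple(DoseEvent(24.0 * k, 600.0) for k in range(2))
        ind = derive_individual_parameters(pop, typical_cov, RandomEffects())
        prof = solve_profile(ind, doses, [2.0, 5.0, 26.0, 29.0], pop)
        recs = tuple(simulate_observations(prof, [2.0, 5.0, 26.0, 29.0], pop,
                                           rng=5, occasions=[1, 1, 2, 2]))
        obs = ObservationSet(recs, doses, typical_cov,
                             {1: (0.0, 24.0), 2: (24.0, 48.0)})
        r1 = estimate_map(obs, pop)
        r2 = estimate_map(obs, pop)
        assert np.array_equal(r1.deviates, r2.deviates)
        assert r1.objective == r2.objective

    def test_noise_free_rich_sampling_recovers_eta_cl(self, pop, typical_cov):
        true = RandomEffects(eta_CL=0.3, eta_MTT=-0.2)
        windows = {1: (0.0, 168.0), 2: (168.0, 336.0), 3: (336.0, 504.0)}
        doses = tuple(DoseEvent(24.0 * k, 600.0) for k in range(15))
        times = [s + dt for s in (0.0, 168.0, 336.0)
                 for dt in (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)]
        obs = _noise_free_obs(pop, typical_cov, true, times, doses, windows)
        res = MAPEstimator(obs, pop, estimate_iov=False).fit()
        assert res.converged
        assert res.eta_CL == pytest.approx(0.3, abs=0.02)
        assert res.eta_MTT == pytest.approx(-0.2, abs=0.05)

    def test_eta_kappa_aliasing_splits_signal_by_prior_weights(
            self, pop, typical_cov):
        """With IOV estimated jointly, perfect data pin only eta + kappa_k
        per occasion; the MAP optimum attributes the share
        K/pi^2 / (1/omega^2 + K/pi^2) of a pure-eta signal to eta."""
        true = RandomEffects(eta_CL=0.3, eta_MTT=-0.2)
        windows = {1: (0.0, 168.0), 2: (168.0, 336.0), 3: (336.0, 504.0)}
        doses = tuple(DoseEvent(24.0 * k, 600.0) for k in range(15))
        times = [s + dt for s in (0.0, 168.0, 336.0)
                 for dt in (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)]
        obs = _noise_free_obs(pop, typical_cov, true, times, doses, windows)
        res = MAPEstimator(obs, pop).fit()
        w = (3 / pop.pi_CL ** 2) / (1 / pop.omega_CL ** 2 + 3 / pop.pi_CL ** 2)
        assert res.eta_CL == pytest.approx(0.3 * w, abs=0.03)

    def test_more_occasions_change_the_estimates(self, pop, typical_cov):
        true = RandomEffects(eta_CL=0.25, eta_MTT=0.1,
                             kappa={"CL": (0.1, -0.2), "V": (0.0, 0.1),
                                    "ka": (0.2, -0.1), "MTT": (0.0, 0.3)})
        windows = {1: (0.0, 168.0), 2: (168.0, 336.0)}
        doses = tuple(DoseEvent(24.0 * k, 600.0) for k in range(10))
        times = [2.0, 5.0, 170.0, 173.0]
        obs = _noise_free_obs(pop, typical_cov, true, times, doses, windows)
        full = MAPEstimator(obs, pop).fit()
        occ1 = MAPEstimator(obs.restricted_to([1]), pop).fit()
        assert occ1.model._occs == [1]
        assert full.model._occs == [1, 2]
        assert full.eta_CL != occ1.eta_CL

    def test_map_estimates_shrink_toward_prior(self, pop, typical_cov):
        # sparse data: |posterior mode| below the truth used to simulate it
        true = RandomEffects(eta_CL=0.5)
        windows = {1: (0.0, 168.0)}
        doses = tuple(DoseEvent(24.0 * k, 600.0) for k in range(2))
        obs = _noise_free_obs(pop, typical_cov, true, [2.0, 5.0], doses,
                              windows)
        res = MAPEstimator(obs, pop).fit()
        assert 0.0 < res.eta_CL < 0.5

    def test_fast_objective_matches_reference_path(self, pop, typical_cov):
        true = RandomEffects(eta_CL=0.15, eta_MTT=0.1,
                             kappa={"CL": (0.05, -0.1), "V": (0.1, 0.0),
                                    "ka": (-0.2, 0.3), "MTT": (0.1, -0.1)})
        windows = {1: (0.0, 168.0), 2: (168.0, 336.0)}
        doses = tuple(DoseEvent(24.0 * k, 600.0) for k in range(10))
        obs = _noise_free_obs(pop, typical_cov, true, [2.0, 5.0, 170.0, 173.0],
                              doses, windows)
        est = MAPEstimator(obs, pop, rtol=1e-10, atol=1e-12)
        probe = RandomEffects(eta_CL=0.1, eta_MTT=-0.05,
                              kappa={"CL": (0.2, 0.0), "V": (0.0, -0.1),
                                     "ka": (0.1, 0.1), "MTT": (0.0, 0.2)})
        fast = est.objective_from_effects(probe)
        ref = map_objective(probe, obs, pop)
        assert fast == pytest.approx(ref, rel=1e-6)

    def test_summary_lists_all_parameters(self, pop, typical_cov):
        res = estimate_map(_empty_obs(typical_cov), pop)
        text = res.summary()
        assert "eta_CL" in text and "-2 log posterior" in text


class TestPredictExposure:
    def test_typical_posterior_equals_population_prediction(self, pop, typical_cov):
        from linezolid_mipd.exposure import exposure_from_simulation
        regimen = DosingRegimen(600.0, 24.0)
        m = predict_exposure(RandomEffects(), regimen, typical_cov, pop,
                             window_start=648.0)
        ind = derive_individual_parameters(pop, typical_cov, RandomEffects())
        ref = exposure_from_simulation(
            ind, build_schedule(regimen.with_times(0.0, 672.0)), pop,
            MIC=typical_cov.MIC, window_start=648.0)
        assert m.fAUC0_24 == pytest.approx(ref.fAUC0_24, rel=1e-9)
        assert m.fCmin == pytest.approx(ref.fCmin, rel=1e-9)

    def test_higher_clearance_lowers_exposure(self, pop, typical_cov):
        regimen = DosingRegimen(600.0, 24.0)
        lo = predict_exposure(RandomEffects(eta_CL=0.4), regimen, typical_cov,
                              pop, window_start=648.0)
        typ = predict_exposure(RandomEffects(), regimen, typical_cov, pop,
                               window_start=648.0)
        assert lo.fAUC0_24 < typ.fAUC0_24
        assert lo.fCmin < typ.fCmin

    def test_auto_inhibition_makes_auc_supra_proportional(self, pop, typical_cov):
        m600 = predict_exposure(RandomEffects(), DosingRegimen(600.0, 24.0),
                                typical_cov, pop, window_start=648.0)
        m1200 = predict_exposure(RandomEffects(), DosingRegimen(1200.0, 24.0),
                                 typical_cov, pop, window_start=648.0)
        assert m1200.fAUC0_24 / m600.fAUC0_24 >= 2.0

    def test_candidate_must_cover_window(self, pop, typical_cov):
        with pytest.raises(ValueError, match="window"):
            predict_exposure(RandomEffects(),
                             DosingRegimen(600.0, 24.0, start_time_h=700.0),
                             typical_cov, pop, window_start=648.0)
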