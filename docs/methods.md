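# Methods

## Structural model

Linezolid disposition is described by a one-compartment model with
first-order elimination, transit-compartment absorption and an empirical
auto-inhibition of clearance.  Each oral dose enters the first of NN = 5
transit compartments as an instantaneous bolus and cascades with rate

    k_tr = (NN + 1) / MTT

into an absorption compartment, from which it is absorbed into the
central compartment (volume V) with rate constant k_a:

    dA1/dt = -k_tr A1
    dAn/dt =  k_tr A(n-1) - k_tr An          n = 2..5
    dAa/dt =  k_tr A5 - k_a Aa

Elimination is inhibited by the drug itself.  An inhibition compartment
with concentration C_i relaxes toward the central concentration with a
slow rate constant k_IC and scales clearance between 1 (no drug) and
RCLF (full inhibition) with potency IC50:

    dAc/dt = k_a Aa - (CL/V) Ac [ RCLF + (1 - RCLF)(1 - C_i/(IC50 + C_i)) ]
    dCi/dt = k_IC (Ac/V - C_i)

Two bookkeeping states (cumulative eliminated amount and cumulative
integral of Ac/V) ride along in the integration, giving mass-balance
checks and window AUCs at solver accuracy without auxiliary quadrature.

Parameters refer to a 70 kg patient and scale allometrically (exponent
0.75 on CL/F, 1 on V/F).  Covariate effects are linear multiplicative:
CL/F is 43% higher with HIV co-infection, k_a 95% higher in females, and
MTT 96% higher under P-gp-inhibitor co-medication.  Bioavailability is
not separable from the apparent parameters and is fixed at 1.  Defaults
(CL/F 6.3 L/h, V/F 50.6 L, k_a 1.8 h^-1, MTT 0.53 h, k_IC 5e-4 h^-1
fixed, IC50 0.38 mg/L fixed, RCLF 0.798) are the final population
estimates for adult drug-resistant-TB patients.

Between-patient variability is exponential: IIV on CL (SD 0.26) and MTT
(0.62); IOV, redrawn per sampling occasion, on CL (0.27), V (0.26),
k_a (0.93) and MTT (0.69); no correlations.  Residual error is combined
additive (0.53 mg/L) plus proportional (5.4%) on the normal scale.
Occasion k's IOV deviates apply from that occasion's first sample until
the next occasion starts (the last observed occasion's window closes at
its dose-change day); outside every window the population-typical
occasion (kappa = 0) applies, which in particular makes the day-28
evaluation window occasion-typical.

## Numerics

The system is integrated with an adaptive embedded Dormand-Prince 5(4)
pair compiled with numba, restarted at every dose, occasion switch and
output time; default tolerances rtol 1e-8 / atol 1e-10.  After
absorption completes, the emptied transit/absorption states are snapped
to exact zero once below 1e-14 mg (≲1e-17 of a dose) — left nonzero,
their fast eigenvalues (k_tr ~ 11 h^-1) keep the explicit pair
stability-limited indefinitely; zeroed, they stay zero and steps grow to
the accuracy limit of the slow states.  With inhibition disabled the
system is linear, and a matrix-exponential propagator provides an
independent closed-form oracle; the tests require agreement within 1e-6
relative, and observed agreement is ~1e-11.  Inside MAP estimation the
objective is simulated at rtol 1e-5: solver error there is several
orders of magnitude below the residual error model, and the looser
tolerance keeps the grid-search-free workflow tractable on one CPU.
Breakpoints closer than 1e-10 h are treated as coincident.

## Exposure metrics

Efficacy is indexed by fAUC0-24h/MIC (target strictly > 119) and safety
by the unbound trough fCmin (target strictly < 1.38 mg/L); total
concentrations are multiplied by an unbound fraction of 0.69 (linear
binding).  The evaluation window is day 28 of treatment (648-672 h):
late enough that the slowly equilibrating inhibition compartment (time
constant 1/k_IC ≈ 83 days) carries the accumulated history, and the same
window is used for candidate evaluation, truth-model exposure and
true-dose derivation so attainment comparisons are internally
consistent.  The trough is the concentration immediately before each
scheduled dose in the window; for twice-daily regimens the larger of the
two pre-dose values is used (conservative for safety).  Window AUC comes
from the solver's cumulative-integral state when the window endpoints
are simulated exactly, with a trapezoid fallback on grids no coarser
than 0.1 h.

Observations are y = f(1 + eps_p) + eps_a with independent normal
errors; negative draws are floored at zero, values below the LLOQ
(0.05 mg/L) are flagged and carried as LLOQ/2 in fitting, and samples
drawn at or before the first dose (known zero concentration) are
excluded from fitting rather than substituted.

## MAP forecasting

`MAPEstimator` minimizes minus twice the log posterior

    sum_j [ (y_j - f_j)^2 / v_j + ln v_j ]  +  sum (eta/omega)^2
      + sum_occ sum (kappa/pi)^2,        v_j = sigma_p^2 f_j^2 + sigma_a^2

jointly over the IIV etas and the IOV kappas of every observed occasion
(ignoring the kappas would bias the etas); future occasions are
forecast with kappa = 0.  Optimization is a deterministic three-point
multi-start (all-zero start plus eta_CL = ±0.5) of L-BFGS-B in
prior-SD-standardized coordinates, bounded at ±4 prior SDs; the best
objective wins and ties go to the smaller deviate vector.  If no start
converges the caller falls back to the population-typical forecast with
a logged warning.

A structural identifiability caveat matters for validation: eta_CL and
the occasion kappa_CLs enter the model only through their sum, so even
noise-free rich sampling pins only eta + kappa_k per occasion.  The MAP
optimum then attributes the share (K/pi^2)/(1/omega^2 + K/pi^2) of a
pure-eta signal to eta — about 0.74 for K = 3 occasions at the default
variances.  This split is the correct Bayesian attribution for
forecasting (predictions depend on the sum, and future occasions use
kappa = 0), but it means "eta recovery" can only be demonstrated with
IOV disabled in both the simulation and the fit
(`MAPEstimator(estimate_iov=False)`), which is how the recovery study is
run; the split factor itself is asserted as a test.

## Dose individualization

Candidates span 150-1200 mg QD and 150-600 mg BID in 150 mg steps
(12 regimens).  Each is simulated under the patient's actual dosing
history with the candidate taking over at the next dose-change day, and
classified against both targets.  Selection: (1) if candidates meet both
targets, the lowest daily dose among them, equal daily doses resolved by
the lower predicted trough (QD beats BID, whose trough is ~2.7-fold
higher at the default half-life) and any residual tie by QD; (2) if only
efficacious candidates exist, the lowest efficacious daily dose plus a
safety warning; (3) if only safe candidates exist, the highest-dose safe
regimen plus an efficacy warning; (4) otherwise 1200 mg QD with both
warnings.

The adaptive workflow starts at 600 mg QD, samples at 0, 2 and 5 h post
dose on days 1, 8 and 15, refits after each occasion on all data so far,
and applies each recommendation one week after its sampling occasion
(days 8, 15, 22).  The day-1 pre-dose sample precedes the first dose and
is excluded, so the first decision rests on two concentrations.  The
"true" individual dose runs the same grid and decision table with the
patient's true etas (kappa = 0) under the candidate regimen from
treatment start — a convention forced by requiring the true dose to be
independent of the observation-noise path; the adaptive decisions, by
contrast, carry their actual dosing history.

## Virtual cohort

Covariates are sampled independently: bodyweight truncated-normal
(mean 61.2, SD 12, bounds 35.3-88.9 kg), 54.5% male, 7.1% HIV.  Two
inputs the source population never reported are explicit, configurable
assumptions: P-gp-inhibitor prevalence (10%) and the MIC distribution
over two-fold dilutions ({0.125: 10%, 0.25: 40%, 0.5: 40%, 1.0: 10%},
centred so a typical patient on 600 mg QD meets efficacy at
MIC ≤ 0.5 mg/L).  A bootstrap mode resamples rows of a user-supplied
covariate table instead, for use when patient-level data are available.
The generator reproduces marginal summaries, not joint covariate
structure, and the headline attainment percentages of any particular
population are therefore not reproducible; the cohort study is read
through ordering properties (attainment nondecreasing and rRMSE
decreasing in the number of sampling occasions, all selections QD),
which are robust to the assumed distributions.

## Evaluation

Predicted exposure (the forecast that chose each dose) is compared with
the truth-model exposure under the same regimen and history via

    rBias = mean[(pred - obs) / ((pred + obs)/2)] x 100
    rRMSE = sqrt(mean[((pred - obs) / ((pred + obs)/2))^2]) x 100

and dose selection via rDPE = (predicted DD - true DD)/true DD x 100 on
total daily dose (QD/BID deliberately collapsed).  Pairs with zero mean
are dropped with a logged warning.  Attainment classifies the
truth-model exposure into {both, efficacy only, safety only, neither}
per policy (flat 600 mg QD and the recommendation after one, two, three
occasions).  Reported fractions and metrics are rounded to 0.1 for
display; patient-level tables keep full precision.

## Study sizes and reproducibility

The packaged cohort study runs 1000 patients by default; the test suite
and the acceptance script use 200 (and 100 for the eta-recovery study),
sizes at which every ordering property examined is stable while a full
run stays in the minutes range on a single core.  All randomness
descends from one seed through per-patient child streams
(`numpy.random.SeedSequence`), so reports are bit-identical for a fixed
seed and configuration regardless of batching; estimation itself
contains no randomness.

## Known limitations

- The MIC distribution and covariate joint structure of the original
  population are assumptions; absolute attainment percentages shift with
  them.
- Protein binding is linear (fixed fu = 0.69); no Cmax-based safety
  metrics.
- The model supports low bodyweights through allometry but no pediatric
  demography is generated.
- Population parameters are taken as known (no estimation or parameter
  uncertainty propagation); MAP forecasts carry no posterior intervals.
- BLQ handling is LLOQ/2 substitution, not a censored likelihood.
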