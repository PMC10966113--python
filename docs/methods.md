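# Methods

## Model and estimands

The package analyses the course of patients after a first donor lymphocyte
infusion (DLI1) as a time-inhomogeneous Markov multi-state process on the
clock-forward scale *t* = days since DLI1. The full graph has 14 states:
per DLI block {DLI, tIS, stop-tIS, relapse} plus three death states (death
without prior tIS/relapse, death after tIS, death after relapse), mirrored
once after a second DLI; third and later DLIs are ignored. The only cycle
is the tIS ⇄ stop-tIS restart loop. Clinically relevant GvHD is defined
operationally by therapeutic systemic immunosuppression (tIS), which gives
exact state-entry and -exit dates instead of grading.

Composite endpoints are sums of state-occupation probabilities:
cGRFS (alive, relapse-free, currently off tIS) over
{DLI1, stop-tIS1, DLI2, stop-tIS2}; "alive with GvHD" over the tIS states;
"death after tIS" over the post-tIS death states; RFS = cGRFS ∪ tIS states;
OS = all non-death states. cGRFS is non-monotone by construction: it falls
when patients start tIS and rises again as they stop it; the suite contains
a designed fixture exhibiting the dip-and-recover shape.

## Timeline cleaning rules

Raw tIS intervals become GvHD episodes by three rules, applied in the
order merge → death-extension → length filter, which makes the operation
idempotent:

- episodes restarting within the merge gap (61 days ≈ 2 months) are one
  episode;
- an episode stopped within 7 days before a death from GvHD is extended to
  the death day;
- episodes shorter than 14 days (closed-interval length, stop − start + 1)
  are discarded unless they end at death.

Months are converted at 30.4375 days/month. Covariates "at time of DLI"
use the most recent measurement in a window from 28 days before to 3 days
after the DLI (configurable; outside the window → unknown). Bone-marrow
chimerism is FDC (no detectable patient material), low MC (<5%), high MC
(≥5%); the absolute lymphocyte count is categorised at 500/1000 ×10⁶/l
(three levels) or 1000 (two levels). The viral covariate is time-varying
with at most one change: "early" from t=0 if an infection occurred in the
week before DLI1, otherwise switching to "early" at the first infection
within 2 weeks after DLI1 or to "late-onset" between 2 and 8 weeks;
infections after relapse, a second DLI, a tIS start, or 8 weeks are
ignored.

Subcohort eligibility (3-month vs 6-month DLI) requires the first DLI of
the matching planned type within 6 resp. 9 months of transplantation and
no prior relapse, death, graft failure, consolidated tIS or modified
cellular product; exclusion reasons follow the fixed precedence relapse >
death > graft failure > prior GvHD > modified product > timing > other, so
each excluded patient is accounted exactly once. Baseline tables report
percentages over patients with known values, rounded half away from zero.

## Long-format preparation

Each sojourn in a transient state yields one counting-process row per
outgoing transition on (t_in, t_out], status 1 on the realised transition
and 0 on its competitors, split at viral change points. Same-day events
are ordered DLI2 < tIS-start < tIS-stop < relapse < death, with later
events offset by +0.5 day — deterministic tie handling was preferred to
random jitter for reproducibility. A tIS episode strictly spanning a DLI2
administration is rejected: the graph has no stop-tIS exit from the DLI2
state, and giving a second DLI during active GvHD treatment is not part of
the modelled protocol. An episode whose stop coincides with death or with
the end of follow-up is treated as ongoing (no stop transition). tIS
continuing beyond relapse is ignored, as the model tracks only death after
relapse.

`prepare_transitions(..., episodes="verbatim")` skips the cleaning rules;
it exists because the cleaning rules define a slightly different estimand
than a generator's raw trajectories (a dropped 13-day episode reclassifies
a later death), and estimator-consistency checks must target the process
actually generated.

## Estimation

Nelson–Aalen increments dN_jk/Y_j are computed on the merged set of
observed transition times; the Aalen–Johansen product integral runs over
exactly those times (no interpolation, right-continuous steps). Rows of
P(s,t) sum to 1 to machine precision because each factor I + dA(u) is
row-stochastic by construction. Cause-specific cumulative incidence uses
the standard S(u−)·dN_c(u)/Y(u) form and satisfies ΣCIF = 1 − KM exactly.
Median follow-up is the reversed Kaplan–Meier (censoring as event) with
quantiles read off the curve.

The Cox partial likelihood is maximised by Newton–Raphson with analytic
gradient and Hessian, step-halving on overshoot, convergence when the
relative log-likelihood change is below 1e−9 (max 50 iterations). Ties use
the Efron approximation by default (Breslow available); the baseline
cumulative hazard is always the Breslow form at the reference pattern
(MAC_RD, FDC, ALC ≥1000, viral none), so a null fit reduces exactly to
Nelson–Aalen. Aliased (constant or collinear) design columns are rejected
by name before fitting; monotone likelihoods (|β| drifting beyond 15, or a
singular step) are flagged and warned about rather than returned as finite
estimates. All models are complete-case: every row of a patient with an
unknown level in any model covariate is dropped, and the count reported.
Wald inference throughout: CI = exp(β̂ ± z₀.₉₇₅·SE), two-sided normal
p-values.

Semi-parametric prediction equips chosen transitions with Cox fits —
A_jk(t|x) = H0_jk(t)·e^{x'β̂} — and leaves the rest nonparametric, then
product-integrates. Pattern-specific increments above 1 (possible when a
tail increment with risk set ≈1 is scaled by a hazard ratio >1) are
truncated at 1 with a warning, keeping probabilities in [0,1] and
absorbing states monotone; a pattern level unseen in training data falls
back to the reference with a warning. Confidence bands everywhere are
patient-level nonparametric bootstrap (percentile, B=500 for curves,
B=200 for predictions because each resample refits the Cox components);
the seed is mandatory and reruns are bit-identical. An analytic
(Aalen-type) variance is deliberately out of scope — the bootstrap gives
one uniform mechanism for hazards, composites and predictions.

## Synthetic cohorts

The generator simulates clock-forward Markov trajectories by competing
exponentials per constant-rate interval, with per-transition
piecewise-constant baseline rates multiplied by exp(covariate effects).
Default conditions: 3-month DLI at day 97 after transplantation,
administrative censoring 5 years after DLI1, conditioning/donor mix ≈
(0.19, 0.22, 0.25, 0.34) over MAC_RD/MAC_UD/RIC_RD/RIC_UD, chimerism
(0.33, 0.38, 0.29), ALC (0.47, 0.33, 0.20), 28% with an infection in the
week before DLI1 and a 2·10⁻³/day infection hazard for 8 weeks after.
Default effects on DLI1→tIS: HR 3.5 for high MC, 2.0 for low MC, 3.2 for
RIC_UD, 3.7 for early viral infection; HR 2.0 for high MC on tIS→death.
Baseline rates are calibrated so that roughly 28–30% of patients start tIS
within 3 months, about one in seven dies during tIS within a year, and
5-year cGRFS is near 50% — realistic magnitudes for this clinical setting,
chosen once and used as fixed study conditions, not tuned as reproduction
targets.

Viral infections are emitted only when they precede the exit from DLI1,
matching the covariate rule, so the generator's time-varying hazard and
the analysis-side viral track coincide. `corrupt_for_realism` injects
missing chimerism/ALC measurements, short (<14 d) spurious tIS episodes
placed far from real ones, and near-gap episode splits; consolidation
provably restores the clean timeline, which the suite asserts.

`true_occupancy` chains matrix exponentials of the generator matrix over
its constant-rate intervals for a fixed covariate pattern and is the exact
oracle for estimators and predictions. What the generator does *not*
emulate: real measurement-error in chimerism assays, pathogen-specific
viral kinetics, semi-Markov (duration-dependent) transition rates, or
correlated covariates; passing tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not clinical
validity on real cohorts.

## Problem sizes in the test suite

Oracle equivalence runs 1,000 random uncensored instances (≤20 patients,
≤5 states). Parameter recovery uses one n=2000 cohort (tolerance ±0.15 on
the log-HR) and 500 replicates at n=1000 for 95%-CI coverage, checked
against (0.93, 0.97). Prediction fidelity uses an illness-death chain
(DLI1 → tIS → death during tIS) with HR 2 on the GvHD transition at
n=5000, compared to the matrix-exponential oracle in sup-norm at 0.01;
the rates are chosen low enough that every occupancy stays outside the
high-variance mid-range, keeping the Monte-Carlo noise floor of that
comparison near 0.005 — with moderate rates the same check is run at
looser tolerance in the unit suite. These sizes make the whole suite run
in a few minutes on one CPU while keeping each check's noise floor well
below its tolerance.

## Known limitations

- Clock-forward Markov only; no semi-Markov estimation or frailties.
- The two-start viral variant fixes branch membership at baseline;
  patients with a post-DLI early infection stay in the no-infection
  branch.
- Bootstrap bands are pointwise percentile intervals, not simultaneous
  bands, and undercover slightly in very small cohorts.
- Monotone-likelihood transitions (e.g. a single death among FDC
  patients) yield flagged, unbounded estimates; no Firth-type correction
  is provided.
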