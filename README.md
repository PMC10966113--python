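# dlimstate

Multi-state event-history analysis of outcomes after donor lymphocyte
infusion (DLI) following T-cell-depleted allogeneic stem-cell
transplantation (alloSCT).

After alloSCT, unmodified donor lymphocyte infusions boost the
graft-versus-leukemia effect but can trigger graft-versus-host disease
(GvHD). GvHD is a *temporary* state — patients may recover and stop
immunosuppression — so simple time-to-first-event endpoints misrepresent
treatment success. This package implements the event-history machinery
needed to analyse such cohorts: it models a patient's course from the first
DLI (DLI1) through GvHD episodes, relapse, a second DLI and death as a
Markov multi-state process, and estimates the composite endpoint *current
GvHD-relapse-free survival* (cGRFS): the probability of being alive,
relapse-free and currently off therapeutic systemic immunosuppression
(tIS). It is written for biostatisticians and transplantation researchers
working with patient-level event histories.

## The model

GvHD is operationalised through tIS: an episode of systemic
immunosuppression given for ≥14 days (or until death) marks clinically
relevant GvHD, with restarts within 2 months merged into one episode. On
the clock-forward time scale *t* = days since DLI1, the cohort moves on a
14-state graph (seven states per DLI block: DLI, tIS, stop-tIS, relapse,
and three death states; mirrored after DLI2).

Estimation follows the standard counting-process route:

- cumulative transition hazards by Nelson–Aalen,
  `dA_jk(t) = dN_jk(t) / Y_j(t)`;
- state-occupation probabilities by the Aalen–Johansen product integral,
  `P(s,t) = ∏_{s<u≤t} (I + dA(u))`;
- composite endpoints as sums of state probabilities:
  cGRFS = P(DLI1) + P(stop tIS) + P(DLI2) + P(stop tIS after DLI2);
  RFS adds the tIS states; OS all non-death states;
- competing-risks cumulative incidence (start of tIS, death during tIS),
  and reversed Kaplan–Meier for follow-up;
- transition-specific Cox proportional-hazards regression with
  time-varying covariates (viral-infection status) via interval splitting,
  Efron ties, Newton–Raphson on the partial likelihood;
- semi-parametric prediction: Cox-equipped transitions contribute
  `A_jk(t|x) = H0_jk(t) exp(x'β)`, the rest their Nelson–Aalen estimates,
  product-integrated into reference-patient probabilities;
- patient-level bootstrap for all confidence bands.

Because no patient-level data ship with the package, a calibrated
synthetic-cohort generator (`dlimstate.simulate`) produces timelines with
the same statistical structure — piecewise-constant baseline hazards,
covariate effects of realistic magnitude (HR ≈ 3.5 for high mixed
chimerism, ≈ 3.7 for early viral infection on the DLI1→tIS transition),
missing measurements and messy tIS episodes — plus exact
matrix-exponential oracles for every estimand.

## Worked example

```python
from dlimstate import (SimulationParams, simulate_cohort, corrupt_for_realism,
    select_subcohort, build_state_graph, prepare_transitions,
    MultiStateModel, fit_cox)

params = SimulationParams(n=400, seed=7, missing_chimerism=0.05)
sim = corrupt_for_realism(simulate_cohort(params))
sel = select_subcohort(sim.cohort, "three_month")

graph = build_state_graph("three_month")
table = prepare_transitions(sel.included, graph,
                            ("conditioning_donor", "chimerism_cat", "viral"))
res = MultiStateModel(table, graph).fit()
print(res.summary())

fit = fit_cox(table, ("dli1", "tis1"), ("conditioning_donor", "viral"))
print(fit)
```

prints

```
Nonparametric multi-state model (Aalen–Johansen)
  states: 14, transitions: 23, patients: 400
  endpoint                12 mo        60 mo
  cgrfs                 0.530       0.445
  alive_gvhd            0.055       0.005
  death_after_tis       0.185       0.243
  rfs                   0.585       0.450
  os                    0.643       0.455
Cox PH transition dli1 -> tis1 (ties=efron)
n=400 patients (0 excluded, incomplete cases), events=145, loglik=-772.6618, converged=True
                     term      coef       HR    lower    upper       se            p
conditioning_donor:MAC_UD -0.044994 0.956003 0.503881 1.813805 0.326751 8.904763e-01
conditioning_donor:RIC_RD  0.201299 1.222991 0.668748 2.236578 0.307989 5.133740e-01
conditioning_donor:RIC_UD  1.299946 3.669099 2.164171 6.220528 0.269346 1.390907e-06
              viral:early  1.215368 3.371534 2.411893 4.712997 0.170899 1.146975e-12
         viral:late_onset -0.184428 0.831580 0.260304 2.656607 0.592602 7.556352e-01
```

Reading the output: a year after the first DLI, 53% of this synthetic
cohort is alive, relapse-free and off immunosuppression (cGRFS), 5.5% is
alive with active GvHD, and 18.5% has died during GvHD treatment. cGRFS is
non-monotone — it dips while patients are on tIS and recovers as GvHD
resolves. The Cox fit recovers the generator's risk factors: an early
viral infection around DLI1 carries a hazard ratio of ≈3.4 (true 3.7) for
needing tIS, and reduced-intensity conditioning with an unrelated donor
≈3.7 (true 3.2); late-onset infections show no effect (true HR 1).

A command-line interface mirrors the library
(`dlimstate simulate|prepare|estimate|fit|predict|report|all`), writing
tidy CSV artifacts — baseline-characteristics summaries, exclusion accounting,
stacked state probabilities, CIF curves, Cox fit reports and
reference-patient predictions — from a YAML configuration.

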