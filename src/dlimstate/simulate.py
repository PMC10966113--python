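"""Synthetic cohort generation for the post-DLI multi-state analysis.

Trajectories follow a clock-forward, time-inhomogeneous Markov process on
the state graph: piecewise-constant baseline transition rates (events per
day on the time-since-DLI1 scale) multiplied by exp(covariate effects),
simulated by competing exponentials per constant-rate interval.  The
generator emits raw patient timelines in the cohort schema — tIS start/stop
pairs, possible restarts, a second DLI, relapse, death, viral-infection
events, chimerism and ALC measurements — alongside the true generating
trajectory, so every estimation stage can be checked against an exact
matrix-exponential oracle (:func:`true_occupancy`).

Default rates are calibrated so that roughly 28–30% of patients start tIS
within 3 months of DLI1 and about one patient in seven dies during tIS
within a year, with hazard ratios of the magnitude reported for mixed
chimerism, conditioning/donor type and early viral infection in this
clinical setting; these are plausibility anchors, not reproduction targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .graph import build_state_graph
from .timelines import DliEvent, PatientTimeline

__all__ = [
    "SimulationParams",
    "SimulatedCohort",
    "simulate_cohort",
    "corrupt_for_realism",
    "true_occupancy",
    "empirical_occupancy",
]

INF = math.inf


def default_rates() -> dict[tuple[str, str], tuple[tuple[float, float], ...]]:
    """Piecewise-constant baseline rates (t_end, events/day) per transition."""
    return {
        ("dli1", "tis1"): ((90, 8e-4), (180, 3e-4), (INF, 5e-5)),
        ("dli1", "relapse1"): ((180, 8e-4), (365, 3e-4), (INF, 4e-5)),
        ("dli1", "death1"): ((365, 3e-4), (INF, 4e-5)),
        ("dli1", "dli2"): ((150, 0.0), (240, 1.2e-2), (INF, 0.0)),
        ("tis1", "stop_tis1"): ((INF, 8e-3),),
        ("tis1", "relapse1"): ((INF, 1e-4),),
        ("tis1", "death_tis1"): ((INF, 3e-3),),
        ("tis1", "dli2"): ((INF, 0.0),),
        ("stop_tis1", "tis1"): ((365, 8e-4), (INF, 1e-4)),
        ("stop_tis1", "relapse1"): ((365, 3e-4), (INF, 4e-5)),
        ("stop_tis1", "death_tis1"): ((365, 6e-4), (INF, 8e-5)),
        ("stop_tis1", "dli2"): ((INF, 0.0),),
        ("relapse1", "death_relapse1"): ((INF, 4e-3),),
        ("dli2", "tis2"): ((365, 1.2e-3), (INF, 2e-4)),
        ("dli2", "relapse2"): ((365, 5e-4), (INF, 6e-5)),
        ("dli2", "death2"): ((365, 3e-4), (INF, 5e-5)),
        ("tis2", "stop_tis2"): ((INF, 8e-3),),
        ("tis2", "relapse2"): ((INF, 1e-4),),
        ("tis2", "death_tis2"): ((INF, 3e-3),),
        ("stop_tis2", "tis2"): ((365, 8e-4), (INF, 1e-4)),
        ("stop_tis2", "relapse2"): ((365, 3e-4), (INF, 4e-5)),
        ("stop_tis2", "death_tis2"): ((365, 6e-4), (INF, 8e-5)),
        ("relapse2", "death_relapse2"): ((INF, 4e-3),),
    }


def default_log_hr() -> dict[tuple[str, str], dict[tuple[str, str], float]]:
    """Covariate effects (log hazard ratios) per transition."""
    return {
        ("dli1", "tis1"): {
            ("conditioning_donor", "RIC_UD"): math.log(3.2),
            ("chimerism_cat", "lowMC"): math.log(2.0),
            ("chimerism_cat", "highMC"): math.log(3.5),
            ("viral", "early"): math.log(3.7),
        },
        ("tis1", "death_tis1"): {("chimerism_cat", "highMC"): math.log(2.0)},
    }


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort."""

    n: int
    seed: int
    dli1_day: float = 97.0  # 3.2 months after alloSCT
    planned_type: str = "three_month"
    censor_day: float = 1825.0  # administrative censoring, days since DLI1
    cond_donor_probs: dict = field(
        default_factory=lambda: {"MAC_RD": 0.19, "MAC_UD": 0.22, "RIC_RD": 0.25, "RIC_UD": 0.34}
    )
    chimerism_probs: tuple[float, float, float] = (0.33, 0.38, 0.29)  # FDC/lowMC/highMC
    alc3_probs: tuple[float, float, float] = (0.47, 0.33, 0.20)  # ge1000/c500_999/lt500
    p_pre_dli_viral: float = 0.28
    post_dli_viral_rate: float = 2e-3  # per day on (0, 56]
    rates: dict = field(default_factory=default_rates)
    log_hr: dict = field(default_factory=default_log_hr)
    # corruption settings (used by corrupt_for_realism)
    missing_chimerism: float = 0.0
    missing_alc: float = 0.0
    spurious_tis_rate: float = 0.0
    split_episode_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for probs in (self.chimerism_probs, self.alc3_probs):
            if abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                raise ValueError("category probabilities must form a simplex")
        if abs(sum(self.cond_donor_probs.values()) - 1) > 1e-9:
            raise ValueError("conditioning/donor probabilities must sum to 1")
        for pieces in self.rates.values():
            if any(r < 0 for _, r in pieces):
                raise ValueError("rates must be non-negative")
        if self.censor_day is None and all(
            r == 0 for pieces in self.rates.values() for _, r in pieces
        ):
            raise ValueError("all rates zero with no censoring: non-terminating")


@dataclass
class SimulatedCohort:
    params: SimulationParams
    cohort: list[PatientTimeline]
    truth: pd.DataFrame  # columns: id, state, t_in, t_out (days since DLI1)


_ALC_RANGES = {"ge1000": (1000, 2500), "c500_999": (500, 999), "lt500": (100, 499)}


def _static_multiplier(effects: dict, cov: dict) -> float:
    m = 0.0
    for (name, level), beta in effects.items():
        if name != "viral" and cov.get(name) == level:
            m += beta
    return math.exp(m)


def _viral_multiplier(effects: dict, level: str) -> float:
    return math.exp(effects.get(("viral", level), 0.0))


def _piecewise(pieces, t):
    for t_end, rate in pieces:
        if t < t_end:
            return rate
    return pieces[-1][1]


def _breakpoints(pieces):
    return [t for t, _ in pieces if t != INF]


def _sample_exit(rng, state, t0, outgoing, censor):
    """First transition out of ``state`` after t0; None when censored.

    ``outgoing`` is a list of (to_state, rate_fn, breakpoints) with
    ``rate_fn(t)`` the covariate-adjusted rate at time t.
    """
    bps = sorted({b for _, _, bp in outgoing for b in bp if t0 < b < censor})
    edges = [t0] + bps + [censor]
    for a, b in zip(edges, edges[1:]):
        lam = np.array([fn(a) for _, fn, _ in outgoing])
        total = lam.sum()
        if total > 0:
            dt = rng.exponential(1.0 / total)
            if a + dt <= b:
                k = rng.choice(len(outgoing), p=lam / total)
                return a + dt, outgoing[k][0]
    return None


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Simulate a cohort of patient timelines plus the generating truth."""
    rng = np.random.default_rng(params.seed)
    graph = build_state_graph("full")
    cohort, truth_rows = [], []

    cd_levels = list(params.cond_donor_probs)
    cd_probs = np.array([params.cond_donor_probs[k] for k in cd_levels])

    for i in range(params.n):
        pid = f"p{i:05d}"
        cond_donor = cd_levels[rng.choice(len(cd_levels), p=cd_probs)]
        conditioning, donor = cond_donor.split("_")
        chim_cat = ("FDC", "lowMC", "highMC")[
            rng.choice(3, p=np.asarray(params.chimerism_probs))
        ]
        alc_cat = ("ge1000", "c500_999", "lt500")[
            rng.choice(3, p=np.asarray(params.alc3_probs))
        ]
        age = float(np.clip(rng.normal(57, 10), 18, 76))

        pre_viral = rng.random() < params.p_pre_dli_viral
        t_viral = None
        if not pre_viral and params.post_dli_viral_rate > 0:
            tv = rng.exponential(1.0 / params.post_dli_viral_rate)
            if tv <= 56.0:
                t_viral = tv

        def viral_level(t):
            if pre_viral:
                return "early"
            if t_viral is not None and t >= t_viral:
                return "early" if t_viral <= 14.0 else "late_onset"
            return "none"

        cov = {
            "conditioning_donor": cond_donor,
            "chimerism_cat": chim_cat,
            "alc_cat3": alc_cat,
        }

        state, t = "dli1", 0.0
        sojourns = []
        while t < params.censor_day and graph.successors(state):
            outgoing = []
            for to in graph.successors(state):
                pieces = params.rates[(state, to)]
                effects = params.log_hr.get((state, to), {})
                static = _static_multiplier(effects, cov)
                has_viral = any(name == "viral" for name, _ in effects)
                bp = _breakpoints(pieces)
                if has_viral and t_viral is not None:
                    bp = bp + [t_viral]

                def rate_fn(u, pieces=pieces, static=static, effects=effects,
                            has_viral=has_viral):
                    r = _piecewise(pieces, u) * static
                    if has_viral:
                        r *= _viral_multiplier(effects, viral_level(u))
                    return r

                outgoing.append((to, rate_fn, bp))
            hit = _sample_exit(rng, state, t, outgoing, params.censor_day)
            if hit is None:
                sojourns.append((state, t, params.censor_day, None))
                break
            t_new, to = hit
            sojourns.append((state, t, t_new, to))
            state, t = to, t_new
        else:
            if not graph.successors(state):
                sojourns.append((state, t, params.censor_day, None))

        tl = _emit_timeline(pid, sojourns, params, rng, conditioning, donor, age,
                            chim_cat, alc_cat, pre_viral, t_viral)
        cohort.append(tl)
        for s, a, b, nxt in sojourns:
            truth_rows.append((pid, s, a, b, nxt))

    truth = pd.DataFrame(truth_rows, columns=["id", "state", "t_in", "t_out", "to"])
    return SimulatedCohort(params, cohort, truth)


def _emit_timeline(pid, sojourns, params, rng, conditioning, donor, age,
                   chim_cat, alc_cat, pre_viral, t_viral):
    d0 = params.dli1_day
    tl = PatientTimeline(
        patient_id=pid,
        conditioning=conditioning,
        donor=donor,
        age_at_sct=age,
        dli_events=[DliEvent(d0, 1, params.planned_type)],
    )
    episodes = []
    for state, a, b, nxt in sojourns:
        if state in ("tis1", "tis2"):
            # a tIS sojourn ends at the stop transition, at death, or at the
            # end of follow-up; on relapse the tIS realistically continues
            # (the model stops tracking it), so the episode runs on to the
            # end of the path and the analysis ignores that part
            end = None if nxt in ("relapse1", "relapse2") else b
            episodes.append([a, end])
        if nxt == "dli2":
            tl.dli_events.append(DliEvent(d0 + b, 2, "other"))
        if nxt in ("relapse1", "relapse2"):
            tl.relapse_day = d0 + b
        if nxt in ("death1", "death_tis1", "death_relapse1",
                   "death2", "death_tis2", "death_relapse2"):
            tl.death_day = d0 + b
            tl.death_cause_gvhd = nxt in ("death_tis1", "death_tis2")
    path_end = tl.death_day - d0 if tl.death_day is not None else params.censor_day
    tl.tis_episodes_raw = [
        (d0 + s, d0 + (t if t is not None else path_end)) for s, t in episodes
    ]
    if tl.death_day is None:
        tl.last_followup_day = d0 + params.censor_day

    # measurements in the look-back window before DLI1
    chim_val = {"FDC": 0.0, "lowMC": None, "highMC": None}[chim_cat]
    if chim_val is None:
        lo, hi = (0.5, 4.9) if chim_cat == "lowMC" else (5.0, 40.0)
        chim_val = float(np.round(rng.uniform(lo, hi), 1))
    tl.chimerism_obs = [(d0 - 7.0, chim_val)]
    lo, hi = _ALC_RANGES[alc_cat]
    tl.alc_obs = [(d0 - 2.0, float(np.round(rng.uniform(lo, hi))))]

    exit_dli1 = next((b for s, a, b, nxt in sojourns if s == "dli1"), 0.0)
    if pre_viral:
        tl.viral_infections = [(d0 - float(rng.integers(0, 8)), "CMV")]
    elif t_viral is not None and t_viral < exit_dli1:
        tl.viral_infections = [(d0 + t_viral, "CMV")]
    return tl


def corrupt_for_realism(
    sim: SimulatedCohort, seed: int | None = None
) -> SimulatedCohort:
    """Inject realistic mess: missing covariates, spurious and split episodes.

    Missing chimerism/ALC measurements, short (<14 d) spurious tIS episodes
    far from real ones, and near-gap episode pairs exercise the cleaning
    rules end to end; consolidation restores the clean timeline exactly.
    """
    p = sim.params
    rng = np.random.default_rng(p.seed + 1 if seed is None else seed)
    out = []
    for tl in sim.cohort:
        tl = replace(tl, tis_episodes_raw=list(tl.tis_episodes_raw),
                     chimerism_obs=list(tl.chimerism_obs), alc_obs=list(tl.alc_obs))
        if rng.random() < p.missing_chimerism:
            tl.chimerism_obs = []
        if rng.random() < p.missing_alc:
            tl.alc_obs = []
        if rng.random() < p.split_episode_rate:
            for j, (s, t) in enumerate(tl.tis_episodes_raw):
                if t - s > 60:  # split into a near-gap pair; consolidation re-merges
                    m = (s + t) / 2
                    tl.tis_episodes_raw[j: j + 1] = [(s, m), (m + 20, t)]
                    break
        if rng.random() < p.spurious_tis_rate:
            spot = _spurious_slot(tl, p)
            if spot is not None:
                tl.tis_episodes_raw = sorted(tl.tis_episodes_raw + [(spot, spot + 4)])
        out.append(tl)
    return SimulatedCohort(p, out, sim.truth)


def _spurious_slot(tl: PatientTimeline, p: SimulationParams) -> float | None:
    """A day where a 5-day episode is guaranteed to be dropped by cleaning."""
    d0 = tl.dli_events[0].day
    end = tl.followup_end - 40
    day = d0 + 30
    while day < end:
        lo, hi = day - 66, day + 70
        clear = all(t < lo or s > hi for s, t in tl.tis_episodes_raw)
        if clear and (tl.relapse_day is None or day + 10 < tl.relapse_day):
            return day
        day += 30
    return None


def true_occupancy(
    params: SimulationParams, pattern: dict, times
) -> pd.DataFrame:
    """Exact state-occupation probabilities for a fixed covariate pattern.

    Chains matrix exponentials of the generator matrix over its
    constant-rate intervals.  The pattern fixes every covariate, including a
    constant viral level, so the result is the oracle for estimators and
    predictions at that pattern.
    """
    graph = build_state_graph("full")
    states = list(graph.states)
    idx = {s: i for i, s in enumerate(states)}
    times = np.asarray(sorted(times), float)

    bps = {0.0, *times.tolist()}
    for pieces in params.rates.values():
        bps.update(_breakpoints(pieces))
    bps = sorted(b for b in bps if 0.0 <= b <= times.max())
    if bps[-1] < times.max():
        bps.append(times.max())

    def q_matrix(t):
        Q = np.zeros((len(states), len(states)))
        for (a, b), pieces in params.rates.items():
            effects = params.log_hr.get((a, b), {})
            mult = math.exp(
                sum(
                    beta
                    for (name, level), beta in effects.items()
                    if pattern.get(name) == level
                )
            )
            r = _piecewise(pieces, t) * mult
            Q[idx[a], idx[b]] += r
            Q[idx[a], idx[a]] -= r
        return Q

    P = np.eye(len(states))
    out = {}
    t_prev = 0.0
    want = set(times.tolist())
    if 0.0 in want:
        out[0.0] = P[idx["dli1"]].copy()
    for b in bps:
        if b <= t_prev:
            continue
        P = P @ expm(q_matrix(t_prev) * (b - t_prev))
        t_prev = b
        if b in want:
            out[b] = P[idx["dli1"]].copy()
    rows = [out[t] for t in times]
    return pd.DataFrame(rows, index=pd.Index(times, name="time"), columns=states)


def empirical_occupancy(truth: pd.DataFrame, times, states) -> pd.DataFrame:
    """Fraction of simulated trajectories in each state at each time."""
    n = truth["id"].nunique()
    times = np.asarray(sorted(times), float)
    counts = pd.DataFrame(0.0, index=pd.Index(times, name="time"), columns=list(states))
    for t in times:
        # occupant of state s at t: sojourn with t_in <= t < t_out, or the
        # final (absorbing/censored) sojourn when t >= t_in
        occ = truth[(truth["t_in"] <= t) & ((t < truth["t_out"]) | truth["to"].isna())]
        occ = occ.sort_values("t_in").groupby("id").tail(1)
        for s, c in occ["state"].value_counts().items():
            counts.loc[t, s] = c / n
    return counts
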