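"""Multi-state model structure and long-format transition data.

The model tracks a patient from the first donor lymphocyte infusion (DLI1)
through GvHD episodes (operationalised as therapeutic immunosuppression,
tIS), relapse, a second DLI and death.  Events after DLI1 and after DLI2
get separate states so that composite endpoints (cGRFS, RFS, OS, alive with
GvHD, death after tIS) can be read off state-occupation probabilities.  The
time scale is clock-forward: days since DLI1 for every transition.

:func:`prepare_transitions` converts consolidated patient timelines into the
long counting-process format used throughout survival analysis: one row per
patient x at-risk transition x covariate-constant interval, with columns
``(id, from, to, trans, Tstart, Tstop, status, ...covariates)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .timelines import PatientTimeline, TimelineError, covariate_profile

__all__ = [
    "StateGraph",
    "build_state_graph",
    "prepare_transitions",
    "resolve_same_day",
    "TIE_PRECEDENCE",
]

#: deterministic ordering of same-day events (earlier acts first)
TIE_PRECEDENCE = ("dli2", "tis_start", "tis_stop", "relapse", "death")

_BLOCK1 = [
    "dli1", "tis1", "stop_tis1", "relapse1",
    "death1", "death_tis1", "death_relapse1",
]
_BLOCK2 = [
    "dli2", "tis2", "stop_tis2", "relapse2",
    "death2", "death_tis2", "death_relapse2",
]

_TRANSITIONS = [
    ("dli1", "tis1"), ("dli1", "relapse1"), ("dli1", "death1"), ("dli1", "dli2"),
    ("tis1", "stop_tis1"), ("tis1", "relapse1"), ("tis1", "death_tis1"), ("tis1", "dli2"),
    ("stop_tis1", "tis1"), ("stop_tis1", "relapse1"), ("stop_tis1", "death_tis1"),
    ("stop_tis1", "dli2"),
    ("relapse1", "death_relapse1"),
    ("dli2", "tis2"), ("dli2", "relapse2"), ("dli2", "death2"),
    ("tis2", "stop_tis2"), ("tis2", "relapse2"), ("tis2", "death_tis2"),
    ("stop_tis2", "tis2"), ("stop_tis2", "relapse2"), ("stop_tis2", "death_tis2"),
    ("relapse2", "death_relapse2"),
]

_GROUPS = {
    "cgrfs": ("dli1", "stop_tis1", "dli2", "stop_tis2"),
    "alive_gvhd": ("tis1", "tis2"),
    "death_after_tis": ("death_tis1", "death_tis2"),
}


@dataclass(frozen=True)
class StateGraph:
    """States, allowed transitions and composite-endpoint groupings."""

    variant: str
    states: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]
    start_states: tuple[str, ...]
    composite_groups: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        idx = {s: i for i, s in enumerate(self.states)}
        object.__setattr__(self, "_index", idx)
        object.__setattr__(
            self, "_trans_no", {t: i + 1 for i, t in enumerate(self.transitions)}
        )
        out: dict[str, list[str]] = {s: [] for s in self.states}
        for a, b in self.transitions:
            out[a].append(b)
        object.__setattr__(self, "_out", out)
        for grp, ss in self.composite_groups.items():
            if not ss <= set(self.states):
                raise ValueError(f"composite group {grp} references unknown states")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self._index[state]

    def transition_number(self, from_state: str, to_state: str) -> int:
        return self._trans_no[(from_state, to_state)]

    def successors(self, state: str) -> tuple[str, ...]:
        return tuple(self._out[state])

    @property
    def absorbing(self) -> frozenset:
        return frozenset(s for s in self.states if not self._out[s])

    @property
    def transient(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if self._out[s])

    def group(self, name: str) -> frozenset:
        return self.composite_groups[name]

    def transition_matrix(self) -> pd.DataFrame:
        """mstate-style matrix of transition numbers (NaN = not allowed)."""
        mat = pd.DataFrame(float("nan"), index=self.states, columns=self.states)
        for (a, b), no in self._trans_no.items():
            mat.loc[a, b] = no
        return mat

    def to_json(self) -> str:
        return json.dumps(
            dict(
                variant=self.variant,
                states=list(self.states),
                transitions=[list(t) for t in self.transitions],
                start_states=list(self.start_states),
                composite_groups={k: sorted(v) for k, v in self.composite_groups.items()},
            ),
            indent=2,
        )

    def reduced_to(self, used_states) -> "StateGraph":
        """Drop states (and their transitions) that are never occupied."""
        keep = set(used_states) | set(self.start_states)
        return StateGraph(
            variant=self.variant,
            states=tuple(s for s in self.states if s in keep),
            transitions=tuple(t for t in self.transitions if t[0] in keep and t[1] in keep),
            start_states=self.start_states,
            composite_groups={
                k: frozenset(s for s in v if s in keep)
                for k, v in self.composite_groups.items()
            },
        )


def _full_groups() -> dict[str, frozenset]:
    g = {k: frozenset(v) for k, v in _GROUPS.items()}
    g["rfs"] = g["cgrfs"] | g["alive_gvhd"]
    g["os"] = g["rfs"] | frozenset({"relapse1", "relapse2"})
    return g


def build_state_graph(variant: str = "full") -> StateGraph:
    """Build the multi-state model for a given analysis variant.

    ``full``, ``three_month`` and ``six_month`` share the 14-state structure
    (seven states per DLI block); the subcohort variants exist so a run can
    be validated against the cohort it is applied to.  ``two_start_viral``
    duplicates the graph into two branches with starting states 'DLI1
    without early viral infection' and 'DLI1 with early viral infection';
    branch membership is fixed at baseline.
    """
    if variant in ("full", "three_month", "six_month"):
        return StateGraph(
            variant=variant,
            states=tuple(_BLOCK1 + _BLOCK2),
            transitions=tuple(_TRANSITIONS),
            start_states=("dli1",),
            composite_groups=_full_groups(),
        )
    if variant == "two_start_viral":
        states, transitions, groups = [], [], {}
        for suf in ("_nv", "_ev"):
            states += [s + suf for s in _BLOCK1 + _BLOCK2]
            transitions += [(a + suf, b + suf) for a, b in _TRANSITIONS]
        base = _full_groups()
        for k, v in base.items():
            groups[k] = frozenset(s + suf for s in v for suf in ("_nv", "_ev"))
        return StateGraph(
            variant=variant,
            states=tuple(states),
            transitions=tuple(transitions),
            start_states=("dli1_nv", "dli1_ev"),
            composite_groups=groups,
        )
    raise ValueError(f"unknown model variant {variant!r}")


def resolve_same_day(events: list[tuple[float, str]]) -> list[tuple[float, str]]:
    """Order same-day events by clinical precedence, offsetting by half days.

    Two events of the same type on one day are rejected.  Within a tied day
    the i-th event (by precedence DLI2 < tIS start < tIS stop < relapse <
    death) is shifted by +0.5 x i days so every interval stays positive.
    """
    for t, kind in events:
        if kind not in TIE_PRECEDENCE:
            raise ValueError(f"unknown event kind {kind!r}")
    out = []
    by_day: dict[float, list[str]] = {}
    for t, kind in events:
        by_day.setdefault(t, []).append(kind)
    for t in sorted(by_day):
        kinds = by_day[t]
        if len(kinds) != len(set(kinds)):
            raise TimelineError(f"two events of the same type on day {t}")
        for i, kind in enumerate(sorted(kinds, key=TIE_PRECEDENCE.index)):
            out.append((t + 0.5 * i, kind))
    return out


def _walk(tl: PatientTimeline, events, censor_t, start_state, suffix=""):
    """Run the state machine over resolved events; return sojourn records.

    Each record is ``(state, t_in, t_out, next_state)`` with ``next_state``
    None for the final censored sojourn.
    """

    def st(name):
        return name + suffix

    pid = tl.patient_id
    state = start_state
    t = 0.0
    sojourns = []
    phase = 1  # before/after DLI2

    def move(to, when):
        nonlocal state, t
        if when <= t:
            raise TimelineError(f"{pid}: zero-length interval at t={when}")
        sojourns.append((state, t, when, to))
        state, t = to, when

    for when, kind in events:
        if when > censor_t:
            raise TimelineError(f"{pid}: event {kind} after end of follow-up")
        base = state[: len(state) - len(suffix)] if suffix else state
        if base in ("death1", "death_tis1", "death_relapse1", "death2",
                    "death_tis2", "death_relapse2"):
            raise TimelineError(f"{pid}: event {kind} after death")
        if base in ("relapse1", "relapse2"):
            if kind == "death":
                move(st("death_relapse1" if phase == 1 else "death_relapse2"), when)
            # tIS and further DLIs after relapse are outside the model
            continue
        if kind == "dli2":
            if phase == 2:
                continue  # third and later DLIs are ignored
            if base == "tis1":
                raise TimelineError(
                    f"{pid}: tIS episode spans DLI2 — sequence not representable"
                )
            move(st("dli2"), when)
            phase = 2
            continue
        if kind == "tis_start":
            if base not in ("dli1", "stop_tis1", "dli2", "stop_tis2"):
                raise TimelineError(f"{pid}: tis_start while in state {state}")
            move(st("tis1" if phase == 1 else "tis2"), when)
        elif kind == "tis_stop":
            if base not in ("tis1", "tis2"):
                raise TimelineError(f"{pid}: tis_stop without active tIS (state {state})")
            move(st("stop_tis1" if phase == 1 else "stop_tis2"), when)
        elif kind == "relapse":
            move(st("relapse1" if phase == 1 else "relapse2"), when)
        elif kind == "death":
            if base in ("tis1", "stop_tis1"):
                move(st("death_tis1"), when)
            elif base in ("tis2", "stop_tis2"):
                move(st("death_tis2"), when)
            elif base == "dli1":
                move(st("death1"), when)
            elif base == "dli2":
                move(st("death2"), when)
    if t < censor_t:
        sojourns.append((state, t, censor_t, None))
    return sojourns


def _patient_events(tl: PatientTimeline, t0: float, censor_t: float):
    """Assemble the event stream (times since DLI1) for one patient."""
    events: list[tuple[float, str]] = []
    later_dlis = sorted(d.day for d in tl.dli_events if d.day > t0)
    if later_dlis:
        events.append((later_dlis[0] - t0, "dli2"))
    eps = tl.tis_episodes if tl.tis_episodes is not None else []
    for ep in eps:
        if ep.start < t0:
            raise TimelineError(f"{tl.patient_id}: tIS before DLI1 is not modelable")
        start_t = ep.start - t0
        # an episode starting on the DLI1 day itself is shifted half a day
        # so the DLI1 sojourn keeps positive length
        events.append((start_t if start_t > 0 else 0.5, "tis_start"))
        stop_t = ep.stop - t0
        ends_at_death = tl.death_day is not None and ep.stop >= tl.death_day
        ongoing = stop_t >= censor_t
        if not ends_at_death and not ongoing:
            events.append((stop_t, "tis_stop"))
    if tl.relapse_day is not None:
        events.append((tl.relapse_day - t0, "relapse"))
    if tl.death_day is not None:
        events.append((tl.death_day - t0, "death"))
    return resolve_same_day(events)


_FIXED_COVARIATES = {
    "conditioning_donor": lambda tl, prof: prof.conditioning_donor,
    "chimerism_cat": lambda tl, prof: prof.chimerism_cat,
    "alc_cat3": lambda tl, prof: prof.alc_cat3,
    "alc_cat2": lambda tl, prof: prof.alc_cat2,
    "age_at_sct": lambda tl, prof: tl.age_at_sct,
}


def prepare_transitions(
    cohort: list[PatientTimeline],
    graph: StateGraph,
    covariates: tuple[str, ...] = (),
    episodes: str = "consolidated",
) -> pd.DataFrame:
    """Long-format at-risk records for every patient and transition.

    For each sojourn in a transient state, one row per outgoing transition
    is emitted over the sojourn interval, with ``status`` 1 on the realised
    transition and 0 on the competing ones (censored at that time).  Rows
    are split at every change point of a time-varying covariate (the viral
    track).  Administrative censoring is at the end of follow-up.

    ``episodes='consolidated'`` applies the GvHD cleaning rules (minimum
    length, merge gap, pre-death extension) to the raw tIS intervals;
    ``'verbatim'`` takes them at face value, which is appropriate when the
    input is already episode-level truth (e.g. simulator output used for
    estimator-consistency checks).
    """
    if episodes not in ("consolidated", "verbatim"):
        raise ValueError(f"unknown episode handling {episodes!r}")
    two_start = graph.variant == "two_start_viral"
    time_varying = "viral" in covariates
    fixed = [c for c in covariates if c != "viral"]
    for c in fixed:
        if c not in _FIXED_COVARIATES:
            raise ValueError(f"unknown covariate {c!r}")

    rows = []
    for tl in cohort:
        if episodes == "verbatim":
            from dataclasses import replace as _replace

            from .timelines import TisEpisode

            tl = _replace(tl, tis_episodes=[TisEpisode(s, t) for s, t in tl.tis_episodes_raw])
        elif tl.tis_episodes is None:
            tl = tl.consolidate()
        dli = tl.first_dli
        if dli is None:
            raise TimelineError(f"{tl.patient_id}: no DLI1, cannot anchor the clock")
        t0 = dli.day
        censor_t = tl.followup_end - t0
        if censor_t < 0:
            raise TimelineError(f"{tl.patient_id}: follow-up ends before DLI1")
        prof = covariate_profile(tl)
        track = prof.viral_track
        if two_start:
            suffix = "_ev" if track.level0 == "early" else "_nv"
            start_state = "dli1" + suffix
        else:
            suffix = ""
            start_state = graph.start_states[0]
        events = _patient_events(tl, t0, censor_t)
        sojourns = _walk(tl, events, censor_t, start_state, suffix)
        cov_vals = {c: _FIXED_COVARIATES[c](tl, prof) for c in fixed}

        for state, t_in, t_out, nxt in sojourns:
            succ = graph.successors(state)
            if not succ:
                continue
            if nxt is not None and nxt not in succ:
                raise TimelineError(
                    f"{tl.patient_id}: transition {state} -> {nxt} not in graph"
                )
            cuts = [t_in, t_out]
            if time_varying:
                cuts += [c for c in track.change_points if t_in < c < t_out]
            cuts = sorted(set(cuts))
            for a, b in zip(cuts, cuts[1:]):
                for k in succ:
                    row = dict(
                        id=tl.patient_id,
                        **{"from": state, "to": k},
                        trans=graph.transition_number(state, k),
                        Tstart=a,
                        Tstop=b,
                        status=int(b == t_out and nxt == k),
                    )
                    row.update(cov_vals)
                    if time_varying:
                        row["viral"] = track.level_at(a)
                    rows.append(row)

    cols = ["id", "from", "to", "trans", "Tstart", "Tstop", "status"] + list(covariates)
    table = pd.DataFrame(rows, columns=cols)
    if len(table) and (table["Tstart"] >= table["Tstop"]).any():
        raise TimelineError("zero-length at-risk interval after tie resolution")
    return table
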