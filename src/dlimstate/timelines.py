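"""Patient event histories and cohort construction.

A :class:`PatientTimeline` holds one patient's dated clinical events on a
calendar whose origin (day 0) is the allogeneic stem-cell transplantation
(alloSCT).  Clinically relevant graft-versus-host disease (GvHD) is defined
operationally through therapeutic systemic immunosuppression (tIS): an
episode of tIS marks a GvHD episode, with exact start and stop dates.  This
module implements the episode-consolidation rules, the covariate
categorisations measured at the first donor lymphocyte infusion (DLI1) —
bone-marrow chimerism, absolute lymphocyte count (ALC), and the time-varying
viral-infection status — the subcohort eligibility rules for the low-dose
3-month DLI and the 6-month DLI, and baseline summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

DAYS_PER_MONTH = 30.4375
#: minimum tIS episode length (closed interval, stop - start + 1) to count as GvHD
MIN_TIS_DAYS = 14
#: episodes restarting within this gap are one GvHD episode ("2 months")
MERGE_GAP_DAYS = 61
#: tIS stopped within this window before a GvHD death is extended to death
DEATH_EXTENSION_DAYS = 7
#: look-back window for "measurement at time of DLI": (DLI-28, DLI+3) days
MEASUREMENT_WINDOW = (-28.0, 3.0)
#: viral infections count from one week before DLI1 ...
VIRAL_PRE_WINDOW_DAYS = 7
#: ... until eight weeks after; 'early' means within two weeks after
VIRAL_EARLY_DAYS = 14
VIRAL_POST_WINDOW_DAYS = 56

CHIMERISM_LEVELS = ("FDC", "lowMC", "highMC")
ALC3_LEVELS = ("ge1000", "c500_999", "lt500")
ALC2_LEVELS = ("ge1000", "lt1000")
VIRAL_LEVELS = ("none", "early", "late_onset")
CONDITIONING_DONOR_LEVELS = ("MAC_RD", "MAC_UD", "RIC_RD", "RIC_UD")
UNKNOWN = "unknown"

#: when several exclusion reasons apply, report the first of these
EXCLUSION_PRECEDENCE = (
    "relapse",
    "death",
    "graft_failure",
    "prior_gvhd",
    "modified_product",
    "timing",
    "other",
)


class TimelineError(ValueError):
    """A patient timeline violates a structural rule."""


@dataclass(frozen=True)
class DliEvent:
    day: float
    ordinal: int
    planned_type: str  # three_month | six_month | other


@dataclass(frozen=True)
class TisEpisode:
    """One consolidated episode of therapeutic immunosuppression (closed days)."""

    start: float
    stop: float
    merged_from: int = 1

    @property
    def length(self) -> float:
        return self.stop - self.start + 1


@dataclass
class PatientTimeline:
    """Dated clinical events for one patient; day 0 is the alloSCT."""

    patient_id: str
    allosct_day: float = 0.0
    dli_events: list[DliEvent] = field(default_factory=list)
    tis_episodes_raw: list[tuple[float, float]] = field(default_factory=list)
    relapse_day: float | None = None
    death_day: float | None = None
    death_cause_gvhd: bool | None = None
    viral_infections: list[tuple[float, str]] = field(default_factory=list)
    chimerism_obs: list[tuple[float, object]] = field(default_factory=list)
    alc_obs: list[tuple[float, float]] = field(default_factory=list)
    graft_failure_day: float | None = None
    last_followup_day: float | None = None
    conditioning: str | None = None  # MAC | RIC
    donor: str | None = None  # RD | UD
    age_at_sct: float | None = None
    extra: dict = field(default_factory=dict)

    # consolidated episodes, filled by consolidate()
    tis_episodes: list[TisEpisode] | None = None

    def validate(self) -> None:
        days = [d.day for d in self.dli_events]
        days += [s for s, _ in self.tis_episodes_raw] + [t for _, t in self.tis_episodes_raw]
        days += [d for d, _ in self.viral_infections]
        if self.relapse_day is not None:
            days.append(self.relapse_day)
        if any(d < 0 for d in days):
            raise TimelineError(f"{self.patient_id}: negative event day")
        if self.death_day is not None and any(d > self.death_day for d in days):
            raise TimelineError(f"{self.patient_id}: event after death")

    def consolidate(self) -> "PatientTimeline":
        """Return a copy with tIS episodes consolidated per the GvHD rules."""
        eps = consolidate_tis_episodes(
            self.tis_episodes_raw, self.death_day, bool(self.death_cause_gvhd)
        )
        return replace(self, tis_episodes=eps)

    @property
    def first_dli(self) -> DliEvent | None:
        return min(self.dli_events, key=lambda d: d.day) if self.dli_events else None

    @property
    def followup_end(self) -> float:
        if self.death_day is not None:
            return self.death_day
        if self.last_followup_day is not None:
            return self.last_followup_day
        raise TimelineError(f"{self.patient_id}: no follow-up end")

    @property
    def conditioning_donor(self) -> str:
        if self.conditioning in ("MAC", "RIC") and self.donor in ("RD", "UD"):
            return f"{self.conditioning}_{self.donor}"
        return UNKNOWN


def consolidate_tis_episodes(
    raw: list[tuple[float, float]],
    death_day: float | None = None,
    death_cause_gvhd: bool = False,
    *,
    min_length: float = MIN_TIS_DAYS,
    merge_gap: float = MERGE_GAP_DAYS,
    death_window: float = DEATH_EXTENSION_DAYS,
) -> list[TisEpisode]:
    """Consolidate raw tIS intervals into GvHD episodes.

    Episodes restarting within ``merge_gap`` days are combined into one;
    an episode stopped within ``death_window`` days before a death from GvHD
    is extended to the death day; episodes shorter than ``min_length`` days
    (closed-interval length stop - start + 1) are discarded unless they end
    at death.
    """
    eps = sorted(raw)
    for start, stop in eps:
        if stop < start:
            raise TimelineError(f"tIS interval with stop < start: ({start}, {stop})")
        if death_day is not None and stop > death_day:
            raise TimelineError(f"tIS stop {stop} after death {death_day}")
    for (s1, t1), (s2, t2) in zip(eps, eps[1:]):
        if s2 <= t1:
            raise TimelineError(f"overlapping raw tIS intervals ({s1},{t1}) and ({s2},{t2})")

    merged: list[TisEpisode] = []
    for start, stop in eps:
        if merged and start - merged[-1].stop < merge_gap:
            prev = merged[-1]
            merged[-1] = TisEpisode(prev.start, stop, prev.merged_from + 1)
        else:
            merged.append(TisEpisode(start, stop))

    out: list[TisEpisode] = []
    for ep in merged:
        stop = ep.stop
        if (
            death_day is not None
            and death_cause_gvhd
            and stop < death_day
            and death_day - stop <= death_window
        ):
            stop = death_day
        ends_at_death = death_day is not None and stop == death_day
        if stop - ep.start + 1 >= min_length or ends_at_death:
            out.append(TisEpisode(ep.start, stop, ep.merged_from))
    return out


def classify_chimerism(measurement) -> str:
    """Categorise a bone-marrow chimerism measurement at DLI.

    ``measurement`` is the percentage of patient-derived material (0 means
    none detectable, hence full donor chimerism), the string ``"detected"``
    for detectable-but-unquantified patient material, or None for missing.
    """
    if measurement is None:
        return UNKNOWN
    if isinstance(measurement, str):
        if measurement == "detected":
            return "lowMC"
        raise TimelineError(f"unrecognised chimerism value {measurement!r}")
    pct = float(measurement)
    if not 0.0 <= pct <= 100.0:
        raise TimelineError(f"chimerism percentage out of range: {pct}")
    if pct == 0.0:
        return "FDC"
    return "lowMC" if pct < 5.0 else "highMC"


def classify_alc(count: float | None, scheme: str = "three_level") -> str:
    """Categorise an absolute lymphocyte count (10^6/l) at DLI."""
    if count is None:
        return UNKNOWN
    if count < 0:
        raise TimelineError(f"negative ALC: {count}")
    if scheme == "three_level":
        if count >= 1000:
            return "ge1000"
        return "c500_999" if count >= 500 else "lt500"
    if scheme == "two_level":
        return "ge1000" if count >= 1000 else "lt1000"
    raise ValueError(f"unknown ALC scheme {scheme!r}")


def measurement_at_dli(
    obs: list[tuple[float, object]],
    dli_day: float,
    window: tuple[float, float] = MEASUREMENT_WINDOW,
):
    """Most recent observation within the look-back window around a DLI."""
    lo, hi = dli_day + window[0], dli_day + window[1]
    cands = [(day, val) for day, val in obs if lo <= day <= hi]
    if not cands:
        return None
    return max(cands, key=lambda p: p[0])[1]


@dataclass(frozen=True)
class ViralTrack:
    """Piecewise-constant viral-infection status on the time-since-DLI1 clock.

    The level starts at ``level0`` and, if ``switch_time`` is not None,
    changes once to ``switch_level`` at that time; it never changes again.
    """

    level0: str
    switch_time: float | None = None
    switch_level: str | None = None

    def level_at(self, t: float) -> str:
        if self.switch_time is not None and t >= self.switch_time:
            return self.switch_level
        return self.level0

    @property
    def change_points(self) -> list[float]:
        return [] if self.switch_time is None else [self.switch_time]


def build_viral_track(
    infections: list[tuple[float, str]],
    dli1_day: float,
    *,
    relapse_day: float | None = None,
    dli2_day: float | None = None,
    tis_start_days: list[float] = (),
) -> ViralTrack:
    """Derive the time-varying viral covariate from PCR-confirmed infections.

    Infections within one week before DLI1 set the status to ``early`` from
    time 0.  Otherwise the first infection within two weeks after DLI1
    switches the status to ``early``, and the first infection between two and
    eight weeks to ``late_onset``.  Infections after a relapse, a second DLI
    or a tIS start, or beyond eight weeks, are ignored; the status changes at
    most once.
    """
    days = sorted(d for d, _ in infections)
    if any(dli1_day - VIRAL_PRE_WINDOW_DAYS <= d <= dli1_day for d in days):
        return ViralTrack("early")
    censors = [c for c in (relapse_day, dli2_day, *tis_start_days) if c is not None]
    cutoff = min(censors) if censors else math.inf
    for d in days:
        if d <= dli1_day or d >= cutoff:
            continue
        t = d - dli1_day
        if t > VIRAL_POST_WINDOW_DAYS:
            break
        if t <= VIRAL_EARLY_DAYS:
            return ViralTrack("none", t, "early")
        return ViralTrack("none", t, "late_onset")
    return ViralTrack("none")


@dataclass
class CovariateProfile:
    """Covariate values fixed at DLI1 plus the time-varying viral track."""

    conditioning_donor: str
    chimerism_cat: str
    alc_cat3: str
    alc_cat2: str
    viral_track: ViralTrack


def covariate_profile(tl: PatientTimeline) -> CovariateProfile:
    """Categorise a patient's covariates at their first DLI."""
    dli = tl.first_dli
    if dli is None:
        raise TimelineError(f"{tl.patient_id}: no DLI, covariates undefined")
    chim = measurement_at_dli(tl.chimerism_obs, dli.day)
    alc = measurement_at_dli(tl.alc_obs, dli.day)
    eps = tl.tis_episodes
    if eps is None:
        eps = consolidate_tis_episodes(
            tl.tis_episodes_raw, tl.death_day, bool(tl.death_cause_gvhd)
        )
    dli2 = [d.day for d in tl.dli_events if d.day > dli.day]
    track = build_viral_track(
        tl.viral_infections,
        dli.day,
        relapse_day=tl.relapse_day,
        dli2_day=min(dli2) if dli2 else None,
        tis_start_days=[e.start for e in eps if e.start > dli.day],
    )
    return CovariateProfile(
        conditioning_donor=tl.conditioning_donor,
        chimerism_cat=classify_chimerism(chim),
        alc_cat3=classify_alc(alc, "three_level"),
        alc_cat2=classify_alc(alc, "two_level"),
        viral_track=track,
    )


@dataclass
class SubcohortSelection:
    included: list[PatientTimeline]
    exclusions: pd.DataFrame  # columns: patient_id, reason


_WINDOW_MONTHS = {"three_month": 6.0, "six_month": 9.0}


def select_subcohort(cohort: list[PatientTimeline], which: str) -> SubcohortSelection:
    """Select the low-dose 3-month or the 6-month DLI subcohort.

    A patient is included when their first DLI is of the requested planned
    type, is given within the timing window (6 or 9 months after alloSCT),
    and is not preceded by relapse, death, graft failure, consolidated tIS
    for GvHD, or a modified cellular product.  Excluded patients are
    returned with a single machine-readable reason chosen by precedence.
    """
    if which not in _WINDOW_MONTHS:
        raise ValueError(f"unknown subcohort {which!r}")
    window_days = _WINDOW_MONTHS[which] * DAYS_PER_MONTH
    included, excluded = [], []

    for tl in cohort:
        tl = tl.consolidate() if tl.tis_episodes is None else tl
        dli = tl.first_dli
        cutoff = dli.day if dli is not None else math.inf
        reasons = set()
        if tl.relapse_day is not None and tl.relapse_day < cutoff:
            reasons.add("relapse")
        if tl.death_day is not None and tl.death_day < cutoff:
            reasons.add("death")
        if tl.graft_failure_day is not None and tl.graft_failure_day < cutoff:
            reasons.add("graft_failure")
        if any(e.start < cutoff for e in tl.tis_episodes):
            reasons.add("prior_gvhd")
        if dli is not None and dli.planned_type == "other":
            reasons.add("modified_product")
        if dli is None:
            reasons.add("other")
        elif not reasons:
            if dli.planned_type != which:
                reasons.add("other")
            elif dli.day - tl.allosct_day > window_days:
                reasons.add("timing")
        if reasons:
            reason = next(r for r in EXCLUSION_PRECEDENCE if r in reasons)
            excluded.append((tl.patient_id, reason))
        else:
            included.append(tl)

    exc = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return SubcohortSelection(included, exc)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def summarize_cohort(
    counts: dict[str, dict[str, int]] | list[PatientTimeline],
    covariates: tuple[str, ...] = ("conditioning_donor", "chimerism_cat", "alc_cat3"),
) -> pd.DataFrame:
    """Baseline characteristics table: counts and percentages per category.

    Percentages are computed over patients with known values (unknown is
    listed as a count without a percentage) and rounded half away from zero.
    Accepts either a cohort of timelines or a pre-tabulated mapping
    ``{covariate: {level: count}}``.
    """
    if not isinstance(counts, dict):
        profs = [covariate_profile(tl) for tl in counts]
        counts = {}
        for cov in covariates:
            levels: dict[str, int] = {}
            for p in profs:
                val = getattr(p, cov)
                levels[val] = levels.get(val, 0) + 1
            counts[cov] = levels

    rows = []
    for cov, levels in counts.items():
        known = sum(n for lvl, n in levels.items() if lvl != UNKNOWN)
        for lvl, n in levels.items():
            pct = round_half_away(100.0 * n / known) if lvl != UNKNOWN and known else None
            rows.append((cov, lvl, n, pct))
    return pd.DataFrame(rows, columns=["covariate", "level", "count", "percent"])


# ---------------------------------------------------------------------------
# CSV schema: patients.csv (baseline) + events.csv (dated events)

_EVENT_TYPES = (
    "dli",
    "tis_start",
    "tis_stop",
    "relapse",
    "death",
    "viral",
    "chimerism",
    "alc",
    "graft_failure",
)


def write_cohort(cohort: list[PatientTimeline], patients_csv, events_csv) -> None:
    prows, erows = [], []
    for tl in cohort:
        prows.append(
            dict(
                patient_id=tl.patient_id,
                conditioning=tl.conditioning,
                donor=tl.donor,
                age_at_sct=tl.age_at_sct,
                death_cause_gvhd=tl.death_cause_gvhd,
                last_followup_day=tl.last_followup_day,
            )
        )
        pid = tl.patient_id
        for d in tl.dli_events:
            erows.append((pid, "dli", d.day, d.ordinal, d.planned_type))
        for s, t in tl.tis_episodes_raw:
            erows.append((pid, "tis_start", s, None, None))
            erows.append((pid, "tis_stop", t, None, None))
        if tl.relapse_day is not None:
            erows.append((pid, "relapse", tl.relapse_day, None, None))
        if tl.death_day is not None:
            erows.append((pid, "death", tl.death_day, None, None))
        if tl.graft_failure_day is not None:
            erows.append((pid, "graft_failure", tl.graft_failure_day, None, None))
        for day, label in tl.viral_infections:
            erows.append((pid, "viral", day, None, label))
        for day, val in tl.chimerism_obs:
            erows.append((pid, "chimerism", day, val, None))
        for day, val in tl.alc_obs:
            erows.append((pid, "alc", day, val, None))
    pd.DataFrame(prows).to_csv(patients_csv, index=False)
    pd.DataFrame(erows, columns=["patient_id", "event_type", "day", "value", "label"]).to_csv(
        events_csv, index=False
    )


def read_cohort(patients_csv, events_csv) -> list[PatientTimeline]:
    patients = pd.read_csv(patients_csv)
    events = pd.read_csv(events_csv)
    bad = set(events["event_type"]) - set(_EVENT_TYPES)
    if bad:
        raise TimelineError(f"unknown event types in events.csv: {sorted(bad)}")
    out = []
    grouped = dict(tuple(events.groupby("patient_id")))
    for _, p in patients.iterrows():
        pid = p["patient_id"]
        ev = grouped.get(pid, pd.DataFrame(columns=events.columns))
        tl = PatientTimeline(
            patient_id=str(pid),
            conditioning=_opt(p.get("conditioning")),
            donor=_opt(p.get("donor")),
            age_at_sct=_optf(p.get("age_at_sct")),
            death_cause_gvhd=_optbool(p.get("death_cause_gvhd")),
            last_followup_day=_optf(p.get("last_followup_day")),
        )
        starts, stops = [], []
        for _, e in ev.sort_values("day").iterrows():
            et, day = e["event_type"], float(e["day"])
            if et == "dli":
                tl.dli_events.append(
                    DliEvent(day, int(float(e["value"])), str(e["label"]))
                )
            elif et == "tis_start":
                starts.append(day)
            elif et == "tis_stop":
                stops.append(day)
            elif et == "relapse":
                tl.relapse_day = day
            elif et == "death":
                tl.death_day = day
            elif et == "graft_failure":
                tl.graft_failure_day = day
            elif et == "viral":
                tl.viral_infections.append((day, str(e["label"])))
            elif et == "chimerism":
                val = e["value"]
                tl.chimerism_obs.append(
                    (day, val if val == "detected" else float(val))
                )
            elif et == "alc":
                tl.alc_obs.append((day, float(e["value"])))
        if len(starts) != len(stops):
            raise TimelineError(f"{pid}: unmatched tis_start/tis_stop events")
        tl.tis_episodes_raw = list(zip(sorted(starts), sorted(stops)))
        tl.validate()
        out.append(tl)
    return out


def _opt(v):
    return None if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v) else str(v)


def _optf(v):
    return None if v is None or pd.isna(v) else float(v)


def _optbool(v):
    if v is None or pd.isna(v):
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)
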