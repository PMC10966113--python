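"""Nonparametric estimation for the multi-state model.

Implements the Nelson–Aalen estimator of cumulative transition hazards, the
Aalen–Johansen product-integral estimator of state-occupation probabilities
P(s, t), cause-specific cumulative incidence under competing risks, the
reversed Kaplan–Meier quantification of follow-up, composite endpoint
curves (cGRFS, alive-with-GvHD, death-after-tIS, RFS, OS) as sums of state
probabilities, and patient-level bootstrap confidence bands.

The product integral is computed on the merged set of observed transition
times only; all curves are right-continuous step functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import StateGraph

__all__ = [
    "HazardEstimate",
    "ProbabilityMatrix",
    "MultiStateModel",
    "MultiStateResults",
    "nelson_aalen",
    "aalen_johansen",
    "cumulative_incidence",
    "reversed_km",
    "composite_curves",
    "band_ci",
]

COMPOSITE_ORDER = ("cgrfs", "alive_gvhd", "death_after_tis", "rfs", "os")


@dataclass
class HazardEstimate:
    """Cumulative-hazard increments dA_jk(t) = dN_jk(t)/Y_j(t) per transition."""

    graph: StateGraph
    times: np.ndarray  # sorted unique transition times
    dN: np.ndarray  # (n_transitions, n_times) event counts
    Y: np.ndarray  # (n_states, n_times) at-risk counts in the source state

    @property
    def dA(self) -> np.ndarray:
        src = np.array([self.graph.index(a) for a, _ in self.graph.transitions])
        Ysrc = self.Y[src, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(Ysrc > 0, self.dN / np.where(Ysrc > 0, Ysrc, 1), 0.0)
        return d

    def cumulative(self, transition: tuple[str, str]) -> pd.DataFrame:
        i = self.graph.transition_number(*transition) - 1
        return pd.DataFrame(
            {"time": self.times, "cumhaz": np.cumsum(self.dA[i])}
        )


def _risk_sets(table: pd.DataFrame, graph: StateGraph, times: np.ndarray) -> np.ndarray:
    """Y_j(t): number of subjects at risk in state j at each time (left limit)."""
    Y = np.zeros((graph.n_states, len(times)))
    intervals = table.drop_duplicates(subset=["id", "from", "Tstart", "Tstop"])
    for state, grp in intervals.groupby("from", sort=False):
        j = graph.index(state)
        starts = np.sort(grp["Tstart"].to_numpy(float))
        stops = np.sort(grp["Tstop"].to_numpy(float))
        # at risk at t: Tstart < t <= Tstop
        Y[j] = np.searchsorted(starts, times, side="left") - np.searchsorted(
            stops, times, side="left"
        )
    return Y


def nelson_aalen(table: pd.DataFrame, graph: StateGraph) -> HazardEstimate:
    """Nelson–Aalen increments for every transition of the graph."""
    ev = table[table["status"] == 1]
    times = np.unique(ev["Tstop"].to_numpy(float))
    dN = np.zeros((len(graph.transitions), len(times)))
    tpos = {t: i for i, t in enumerate(times)}
    for (trans, t), n in ev.groupby(["trans", "Tstop"]).size().items():
        dN[int(trans) - 1, tpos[float(t)]] = n
    Y = _risk_sets(table, graph, times)
    src = np.array([graph.index(a) for a, _ in graph.transitions], dtype=int)
    bad = (dN > 0) & (Y[src, :] <= 0)
    if bad.any():
        raise ValueError("event observed with empty risk set — inconsistent table")
    return HazardEstimate(graph, times, dN, Y)


@dataclass
class ProbabilityMatrix:
    """Aalen–Johansen state-occupation probabilities P(s, t).

    ``P[i]`` is the full transition-probability matrix from time ``s`` to
    ``times[i]`` (rows: state at s; columns: state at t); ``times[0] == s``
    with ``P[0]`` the identity.  Curves are right-continuous step functions.
    """

    graph: StateGraph
    s: float
    times: np.ndarray  # (T,), times[0] == s
    P: np.ndarray  # (T, n_states, n_states)

    def at(self, t: float) -> np.ndarray:
        i = np.searchsorted(self.times, t, side="right") - 1
        return self.P[max(i, 0)]

    def occupation(self, start: str | dict[str, float] | None = None) -> pd.DataFrame:
        """State-occupation probabilities over time from a start state.

        ``start`` may be a state label, a mixture ``{state: weight}``, or
        None for the graph's single start state.
        """
        w = self._weights(start)
        vals = np.einsum("j,tjk->tk", w, self.P)
        return pd.DataFrame(vals, index=pd.Index(self.times, name="time"),
                            columns=list(self.graph.states))

    def _weights(self, start) -> np.ndarray:
        w = np.zeros(self.graph.n_states)
        if start is None:
            if len(self.graph.start_states) != 1:
                raise ValueError("start state required for multi-start graphs")
            start = self.graph.start_states[0]
        if isinstance(start, str):
            w[self.graph.index(start)] = 1.0
        else:
            for state, weight in start.items():
                w[self.graph.index(state)] = weight
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("start-state mixture weights must sum to 1")
        return w


def aalen_johansen(
    hz: HazardEstimate, s: float = 0.0, t_max: float | None = None
) -> ProbabilityMatrix:
    """Product-integral P(s,t) = prod_{s < u <= t} (I + dA(u))."""
    g = hz.graph
    n = g.n_states
    dA = hz.dA
    src = [g.index(a) for a, _ in g.transitions]
    dst = [g.index(b) for _, b in g.transitions]
    mask = hz.times > s
    if t_max is not None:
        mask &= hz.times <= t_max
    use = np.nonzero(mask)[0]
    times = np.concatenate([[s], hz.times[use]])
    P = np.empty((len(times), n, n))
    P[0] = np.eye(n)
    cur = np.eye(n)
    for out_i, ti in enumerate(use, start=1):
        M = np.eye(n)
        col = dA[:, ti]
        for k in range(len(src)):
            if col[k]:
                M[src[k], dst[k]] += col[k]
                M[src[k], src[k]] -= col[k]
        cur = cur @ M
        P[out_i] = cur
    return ProbabilityMatrix(g, s, times, P)


def composite_curves(
    pm: ProbabilityMatrix,
    start: str | dict[str, float] | None = None,
    endpoints: tuple[str, ...] = COMPOSITE_ORDER,
) -> pd.DataFrame:
    """Composite endpoints as sums of state-occupation probabilities.

    Returns a tidy frame (endpoint, time, estimate).  cGRFS sums the
    alive-without-relapse-and-off-tIS states, RFS adds the alive-with-GvHD
    states, OS all non-death states.
    """
    occ = pm.occupation(start)
    rows = []
    for ep in endpoints:
        states = sorted(pm.graph.group(ep))
        est = occ[states].sum(axis=1)
        for t, v in est.items():
            rows.append((ep, t, v))
    return pd.DataFrame(rows, columns=["endpoint", "time", "estimate"])


# ---------------------------------------------------------------------------
# Kaplan–Meier helpers, competing risks, reversed KM


def _km(times: np.ndarray, events: np.ndarray):
    """Kaplan–Meier survival curve; returns (event grid, S at grid)."""
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    grid = np.unique(times[events.astype(bool)])
    n = len(times)
    S, out = 1.0, []
    for t in grid:
        y = n - np.searchsorted(times, t, side="left")
        d = np.sum((times == t) & (events.astype(bool)))
        S *= 1.0 - d / y
        out.append(S)
    return grid, np.asarray(out)


@dataclass
class CumulativeIncidence:
    """Cause-specific cumulative incidence curves under competing risks."""

    times: np.ndarray
    cif: dict[str, np.ndarray]  # cause -> CIF evaluated at `times`
    survival: np.ndarray  # all-cause Kaplan–Meier at `times`

    def at(self, cause: str, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.cif[cause][i]) if i >= 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cause, vals in self.cif.items():
            for t, v in zip(self.times, vals):
                rows.append((cause, t, v))
        return pd.DataFrame(rows, columns=["cause", "time", "estimate"])


def cumulative_incidence(
    durations, causes, censored_label: object = 0
) -> CumulativeIncidence:
    """Aalen–Johansen cumulative incidence: CIF_c(t) = sum S(u-) dN_c(u)/Y(u).

    ``causes`` holds a cause label per subject, with ``censored_label`` for
    censored observations.
    """
    durations = np.asarray(durations, float)
    causes = np.asarray(causes, object)
    is_event = causes != censored_label
    labels = sorted({c for c in causes[is_event]}, key=str)
    grid = np.unique(durations[is_event])
    sorted_dur = np.sort(durations)
    n = len(durations)
    S = 1.0
    cif = {c: np.zeros(len(grid)) for c in labels}
    surv = np.ones(len(grid))
    acc = {c: 0.0 for c in labels}
    for i, t in enumerate(grid):
        y = n - np.searchsorted(sorted_dur, t, side="left")
        d_tot = 0
        for c in labels:
            d_c = np.sum((durations == t) & (causes == c))
            acc[c] += S * d_c / y  # S is the left limit S(t-)
            cif[c][i] = acc[c]
            d_tot += d_c
        S *= 1.0 - d_tot / y
        surv[i] = S
    return CumulativeIncidence(grid, cif, surv)


def sojourns_from_state(
    table: pd.DataFrame, from_state: str, clock: str = "forward"
) -> tuple[np.ndarray, np.ndarray]:
    """Exit times and causes for the first sojourn in ``from_state``.

    ``clock='reset'`` measures durations from entry into the state (used for
    death during tIS from start of tIS); ``'forward'`` keeps the DLI1 clock.
    Returns (durations, causes) with cause 0 for censored sojourns.
    """
    sub = table[table["from"] == from_state]
    durations, causes = [], []
    for _, grp in sub.groupby("id", sort=False):
        entry = grp["Tstart"].min()
        g = grp.sort_values("Tstart")
        # walk contiguous intervals of the first sojourn only
        cur = entry
        cause, exit_t = 0, None
        for t0 in np.sort(g["Tstart"].unique()):
            if t0 != cur:
                break
            block = g[g["Tstart"] == t0]
            exit_t = block["Tstop"].iloc[0]
            hit = block[block["status"] == 1]
            if len(hit):
                cause = hit["to"].iloc[0]
                break
            cur = exit_t
        durations.append(exit_t - (entry if clock == "reset" else 0.0))
        causes.append(cause)
    return np.asarray(durations, float), np.asarray(causes, object)


@dataclass
class FollowUpSummary:
    median: float | None
    q25: float | None
    q75: float | None
    curve: pd.DataFrame  # time, survival (probability of remaining in follow-up)

    @property
    def reached(self) -> bool:
        return self.median is not None


def reversed_km(last_contact, died) -> FollowUpSummary:
    """Median follow-up by the reversed Kaplan–Meier method.

    Censoring is treated as the event and death as censored, so the curve
    estimates the follow-up distribution; quantiles are read off the curve
    (None when the curve never drops below the threshold).
    """
    t = np.asarray(last_contact, float)
    died = np.asarray(died, bool)
    grid, S = _km(t, (~died).astype(int))

    def q(level):
        hit = np.nonzero(S <= level)[0]
        return float(grid[hit[0]]) if len(hit) else None

    curve = pd.DataFrame({"time": grid, "survival": S})
    return FollowUpSummary(q(0.5), q(0.75), q(0.25), curve)


# ---------------------------------------------------------------------------
# Bootstrap bands


def _step_eval(times: np.ndarray, values: np.ndarray, grid: np.ndarray, v0: float):
    idx = np.searchsorted(times, grid, side="right") - 1
    return np.where(idx >= 0, values[np.maximum(idx, 0)], v0)


def band_ci(
    table: pd.DataFrame,
    graph: StateGraph,
    seed: int,
    B: int = 500,
    level: float = 0.95,
    s: float = 0.0,
    start=None,
    endpoints: tuple[str, ...] = COMPOSITE_ORDER,
) -> pd.DataFrame:
    """Pointwise percentile bootstrap bands for composite curves.

    Patients (ids) are resampled with replacement and the full pipeline
    (Nelson–Aalen, Aalen–Johansen, composites) is recomputed per resample;
    deterministic given ``seed``.
    """
    if B < 40 and level >= 0.95:
        warnings.warn(f"B={B} is small for a {level:.0%} percentile interval")
    rng = np.random.default_rng(seed)
    est = composite_curves(aalen_johansen(nelson_aalen(table, graph), s=s), start, endpoints)
    ids = table["id"].unique()
    groups = {i: g for i, g in table.groupby("id", sort=False)}
    grids = {ep: g["time"].to_numpy() for ep, g in est.groupby("endpoint")}
    draws = {ep: np.empty((B, len(g))) for ep, g in grids.items()}
    for b in range(B):
        sample = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for k, pid in enumerate(sample):
            g = groups[pid].copy()
            g["id"] = f"b{k}"
            parts.append(g)
        bt = pd.concat(parts, ignore_index=True)
        bc = composite_curves(aalen_johansen(nelson_aalen(bt, graph), s=s), start, endpoints)
        for ep, g in bc.groupby("endpoint"):
            draws[ep][b] = _step_eval(
                g["time"].to_numpy(), g["estimate"].to_numpy(), grids[ep],
                g["estimate"].iloc[0],
            )
    alpha = 1.0 - level
    lo, hi = [], []
    for _, row in est.iterrows():
        ep = row["endpoint"]
        j = np.searchsorted(grids[ep], row["time"])
        lo.append(np.quantile(draws[ep][:, j], alpha / 2))
        hi.append(np.quantile(draws[ep][:, j], 1 - alpha / 2))
    out = est.copy()
    out["lower"], out["upper"] = lo, hi
    return out


# ---------------------------------------------------------------------------
# Model / Results surface


class MultiStateModel:
    """Nonparametric Markov multi-state model on the clock-forward scale.

    Parameters
    ----------
    table : DataFrame
        Long-format transition data from :func:`dlimstate.graph.prepare_transitions`.
    graph : StateGraph
        The state structure the table was built against.
    """

    def __init__(self, table: pd.DataFrame, graph: StateGraph):
        self.table = table
        self.graph = graph

    @classmethod
    def from_timelines(cls, cohort, graph, covariates=(), episodes="consolidated"):
        from .graph import prepare_transitions

        return cls(prepare_transitions(cohort, graph, covariates, episodes), graph)

    def fit(self, s: float = 0.0) -> "MultiStateResults":
        hz = nelson_aalen(self.table, self.graph)
        return MultiStateResults(self, hz, aalen_johansen(hz, s=s))


@dataclass
class MultiStateResults:
    model: MultiStateModel
    hazards: HazardEstimate
    probabilities: ProbabilityMatrix

    def occupation(self, start=None) -> pd.DataFrame:
        return self.probabilities.occupation(start)

    def composites(self, start=None) -> pd.DataFrame:
        return composite_curves(self.probabilities, start)

    def bootstrap_bands(self, seed: int, B: int = 500, start=None) -> pd.DataFrame:
        return band_ci(
            self.model.table, self.model.graph, seed=seed, B=B,
            s=self.probabilities.s, start=start,
        )

    def summary(self, horizons=(365.25, 1826.25), start=None) -> str:
        comp = self.composites(start)
        lines = [
            "Nonparametric multi-state model (Aalen–Johansen)",
            f"  states: {self.model.graph.n_states}, "
            f"transitions: {len(self.model.graph.transitions)}, "
            f"patients: {self.model.table['id'].nunique()}",
            f"  {'endpoint':<16}" + "".join(f"{h / 30.4375:>10.0f} mo" for h in horizons),
        ]
        for ep, g in comp.groupby("endpoint", sort=False):
            vals = _step_eval(
                g["time"].to_numpy(), g["estimate"].to_numpy(),
                np.asarray(horizons, float), g["estimate"].iloc[0],
            )
            lines.append(f"  {ep:<16}" + "".join(f"{v:>11.3f} " for v in vals))
        return "\n".join(lines)
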