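"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dlimstate import (
    SimulationParams,
    StateGraph,
    build_state_graph,
    prepare_transitions,
    simulate_cohort,
)

COVARIATES = ("conditioning_donor", "chimerism_cat", "viral")


@pytest.fixture(scope="session")
def full_graph():
    return build_state_graph("full")


@pytest.fixture(scope="session")
def sim300():
    """A moderate synthetic cohort under the default study conditions."""
    return simulate_cohort(SimulationParams(n=300, seed=20240313))


@pytest.fixture(scope="session")
def table300(sim300, full_graph):
    return prepare_transitions(sim300.cohort, full_graph, COVARIATES)


# ---------------------------------------------------------------------------
# oracle helpers (independent of the estimation code paths they check)


def toy_graph(states, transitions, groups=None):
    return StateGraph(
        "toy", tuple(states), tuple(tuple(t) for t in transitions),
        (states[0],), {k: frozenset(v) for k, v in (groups or {}).items()},
    )


def table_from_sojourns(graph, sojourns_by_patient):
    """Build a long-format table from explicit per-patient sojourn records.

    Each sojourn is (state, t_in, t_out, next_state_or_None); mirrors the
    layout contract of prepare_transitions but is written independently.
    """
    rows = []
    for pid, sojourns in sojourns_by_patient.items():
        for state, t_in, t_out, nxt in sojourns:
            for k in graph.successors(state):
                rows.append(
                    {
                        "id": pid,
                        "from": state,
                        "to": k,
                        "trans": graph.transition_number(state, k),
                        "Tstart": float(t_in),
                        "Tstop": float(t_out),
                        "status": int(nxt == k),
                    }
                )
    return pd.DataFrame(rows)


def random_uncensored_instance(rng):
    """A random small multi-state dataset on an integer time grid.

    All patients start in state 0 and are followed to a common horizon, so
    occupation fractions are directly countable from the trajectories.
    Returns (graph, table, trajectories) with trajectories a dict
    id -> list of sojourns.
    """
    n_states = int(rng.integers(2, 6))
    states = tuple(f"s{i}" for i in range(n_states))
    trans = [
        (i, j)
        for i in range(n_states)
        for j in range(n_states)
        if i < j and rng.random() < 0.6
    ]
    if not any(a == 0 for a, _ in trans):
        trans.append((0, n_states - 1))
    graph = toy_graph(states, [(states[a], states[b]) for a, b in trans])
    horizon = 12
    trajectories = {}
    for p in range(int(rng.integers(2, 21))):
        state, t, soj = 0, 0, []
        while True:
            succ = [b for a, b in trans if a == state]
            if not succ or t >= horizon or rng.random() < 0.2:
                soj.append((states[state], t, horizon, None))
                break
            t2 = min(t + int(rng.integers(1, 5)), horizon)
            if t2 == horizon:
                soj.append((states[state], t, horizon, None))
                break
            nxt = succ[int(rng.integers(len(succ)))]
            soj.append((states[state], t, t2, states[nxt]))
            state, t = nxt, t2
        trajectories[f"p{p}"] = soj
    return graph, table_from_sojourns(graph, trajectories), trajectories


def count_occupation(trajectories, states, times):
    """Brute-force state-occupation fractions by trajectory counting."""
    n = len(trajectories)
    out = np.zeros((len(times), len(states)))
    idx = {s: i for i, s in enumerate(states)}
    for soj in trajectories.values():
        for k, t in enumerate(times):
            for state, t_in, t_out, nxt in soj:
                last = nxt is None
                if t_in <= t and (t < t_out or last):
                    out[k, idx[state]] += 1.0
                    break
    return out / n
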