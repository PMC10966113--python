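"""Nelson–Aalen / Aalen–Johansen estimation, CIFs, reversed KM, composites."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from dlimstate import (
    DliEvent,
    MultiStateModel,
    PatientTimeline,
    ProbabilityMatrix,
    aalen_johansen,
    band_ci,
    build_state_graph,
    composite_curves,
    cumulative_incidence,
    nelson_aalen,
    prepare_transitions,
    reversed_km,
)

from conftest import (
    count_occupation,
    random_uncensored_instance,
    table_from_sojourns,
    toy_graph,
)


class TestNelsonAalen:
    def test_single_event_increment(self):
        g = toy_graph(["a", "b"], [("a", "b")])
        t = table_from_sojourns(
            g, {"p1": [("a", 0, 1, "b")], "p2": [("a", 0, 5, None)]}
        )
        hz = nelson_aalen(t, g)
        assert hz.times.tolist() == [1.0]
        assert hz.dA[0, 0] == 0.5  # 1 event / 2 at risk

    def test_no_events_zero_hazard(self):
        g = toy_graph(["a", "b"], [("a", "b")])
        t = table_from_sojourns(g, {"p1": [("a", 0, 5, None)]})
        hz = nelson_aalen(t, g)
        assert hz.times.size == 0

    def test_competing_increments_follow_risk_sets(self):
        g = toy_graph(["s", "x", "y", "z"], [("s", "x"), ("s", "y"), ("s", "z")])
        t = table_from_sojourns(
            g,
            {
                "p1": [("s", 0, 1, "x")],
                "p2": [("s", 0, 2, "y")],
                "p3": [("s", 0, 3, "z")],
                "p4": [("s", 0, 3, None)],
            },
        )
        dA = nelson_aalen(t, g).dA
        assert dA[0, 0] == pytest.approx(1 / 4)
        assert dA[1, 1] == pytest.approx(1 / 3)
        assert dA[2, 2] == pytest.approx(1 / 2)


class TestAalenJohansen:
    def test_two_state_equals_one_minus_km(self):
        rng = np.random.default_rng(5)
        g = toy_graph(["alive", "dead"], [("alive", "dead")])
        times = np.ceil(rng.exponential(50, 80))
        cens = np.ceil(rng.uniform(10, 120, 80))
        soj = {
            f"p{i}": [("alive", 0, min(t, c), "dead" if t <= c else None)]
            for i, (t, c) in enumerate(zip(times, cens))
        }
        table = table_from_sojourns(g, soj)
        pm = aalen_johansen(nelson_aalen(table, g))
        km = KaplanMeierFitter().fit(np.minimum(times, cens), times <= cens)
        for t in pm.times[1:]:
            assert pm.occupation("alive").loc[t, "dead"] == pytest.approx(
                1 - km.predict(t), abs=1e-12
            )

    def test_hand_product_integral(self):
        # dA_12(1) = 1/2, dA_13(2) = 1 -> row from state 1 is (0, 1/2, 1/2)
        g = toy_graph(["s1", "s2", "s3"], [("s1", "s2"), ("s1", "s3")])
        t = table_from_sojourns(
            g, {"a": [("s1", 0, 1, "s2")], "b": [("s1", 0, 2, "s3")]}
        )
        pm = aalen_johansen(nelson_aalen(t, g))
        np.testing.assert_allclose(pm.at(2)[0], [0.0, 0.5, 0.5])

    def test_no_events_identity(self):
        g = toy_graph(["a", "b"], [("a", "b")])
        t = table_from_sojourns(g, {"p": [("a", 0, 9, None)]})
        pm = aalen_johansen(nelson_aalen(t, g))
        np.testing.assert_array_equal(pm.at(9), np.eye(2))

    def test_prediction_origin_beyond_last_event(self):
        g = toy_graph(["a", "b"], [("a", "b")])
        t = table_from_sojourns(g, {"p": [("a", 0, 3, "b")]})
        pm = aalen_johansen(nelson_aalen(t, g), s=10)
        assert pm.times.tolist() == [10]
        np.testing.assert_array_equal(pm.P[0], np.eye(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_trajectory_counting_when_uncensored(self, seed):
        rng = np.random.default_rng(seed)
        g, table, traj = random_uncensored_instance(rng)
        pm = aalen_johansen(nelson_aalen(table, g))
        occ = pm.occupation(g.states[0])
        brute = count_occupation(traj, g.states, pm.times)
        np.testing.assert_allclose(occ.to_numpy(), brute, atol=1e-12)

    def test_row_stochastic_and_absorbing_monotone(self, table300, full_graph):
        pm = MultiStateModel(table300, full_graph).fit().probabilities
        sums = pm.P.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        assert pm.P.min() >= -1e-12 and pm.P.max() <= 1 + 1e-12
        i0 = full_graph.index("dli1")
        for s in full_graph.absorbing:
            col = pm.P[:, i0, full_graph.index(s)]
            assert np.all(np.diff(col) >= -1e-12)


class TestCumulativeIncidence:
    def test_two_causes_half_each(self):
        cif = cumulative_incidence([1.0, 2.0], ["A", "B"])
        assert cif.at("A", 10) == pytest.approx(0.5)
        assert cif.at("B", 10) == pytest.approx(0.5)

    def test_single_cause_equals_one_minus_km(self):
        rng = np.random.default_rng(11)
        t = np.ceil(rng.exponential(30, 60))
        c = np.ceil(rng.uniform(5, 60, 60))
        obs = np.minimum(t, c)
        cause = np.where(t <= c, "death", "0").astype(object)
        cause[cause == "0"] = 0
        cif = cumulative_incidence(obs, cause)
        km = KaplanMeierFitter().fit(obs, t <= c)
        for u in cif.times:
            assert cif.at("death", u) == pytest.approx(1 - km.predict(u), abs=1e-12)

    def test_all_censored_zero(self):
        cif = cumulative_incidence([3.0, 4.0], [0, 0])
        assert cif.times.size == 0

    def test_cause_sum_equals_one_minus_all_cause_km(self):
        rng = np.random.default_rng(3)
        n = 150
        t = np.ceil(rng.exponential(25, n))
        cause = rng.choice(["tis", "relapse", "death"], n)
        c = np.ceil(rng.uniform(5, 70, n))
        obs = np.minimum(t, c)
        causes = np.where(t <= c, cause, "0").astype(object)
        causes[causes == "0"] = 0
        cif = cumulative_incidence(obs, causes)
        total = sum(cif.cif[k] for k in cif.cif)
        np.testing.assert_allclose(total, 1 - cif.survival, atol=1e-12)
        for k in cif.cif:  # CIFs are non-decreasing
            assert np.all(np.diff(cif.cif[k]) >= -1e-12)


class TestReversedKM:
    def test_death_censored_censoring_event(self):
        fup = reversed_km([5.0, 10.0], [True, False])
        assert fup.median == 10.0

    def test_all_censored_at_common_time(self):
        fup = reversed_km([30.0, 30.0, 30.0], [False] * 3)
        assert fup.median == 30.0 and fup.q25 == 30.0

    def test_no_censoring_median_not_reached(self):
        fup = reversed_km([5.0, 8.0], [True, True])
        assert fup.median is None and not fup.reached

    def test_agrees_with_inverted_lifelines_km(self):
        rng = np.random.default_rng(8)
        t = np.ceil(rng.uniform(1, 100, 200))
        died = rng.random(200) < 0.4
        fup = reversed_km(t, died)
        km = KaplanMeierFitter().fit(t, ~died)
        assert fup.median == pytest.approx(km.median_survival_time_)


class TestComposites:
    def _pm_from_row(self, graph, row_probs):
        n = graph.n_states
        P = np.stack([np.eye(n), np.tile(row_probs, (n, 1))])
        return ProbabilityMatrix(graph, 0.0, np.array([0.0, 5.0]), P)

    def test_all_mass_in_start_state(self, full_graph):
        pm = aalen_johansen(
            nelson_aalen(
                prepare_transitions(
                    [PatientTimeline("p", dli_events=[DliEvent(0, 1, "three_month")],
                                     last_followup_day=100)],
                    full_graph,
                ),
                full_graph,
            )
        )
        comp = composite_curves(pm, "dli1").set_index(["endpoint", "time"])
        for ep in ("cgrfs", "rfs", "os"):
            assert comp.loc[(ep, 0.0), "estimate"] == 1.0
        assert comp.loc[("alive_gvhd", 0.0), "estimate"] == 0.0

    def test_caption_arithmetic(self, full_graph):
        row = np.zeros(14)
        for state, p in [("dli1", 0.4), ("tis1", 0.2), ("stop_tis1", 0.1),
                         ("relapse1", 0.1), ("death_tis1", 0.1), ("death1", 0.1)]:
            row[full_graph.index(state)] = p
        pm = self._pm_from_row(full_graph, row)
        comp = composite_curves(pm, "dli1").set_index(["endpoint", "time"])
        assert comp.loc[("cgrfs", 5.0), "estimate"] == pytest.approx(0.5)
        assert comp.loc[("alive_gvhd", 5.0), "estimate"] == pytest.approx(0.2)
        assert comp.loc[("death_after_tis", 5.0), "estimate"] == pytest.approx(0.1)
        assert comp.loc[("rfs", 5.0), "estimate"] == pytest.approx(0.7)
        assert comp.loc[("os", 5.0), "estimate"] == pytest.approx(0.8)

    def test_all_dead_os_zero(self, full_graph):
        row = np.zeros(14)
        row[full_graph.index("death1")] = 1.0
        comp = composite_curves(self._pm_from_row(full_graph, row), "dli1")
        os_ = comp[(comp["endpoint"] == "os") & (comp["time"] == 5.0)]
        assert os_["estimate"].iloc[0] == 0.0

    def test_nesting_on_simulated_cohort(self, table300, full_graph):
        comp = MultiStateModel(table300, full_graph).fit().composites("dli1")
        wide = comp.pivot(index="time", columns="endpoint", values="estimate")
        assert (wide["cgrfs"] <= wide["rfs"] + 1e-12).all()
        assert (wide["rfs"] <= wide["os"] + 1e-12).all()

    def test_cgrfs_decreases_then_increases(self, full_graph):
        # one of five patients needs tIS and recovers: cGRFS dips, then rises
        cohort = [
            PatientTimeline("gvhd", dli_events=[DliEvent(10, 1, "three_month")],
                            tis_episodes_raw=[(30, 90)], last_followup_day=210)
        ] + [
            PatientTimeline(f"ok{i}", dli_events=[DliEvent(10, 1, "three_month")],
                            last_followup_day=210)
            for i in range(4)
        ]
        res = MultiStateModel.from_timelines(cohort, full_graph).fit()
        comp = res.composites("dli1")
        cg = comp[comp["endpoint"] == "cgrfs"].set_index("time")["estimate"]
        assert cg.loc[20.0] == pytest.approx(0.8)  # on tIS
        assert cg.loc[80.0] == pytest.approx(1.0)  # recovered
        assert cg.min() < cg.iloc[0] and cg.iloc[-1] > cg.min()


class TestBootstrapBands:
    def _two_state(self, n, seed):
        rng = np.random.default_rng(seed)
        g = toy_graph(["alive", "dead"], [("alive", "dead")],
                      groups={"os": ["alive"]})
        t = np.ceil(rng.exponential(40, n))
        c = np.ceil(rng.uniform(10, 100, n))
        soj = {
            f"p{i}": [("alive", 0, min(a, b), "dead" if a <= b else None)]
            for i, (a, b) in enumerate(zip(t, c))
        }
        return g, table_from_sojourns(g, soj), np.minimum(t, c), t <= c

    def test_deterministic_given_seed(self):
        g, table, _, _ = self._two_state(40, 2)
        b1 = band_ci(table, g, seed=99, B=50, endpoints=("os",))
        b2 = band_ci(table, g, seed=99, B=50, endpoints=("os",))
        pd.testing.assert_frame_equal(b1, b2)

    def test_small_B_warns(self):
        g, table, _, _ = self._two_state(20, 3)
        with pytest.warns(UserWarning, match="small"):
            band_ci(table, g, seed=1, B=10, endpoints=("os",))

    def test_degenerate_no_events_collapses(self):
        g = toy_graph(["a", "b"], [("a", "b")], groups={"os": ["a"]})
        table = table_from_sojourns(g, {"p1": [("a", 0, 5, None)],
                                        "p2": [("a", 0, 5, None)]})
        bands = band_ci(table, g, seed=1, B=50, endpoints=("os",))
        assert (bands["lower"] == 1.0).all() and (bands["upper"] == 1.0).all()

    def test_close_to_greenwood_at_n_500(self):
        g, table, obs, event = self._two_state(500, 7)
        bands = band_ci(table, g, seed=5, B=200, endpoints=("os",))
        km = KaplanMeierFitter().fit(obs, event)
        ci = km.confidence_interval_survival_function_
        for t in (20.0, 40.0, 60.0):
            row = bands[(bands["endpoint"] == "os") & (bands["time"] <= t)].iloc[-1]
            i = ci.index.searchsorted(t, side="right") - 1
            lo, hi = ci.iloc[i, 0], ci.iloc[i, 1]
            assert abs(row["lower"] - lo) < 0.03
            assert abs(row["upper"] - hi) < 0.03
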