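"""Qualitative propagation: semantics, properties and the path-sum oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carecld import (
    Scenario,
    UnknownElementError,
    load_scenarios,
    path_sum_oracle,
    path_sum_totals,
    propagate,
    run_scenario_suite,
)

from conftest import (
    brute_force_path_signs,
    make_model,
    random_signed_digraph,
    random_signed_tree,
)


class TestScenario:
    def test_rejects_bad_activation_sign(self):
        with pytest.raises(ValueError, match="activation sign"):
            Scenario("s", {"a": 2})

    def test_rejects_bad_expected_sign(self):
        with pytest.raises(ValueError, match="expected outcome"):
            Scenario("s", {"a": 1}, expected_outcomes={"b": 5})

    def test_yaml_round_trip(self, tmp_path):
        sc = Scenario("demo", {"a": 1, "b": -1},
                      expected_outcomes={"c": 0}, notes="hello")
        sc.to_yaml(tmp_path / "demo.yaml")
        again = Scenario.from_yaml(tmp_path / "demo.yaml")
        assert again == sc

    def test_load_scenarios_sorted_by_filename(self, tmp_path):
        Scenario("zed", {"a": 1}).to_yaml(tmp_path / "2_zed.yaml")
        Scenario("alpha", {"a": 1}).to_yaml(tmp_path / "1_alpha.yaml")
        assert [s.name for s in load_scenarios(tmp_path)] == ["alpha", "zed"]


class TestPropagate:
    def test_sign_composition_along_a_chain(self):
        model = make_model([("a", "b", 1), ("b", "c", -1)])
        result = propagate(model, Scenario("chain", {"a": 1}))
        assert result.first_response == {"a": 1, "b": 1, "c": -1}
        assert result.converged
        assert result.iterations <= 3
        assert result.status == {"a": "source", "b": "changed", "c": "changed"}

    def test_diamond_cancellation(self):
        model = make_model([("a", "b", 1), ("a", "c", -1),
                            ("b", "d", 1), ("c", "d", 1)])
        result = propagate(model, Scenario("diamond", {"a": 1}))
        assert result.first_response["d"] == 0
        assert result.status["d"] == "unchanged"

    def test_sources_clamped_in_both_summaries(self, fixture_model):
        result = propagate(fixture_model, Scenario("w", {"workload": 1}))
        assert result.first_response["workload"] == 1
        assert result.fixed_point["workload"] == 1
        assert result.status["workload"] == "source"

    def test_unknown_activation_element_raises(self, fixture_model):
        with pytest.raises(UnknownElementError, match="not_an_element"):
            propagate(fixture_model, Scenario("bad", {"not_an_element": 1}))

    def test_nonpositive_max_iter_rejected(self, stress_core):
        with pytest.raises(ValueError, match="max_iter"):
            propagate(stress_core, Scenario("s", {"control": 1}), max_iter=0)

    def test_oscillation_marked_ambiguous(self):
        # a feeds a balancing two-cycle: b and c never settle
        model = make_model([("a", "b", 1), ("b", "c", 1), ("c", "b", -1)])
        result = propagate(model, Scenario("osc", {"a": 1}))
        assert not result.converged
        assert result.status["b"] == "ambiguous"
        assert result.status["c"] == "ambiguous"
        assert result.fixed_point["b"] == 0
        assert result.fixed_point["c"] == 0
        # first response is frozen at the first nonzero state
        assert result.first_response["b"] == 1
        assert result.first_response["c"] == 1

    def test_trajectory_recording(self, stress_core):
        result = propagate(stress_core, Scenario("t", {"job_demand": 1}),
                           record_trajectory=True)
        assert result.trajectory is not None
        assert result.trajectory.shape[1] == stress_core.n_elements
        assert set(np.unique(result.trajectory)) <= {-1, 0, 1}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_antisymmetry(self, seed):
        """Negating every activation negates both summaries everywhere."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        model = random_signed_digraph(rng, n, p=0.3)
        k = int(rng.integers(1, n + 1))
        chosen = rng.choice(n, size=k, replace=False)
        acts = {f"x{i:02d}": int(rng.choice([-1, 1])) for i in chosen}
        plus = propagate(model, Scenario("p", acts))
        minus = propagate(model, Scenario("m", {e: -s for e, s in acts.items()}))
        for el in model.element_ids:
            assert plus.first_response[el] == -minus.first_response[el]
            assert plus.fixed_point[el] == -minus.fixed_point[el]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_reachability(self, seed):
        """Nonzero responses only occur downstream of a source, and
        unreached status marks exactly the non-reachable elements."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        model = random_signed_digraph(rng, n, p=0.2)
        src = f"x{int(rng.integers(n)):02d}"
        result = propagate(model, Scenario("r", {src: 1}))
        g = model.to_digraph()
        import networkx as nx
        reachable = {src} | nx.descendants(g, src)
        for el in model.element_ids:
            if result.first_response[el] != 0:
                assert el in reachable
            assert (result.status[el] == "unreached") == (el not in reachable)

    def test_pure_function_of_inputs(self, fixture_model, scenarios):
        first = run_scenario_suite(fixture_model, scenarios)
        second = run_scenario_suite(fixture_model, scenarios)
        assert len(first) == len(scenarios)
        for a, b in zip(first, second):
            assert a.first_response == b.first_response
            assert a.fixed_point == b.fixed_point
            assert a.status == b.status

    def test_empty_scenario_list(self, fixture_model):
        assert run_scenario_suite(fixture_model, []) == []


class TestFixtureScenarioResponses:
    """The published what-if outcomes, replayed on the built-in model."""

    def test_workload_activation(self, fixture_model):
        result = propagate(fixture_model, Scenario("w", {"workload": 1}))
        fr = result.first_response
        assert fr["quantitative_demands"] == 1
        assert fr["decision_demands"] == 1
        assert fr["work_pace"] == 1
        assert fr["role_conflict"] == 1
        assert fr["provision_of_care_and_services"] == -1
        assert fr["needs_met"] == -1
        assert fr["job_satisfaction"] == -1
        # opposing overload/underload channels cancel: unmodulated
        assert fr["distress"] == 0

    def test_person_centered_care_activation(self, fixture_model):
        result = propagate(fixture_model,
                           Scenario("p", {"person_centered_care": 1}))
        fr = result.first_response
        assert fr["trust_in_home_care_staff"] == 1
        assert fr["provision_of_care_and_services"] == 1
        assert fr["needs_met"] == 1
        assert fr["health_safety_risk"] == -1

    def test_distress_activation(self, fixture_model):
        result = propagate(fixture_model, Scenario("d", {"distress": 1}))
        fr = result.first_response
        assert fr["physio_mental_health_response"] == 1
        assert fr["burnout"] == 1
        assert fr["health_safety_risk"] == 1
        assert fr["job_involvement"] == -1
        assert fr["quality_of_care"] == -1


class TestPathSumOracle:
    def test_single_path(self):
        model = make_model([("a", "b", 1), ("b", "c", 1)])
        oracle = path_sum_oracle(model, Scenario("s", {"a": 1}))
        assert oracle == {"a": 1, "b": 1, "c": 1}

    def test_diamond_cancellation(self):
        model = make_model([("a", "b", 1), ("a", "c", -1),
                            ("b", "d", 1), ("c", "d", 1)])
        oracle = path_sum_oracle(model, Scenario("s", {"a": 1}))
        assert oracle["d"] == 0

    def test_cyclic_model_requires_length_cap(self):
        model = make_model([("a", "b", 1), ("b", "a", 1)])
        with pytest.raises(ValueError, match="max_path_length"):
            path_sum_oracle(model, Scenario("s", {"a": 1}))
        capped = path_sum_oracle(model, Scenario("s", {"a": 1}),
                                 max_path_length=5)
        assert capped["b"] == 1

    def test_paths_do_not_cross_other_sources(self):
        model = make_model([("a", "b", 1), ("b", "c", 1)])
        oracle = path_sum_oracle(model, Scenario("s", {"a": 1, "b": -1}))
        # c hears only the clamped b, not a through b
        assert oracle["c"] == -1

    def test_combinatorial_cap(self):
        edges = [(f"n{i}", f"n{j}", 1) for i in range(8) for j in range(8)
                 if i < j]
        model = make_model(edges)
        with pytest.raises(RuntimeError, match="cap"):
            path_sum_oracle(model, Scenario("s", {"n0": 1}), max_paths=10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_equals_first_response_on_unique_path_dags(self, seed):
        """On trees (unique paths, no aggregation) the oracle, an
        independent brute force, and the propagation first response all
        coincide."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        model = random_signed_tree(rng, n)
        scenario = Scenario("t", {"x00": int(rng.choice([-1, 1]))})
        oracle = path_sum_oracle(model, scenario)
        brute = brute_force_path_signs(model, scenario.activations)
        response = propagate(model, scenario).first_response
        assert oracle == brute == response

    def test_short_path_arrival_differs_from_total_path_sum(self):
        """Regression pinning the documented semantic difference: a
        short positive path registers a +1 first response before a longer
        negative path arrives and cancels it at the fixed point; the
        all-paths oracle already sums both to zero."""
        model = make_model([("a", "d", 1), ("a", "b", 1), ("b", "d", -1)])
        scenario = Scenario("cx", {"a": 1})
        result = propagate(model, scenario)
        assert result.first_response["d"] == 1
        assert result.fixed_point["d"] == 0
        assert path_sum_oracle(model, scenario)["d"] == 0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_path_addition(self, seed):
        """Adding a fresh all-positive chain from the source to a node
        raises that node's raw path sum by exactly the activation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        # DAG in fixed topological order so the added chain cannot close
        # a cycle back to the source
        dag_edges = [
            (f"x{i:02d}", f"x{j:02d}", -1 if rng.random() < 0.25 else 1)
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.3
        ]
        model = make_model(dag_edges, n_nodes=n)
        target = f"x{int(rng.integers(1, n)):02d}"
        source = "x00"
        scenario = Scenario("m", {source: 1})
        before = path_sum_totals(model, scenario)[target]
        edges = [(c.source, c.target, c.polarity) for c in model.connections]
        edges += [(source, "z01", 1), ("z01", "z02", 1), ("z02", target, 1)]
        bigger = make_model(edges, n_nodes=n)
        after = path_sum_totals(bigger, scenario)[target]
        assert after == before + 1
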