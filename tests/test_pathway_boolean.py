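"""KGML parsing, Boolean rule compilation, expression overlay, simulation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netrepurpose.pathway_boolean import (
    BooleanRule,
    KGMLParseError,
    assign_disease_nodes,
    boolecube_eval,
    build_pathway_model,
    compile_update_functions,
    derive_expression_calls,
    parse_kgml,
    relation_to_logic,
    rules_from_text,
    rules_to_text,
    simulate_ode,
    synchronous_fixed_point,
)
from netrepurpose.synthetic_fixtures import PathwaySpec, gen_kgml

KGML_TWO_NODE = """<?xml version="1.0"?>
<pathway name="path:test01" org="hsa" number="1" title="toy">
  <entry id="1" name="hsa:10" type="gene">
    <graphics name="GENEA" type="rectangle"/>
  </entry>
  <entry id="2" name="hsa:20" type="gene">
    <graphics name="GENEB" type="rectangle"/>
  </entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="{subtype}" value="{symbol}"/>
  </relation>
</pathway>
"""


class TestRelationToLogic:
    @pytest.mark.parametrize("name", ["activation", "expression",
                                      "indirect effect", "state change",
                                      "binding/association", "phosphorylation",
                                      "glycosylation", "ubiquitination",
                                      "methylation"])
    def test_activating_vocabulary(self, name):
        assert relation_to_logic(name) == "AND"

    @pytest.mark.parametrize("name", ["inhibition", "repression",
                                      "dissociation", "dephosphorylation"])
    def test_inhibiting_vocabulary(self, name):
        assert relation_to_logic(name) == "NOT"

    def test_case_insensitive(self):
        assert relation_to_logic("Inhibition") == "NOT"
        assert relation_to_logic("ACTIVATION") == "AND"

    def test_unknown_subtype_uses_default(self, caplog):
        assert relation_to_logic("mystery") == "AND"
        assert relation_to_logic("mystery", default="NOT") == "NOT"


class TestParseKGML:
    def test_two_entry_activation(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(KGML_TWO_NODE.format(subtype="activation", symbol="--&gt;"))
        graph = parse_kgml(p)
        assert graph.nodes == ["GENEA", "GENEB"]
        assert graph.edges == [("GENEA", "GENEB", "activation")]

    def test_inhibition_subtype_becomes_inhibitor_edge(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(KGML_TWO_NODE.format(subtype="inhibition", symbol="--|"))
        rules = compile_update_functions(parse_kgml(p))
        assert rules["GENEB"].inhibitors == ("GENEA",)
        assert rules["GENEB"].activators == ()

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<pathway><entry id=1 broken></pathway>")
        with pytest.raises(KGMLParseError):
            parse_kgml(p)

    def test_group_entry_expanded(self, tmp_path):
        p = tmp_path / "grp.xml"
        p.write_text("""<?xml version="1.0"?>
<pathway name="path:grp" org="hsa" number="2" title="grp">
  <entry id="1" name="hsa:1" type="gene"><graphics name="A"/></entry>
  <entry id="2" name="hsa:2" type="gene"><graphics name="B"/></entry>
  <entry id="3" name="hsa:3" type="gene"><graphics name="C"/></entry>
  <entry id="10" name="undefined" type="group">
    <component id="1"/><component id="2"/>
  </entry>
  <relation entry1="10" entry2="3" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>""")
        graph = parse_kgml(p)
        assert set(graph.edges) == {("A", "C", "activation"),
                                    ("B", "C", "activation")}

    def test_generated_kgml_round_trips_to_ground_truth(self, tmp_path):
        for seed in range(3):
            path, truth = gen_kgml(PathwaySpec(n_nodes=8, n_edges=12), seed,
                                   tmp_path / f"rt{seed}.xml")
            compiled = compile_update_functions(parse_kgml(path))
            assert compiled == truth

    def test_all_inhibition_fixture_is_pure_negation(self, tmp_path):
        path, truth = gen_kgml(
            PathwaySpec(n_nodes=6, n_edges=8, inhibition_fraction=1.0),
            seed=4, out_path=tmp_path / "inh.xml")
        for rule in truth.values():
            assert rule.activators == ()


class TestCompileUpdateFunctions:
    def _graph(self, edges, nodes=None):
        from netrepurpose.pathway_boolean import PathwayGraph
        nodes = nodes or sorted({n for e in edges for n in e[:2]})
        return PathwayGraph("p", nodes, edges)

    def test_activator_and_inhibitor_composition(self):
        g = self._graph([("A", "B", "activation"), ("C", "B", "inhibition")])
        rule = compile_update_functions(g)["B"]
        assert rule.evaluate({"A": 1, "C": 0, "B": 0}) is True
        assert rule.evaluate({"A": 1, "C": 1, "B": 0}) is False
        assert rule.evaluate({"A": 0, "C": 0, "B": 1}) is False

    def test_self_conjunction_mode(self):
        g = self._graph([("A", "B", "activation")])
        rule = compile_update_functions(g, self_conjunction=True)["B"]
        assert rule.evaluate({"A": 1, "B": 1}) is True
        assert rule.evaluate({"A": 1, "B": 0}) is False

    def test_input_node_holds_value(self):
        g = self._graph([("A", "B", "activation")])
        rule = compile_update_functions(g)["A"]
        assert rule.is_input
        assert rule.evaluate({"A": 1}) is True
        assert rule.evaluate({"A": 0}) is False

    def test_contradictory_edges_inhibitor_wins(self, caplog):
        g = self._graph([("A", "B", "activation"), ("A", "B", "inhibition")])
        rule = compile_update_functions(g)["B"]
        assert rule.activators == ()
        assert rule.inhibitors == ("A",)

    def test_or_mode_activators(self):
        g = self._graph([("A", "C", "activation"), ("B", "C", "activation")])
        rule = compile_update_functions(g, activator_mode="or")["C"]
        assert rule.evaluate({"A": 1, "B": 0, "C": 0}) is True

    def test_rule_text_round_trip(self):
        g = self._graph([("A", "B", "activation"), ("C", "B", "inhibition"),
                         ("B", "C", "phosphorylation")])
        rules = compile_update_functions(g, self_conjunction=True)
        assert rules_from_text(rules_to_text(rules)) == rules


class TestExpressionCalls:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "experiment", "fc",
                                           "direction"])

    def test_majority_up(self):
        calls = derive_expression_calls(self._table([
            ("g1", "e1", 2.5, "up"), ("g1", "e2", 3.0, "up"),
            ("g1", "e3", 2.2, "down")]))
        (call,) = calls
        assert call.direction == "up" and call.n_up == 2 and call.n_down == 1

    def test_exact_tie_discarded(self):
        (call,) = derive_expression_calls(self._table([
            ("g1", "e1", 2.5, "up"), ("g1", "e2", 3.0, "down")]))
        assert call.direction == "discarded"

    def test_subthreshold_never_called(self):
        calls = derive_expression_calls(self._table([("g1", "e1", 1.8, "up")]))
        assert calls == []

    def test_threshold_is_strict(self):
        calls = derive_expression_calls(self._table([("g1", "e1", 2.0, "up")]))
        assert calls == []

    def test_non_numeric_rows_skipped(self, caplog):
        (call,) = derive_expression_calls(self._table([
            ("g1", "e1", "bad", "up"), ("g1", "e2", 2.5, "down")]))
        assert call.direction == "down"

    def test_disease_node_assignment(self):
        calls = derive_expression_calls(self._table([
            ("up_g", "e1", 3.0, "up"), ("dn_g", "e1", 3.0, "down"),
            ("tie_g", "e1", 3.0, "up"), ("tie_g", "e2", 3.0, "down"),
            ("absent", "e1", 4.0, "up")]))
        dn = assign_disease_nodes(["up_g", "dn_g", "tie_g"], calls)
        assert dn == {"up_g": 1, "dn_g": 0}


class TestBooleCube:
    def test_corner_exactness_exhaustive(self):
        """Interpolation equals the Boolean rule on all corners (n ≤ 10)."""
        rules = [
            BooleanRule("t", activators=("a", "b"), inhibitors=("c",)),
            BooleanRule("t", activators=tuple(f"x{i}" for i in range(6)),
                        inhibitors=("y", "z"), self_conjunct=True),
            BooleanRule("t", activators=("a", "b", "c"), inhibitors=(),
                        activator_mode="or"),
        ]
        for rule in rules:
            for corner in itertools.product((0, 1), repeat=len(rule.inputs)):
                state = dict(zip(rule.inputs, corner))
                assert boolecube_eval(rule, state) == float(rule.evaluate(state))

    def test_or_surrogate_at_half(self):
        rule = BooleanRule("t", activators=("a", "b"), activator_mode="or")
        assert boolecube_eval(rule, {"a": 0.5, "b": 0.5}) == pytest.approx(0.75)

    def test_and_at_half(self):
        rule = BooleanRule("t", activators=("a", "b"))
        assert boolecube_eval(rule, {"a": 0.5, "b": 0.5}) == pytest.approx(0.25)

    def test_closed_form_matches_corner_sum(self):
        rng = np.random.default_rng(0)
        rule = BooleanRule("t", activators=("a", "b"), inhibitors=("c", "d"),
                           self_conjunct=True)
        for _ in range(20):
            state = {n: float(rng.uniform()) for n in rule.inputs}
            assert rule.continuous(state) == pytest.approx(
                boolecube_eval(rule, state), abs=1e-12)

    def test_state_outside_unit_interval_rejected(self):
        rule = BooleanRule("t", activators=("a",))
        with pytest.raises(ValueError):
            boolecube_eval(rule, {"a": 1.2, "t": 0.0})


class TestSimulateODE:
    def test_input_node_holds_value(self):
        rules = {"A": BooleanRule("A"),
                 "B": BooleanRule("B", activators=("A",))}
        final = simulate_ode(rules, {"A": 1.0, "B": 0.0})
        assert final["A"] == pytest.approx(1.0)

    def test_activation_chain_transmits(self):
        rules = {"A": BooleanRule("A"),
                 "B": BooleanRule("B", activators=("A",))}
        final = simulate_ode(rules, {"A": 1.0, "B": 0.0})
        assert final["B"] > 0.95

    def test_boolean_fixed_point_is_ode_equilibrium(self):
        rules = {"A": BooleanRule("A"),
                 "B": BooleanRule("B", activators=("A",)),
                 "C": BooleanRule("C", activators=("B",), inhibitors=("A",))}
        fp = synchronous_fixed_point(rules, {"A": 1, "B": 1, "C": 0})
        assert fp == {"A": 1, "B": 1, "C": 0}
        final = simulate_ode(rules, {n: float(v) for n, v in fp.items()})
        for node, value in fp.items():
            assert final[node] == pytest.approx(value, abs=1e-3)

    def test_trajectory_stays_in_unit_cube(self):
        path, truth = gen_kgml(PathwaySpec(n_nodes=7, n_edges=10,
                                           inhibition_fraction=0.4), 3,
                               "/tmp/traj.xml")
        rng = np.random.default_rng(1)
        init = {n: float(rng.uniform()) for n in truth}
        final = simulate_ode(truth, init)
        assert all(0.0 <= v <= 1.0 for v in final.values())

    def test_acyclic_discretized_trajectory_matches_boolean_fixed_point(
            self, tmp_path):
        """Feed-forward pathways: ODE at t_end, discretized at 0.5, equals
        the synchronous Boolean fixed point from the same initial state."""
        for seed in range(4):
            path, rules = gen_kgml(
                PathwaySpec(n_nodes=8, n_edges=11, inhibition_fraction=0.3),
                seed=seed, out_path=tmp_path / f"ff{seed}.xml")
            rng = np.random.default_rng(seed)
            init = {n: int(rng.integers(2)) for n in rules}
            fp = synchronous_fixed_point(rules, init)
            assert fp is not None  # acyclic with input-hold always settles
            final = simulate_ode(rules, {n: float(v) for n, v in init.items()})
            assert {n: int(v > 0.5) for n, v in final.items()} == fp

    def test_missing_init_rejected(self):
        rules = {"A": BooleanRule("A")}
        with pytest.raises(ValueError):
            simulate_ode(rules, {})


def test_build_pathway_model_partitions_nodes():
    rules = {n: BooleanRule(n) for n in "ABCD"}
    calls = derive_expression_calls(pd.DataFrame(
        [("A", "e1", 3.0, "up"), ("B", "e1", 3.0, "down")],
        columns=["gene", "experiment", "fc", "direction"]))
    model = build_pathway_model("p", rules, calls, tp_values={"C": 1, "Z": 0})
    assert model.dn_values == {"A": 1, "B": 0}
    assert model.tp_values == {"C": 1}  # Z absent from the pathway
    assert model.free_nodes == ["D"]
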