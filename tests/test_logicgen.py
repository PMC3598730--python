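"""Interaction-graph construction and DNF gate synthesis."""

import itertools
import random

import pytest
from sympy import symbols
from sympy.logic import SOPform

from pimkit.discretize import TruthTable
from pimkit.io import RandomPimConfig, random_pim
from pimkit.logicgen import (
    derive_interaction_graph,
    derive_lnodes,
    derive_logical_model,
    effective_edges,
    export_logic,
    synthesize_gate,
)


class TestCorrespondsTo:
    def test_small_example_mapping(self, small):
        _, corr = derive_lnodes(small)
        assert corr.p_to_l == {1: "R.b1", 2: "R.p1", 3: "R.p2", 4: "B.b1"}
        assert corr.l_to_l == [("A.b1", "R.b1")]

    def test_orientation_tiebreak_flips(self, small):
        _, corr = derive_lnodes(small, orientation="first")
        assert corr.p_to_l[1] == "A.b1"
        assert ("R.b1", "A.b1") in corr.l_to_l

    def test_double_docking_inserts_auxiliary(self, double_docking):
        nodes, corr = derive_lnodes(double_docking)
        ids = {n.id for n in nodes}
        assert "A.b1__p4" in ids
        assert corr.p_to_l[3] == "A.b1"
        assert corr.p_to_l[4] == "A.b1__p4"
        # the correspondence stays one-to-one
        assert len(set(corr.p_to_l.values())) == len(corr.p_to_l)

    def test_single_modification_process(self, ubiquitin_degradation):
        nodes, corr = derive_lnodes(ubiquitin_degradation)
        roles = {n.id: n.role for n in nodes}
        assert roles["A.u"] == "site"
        assert roles["A"] == "basal"
        assert corr.p_to_l[2] == "A.u"

    @pytest.mark.parametrize("seed", range(30))
    def test_one_to_one_on_random_pims(self, seed):
        pim = random_pim(RandomPimConfig(seed=seed))
        _, corr = derive_lnodes(pim)
        assert len(set(corr.p_to_l.values())) == len(pim.processes)


class TestInteractionGraph:
    def test_small_example_edges(self, small):
        graph = derive_interaction_graph(small)
        activating = {
            (e.source, e.target) for e in graph.edges if e.etype == "activating"
        }
        unsigned = {
            (e.source, e.target) for e in graph.edges if e.etype == "unsigned"
        }
        assert activating == {
            ("A", "A.b1"),
            ("R", "R.b1"),
            ("R", "R.p1"),
            ("R", "R.p2"),
            ("B", "B.b1"),
            ("A.b1", "R.b1"),
        }
        assert unsigned == {
            ("R.b1", "R.p1"),
            ("R.p1", "R.p2"),
            ("R.p2", "R.p1"),
            ("R.p1", "B.b1"),
        }

    def test_degradation_edge_is_inhibiting_and_delayed(
        self, ubiquitin_degradation
    ):
        graph = derive_interaction_graph(ubiquitin_degradation)
        deg = [e for e in graph.edges if e.etype == "inhibiting"]
        assert len(deg) == 1
        assert deg[0].target == "A" and deg[0].delay
        assert graph.nodes[deg[0].source].role == "degradation"

    @pytest.mark.parametrize("seed", range(30))
    def test_unsigned_edges_bijective_with_influences(self, seed):
        pim = random_pim(RandomPimConfig(seed=seed))
        graph = derive_interaction_graph(pim)
        unsigned = [e for e in graph.edges if e.etype == "unsigned"]
        assert len(unsigned) == len(pim.influences)

    def test_every_site_node_has_basal_activation(self, egf_insulin):
        graph = derive_interaction_graph(egf_insulin)
        for nid, node in graph.nodes.items():
            if node.role in ("site", "auxiliary"):
                sources = {
                    e.source for e in graph.in_edges(nid, "activating")
                }
                assert node.molecule in sources


def _eval_gate(gate, assign):
    def lit(name, pol):
        return assign[name] if pol else not assign[name]

    return any(all(lit(n, p) for n, p in term) for term in gate.terms)


class TestGateSynthesis:
    def test_identity_over_single_input(self):
        tt = TruthTable(4, (2,), {(0,): "0", (1,): "1"})
        gate = synthesize_gate(tt, ["B"], ["R.p1"])
        assert gate.terms == (frozenset({("R.p1", True), ("B", True)}),)

    def test_or_table_with_activating_conjunction(self):
        tt = TruthTable(
            2, (1, 3), {(0, 0): "0", (0, 1): "1", (1, 0): "1", (1, 1): "1"}
        )
        gate = synthesize_gate(tt, ["R"], ["R.b1", "R.p2"])
        assert set(gate.terms) == {
            frozenset({("R.b1", True), ("R", True)}),
            frozenset({("R.p2", True), ("R", True)}),
        }

    def test_tautological_table_reduces_to_activating_and(self):
        tt = TruthTable(1, (2,), {(0,): "1", (1,): "1"})
        gate = synthesize_gate(tt, ["ins.b1", "ir"], ["ir.b_ins2"])
        assert gate.terms == (
            frozenset({("ins.b1", True), ("ir", True)}),
        )

    def test_all_unknown_table_rejected(self):
        tt = TruthTable(1, (2,), {(0,): "*", (1,): "*"})
        with pytest.raises(ValueError, match="unknown"):
            synthesize_gate(tt, [], ["x"])

    def test_itt_policies(self):
        tt = TruthTable(1, (2, 3), {(0, 0): "0", (0, 1): "*",
                                    (1, 0): "*", (1, 1): "1"})
        conservative = synthesize_gate(tt, [], ["a", "b"])
        assert conservative.itt_flag
        as_zero = synthesize_gate(tt, [], ["a", "b"], itt_policy="star_as_0")
        assert not as_zero.itt_flag
        assert _eval_gate(as_zero, {"a": True, "b": False}) is False
        as_one = synthesize_gate(tt, [], ["a", "b"], itt_policy="star_as_1")
        assert _eval_gate(as_one, {"a": True, "b": False}) is True

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 6, 8, 10])
    def test_random_tables_agree_exhaustively(self, n):
        rng = random.Random(n)
        names = [f"x{i}" for i in range(n)]
        cube = list(itertools.product((0, 1), repeat=n))
        rows = {bits: rng.choice("01") for bits in cube}
        if all(v == "0" for v in rows.values()):
            rows[cube[0]] = "1"
        tt = TruthTable(1, tuple(range(n)), rows)
        gate = synthesize_gate(tt, [], names)
        for bits in cube:
            assign = dict(zip(names, (bool(b) for b in bits)))
            assert _eval_gate(gate, assign) == (rows[bits] == "1")

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_agrees_with_independent_minimizer(self, n):
        rng = random.Random(100 + n)
        names = [f"x{i}" for i in range(n)]
        syms = symbols(names)
        cube = list(itertools.product((0, 1), repeat=n))
        for trial in range(20):
            rows = {bits: rng.choice("01") for bits in cube}
            ones = [list(b) for b, v in rows.items() if v == "1"]
            if not ones:
                continue
            tt = TruthTable(1, tuple(range(n)), rows)
            gate = synthesize_gate(tt, [], names)
            expr = SOPform(syms, ones)
            for bits in cube:
                assign = dict(zip(names, (bool(b) for b in bits)))
                expected = bool(expr.subs(dict(zip(syms, bits))))
                assert _eval_gate(gate, assign) == expected


class TestLogicalModel:
    def test_small_example_gate_shapes(self, small):
        lm = derive_logical_model(small)

        def gate_str(nid):
            return {
                frozenset((("" if pol else "!") + name) for name, pol in term)
                for term in lm.gates[nid].terms
            }

        assert gate_str("A.b1") == {frozenset({"A"})}
        assert gate_str("R.b1") == {frozenset({"A.b1", "R"})}
        assert gate_str("R.p1") == {
            frozenset({"R.b1", "R"}),
            frozenset({"R.p2", "R"}),
        }
        assert gate_str("R.p2") == {frozenset({"R.p1", "R"})}
        assert gate_str("B.b1") == {frozenset({"R.p1", "B"})}
        assert lm.gates["R"] is None  # basal activities are inputs

    def test_aon_zero_rows_enter_gate_table(self, small):
        from pimkit.logicgen import gate_truth_table

        tt = gate_truth_table(small, 4)
        assert tt.inputs == (2,)
        assert tt.rows == {(0,): "0", (1,): "1"}

    def test_threshold_variants_nest(self, egf_insulin):
        from pimkit.core import Thresholds
        from pimkit.io import build_egf_insulin

        def edges(t1, t2):
            pim = build_egf_insulin()
            pim.thresholds = Thresholds(t1, t2)
            return effective_edges(derive_logical_model(pim))

        e_down = edges(0.001, 0.01)
        e_m = edges(0.01, 0.1)
        e_up = edges(0.1, 0.25)
        assert e_down < e_m < e_up
        # raising thresholds makes dimerization necessary for EGF binding
        assert ("egfr.d1", "egfr.b_egf", 1) in e_up - e_m
        # and the two insulin sites mutually inhibiting
        assert ("ir.b_ins", "ir.b_ins2", -1) in e_up - e_m
        assert ("ir.b_ins2", "ir.b_ins", -1) in e_up - e_m
        # lowering drops the binding -> phosphorylation requirements
        assert ("shc.b_ir", "shc.p1", 1) in e_m - e_down
        assert ("irs.b_ir", "irs.p1", 1) in e_m - e_down


class TestExportLogic:
    def test_small_example_interaction_counts(self, small):
        lm = derive_logical_model(small)
        sif = export_logic(lm)["model.sif"].strip().splitlines()
        assert len(sif) == 10  # 6 activating + 4 realized unsigned
        signs = {line.split("\t")[1] for line in sif}
        assert signs == {"1"}

    def test_export_round_trip_semantics(self, small):
        lm = derive_logical_model(small)
        gates_tsv = export_logic(lm)["gates.tsv"].strip().splitlines()[1:]
        parsed: dict[str, list[frozenset]] = {}
        for line in gates_tsv:
            nid, term, lits, _ = line.split("\t")
            if term == "input":
                parsed[nid] = None
                continue
            literals = frozenset(
                (lit.lstrip("!"), not lit.startswith("!"))
                for lit in lits.split(" & ")
            )
            parsed.setdefault(nid, []).append(literals)
        for nid, gate in lm.gates.items():
            if gate is None:
                assert parsed[nid] is None
            else:
                assert set(parsed[nid]) == set(gate.terms)

    def test_deterministic(self, egf_insulin):
        lm = derive_logical_model(egf_insulin)
        assert export_logic(lm) == export_logic(derive_logical_model(egf_insulin))
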