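"""Derive the site-specific logical model from a PIM.

Construction is two-step. First an interaction graph is built: one L-node
per molecule site referenced by any process, one basal-activity L-node per
molecule (the presence/absence input used in analysis scenarios), plus
auxiliary and degradation L-nodes where needed. Unsigned edges mirror the
PIM influences one-to-one through the corresponds-to relation; activating
edges encode molecule structure (basal -> each site) and the arbitrary
orientation of binding pairs without prior modification. Second, every
L-node is equipped with a logical gate in disjunctive normal form obtained
from its process's discretized parameter table via Quine-McCluskey, with
every activating input AND-conjoined.

Corresponds-to relation:

* a modification (or homodimerization) process corresponds to its unique
  site L-node;
* a binding process at a previously modified site (all-or-none from the
  modification) corresponds to the *partner* site L-node, the modified
  site staying with its modification process;
* a binding process of two unmodified sites corresponds, by a configurable
  tie-break, to the site of its second-listed molecule; the other site then
  corresponds to that L-node and passes its basal value through an
  activating edge (the choice does not affect analysis results);
* when two binding processes would claim one L-node (one molecule binding
  two previously modified sites through a common site), the process with
  the lowest id keeps it and each later one receives an auxiliary L-node.

Truth tables containing '*' (unknown) outputs cannot feed Quine-McCluskey
directly; the default incomplete-truth-table (ITT) policy excludes those
rows from the on- and off-sets (they become algorithmic don't-cares) and
flags the gate, keeping the raw table attached for inspection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .core import PIM, validate_pim
from .discretize import TruthTable, truth_table
from .qmc import minimize

__all__ = [
    "LNode",
    "CorrespondsTo",
    "Edge",
    "InteractionGraph",
    "GateFunction",
    "LogicalModel",
    "derive_lnodes",
    "derive_interaction_graph",
    "gate_truth_table",
    "synthesize_gate",
    "derive_logical_model",
    "effective_edges",
    "export_logic",
    "export_dot",
]


@dataclass(frozen=True)
class LNode:
    id: str
    role: str  # site | basal | auxiliary | degradation
    molecule: str
    site: str | None = None


@dataclass
class CorrespondsTo:
    p_to_l: dict[int, str] = field(default_factory=dict)
    # arbitrary-orientation pairs (source site, corresponding site); one site
    # may serve several binding processes and thus appear as source repeatedly
    l_to_l: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    etype: str  # activating | unsigned | inhibiting
    delay: bool = False


@dataclass
class InteractionGraph:
    nodes: dict[str, LNode]
    edges: list[Edge]
    corresponds: CorrespondsTo

    def in_edges(self, node: str, etype: str | None = None) -> list[Edge]:
        return [
            e
            for e in self.edges
            if e.target == node and (etype is None or e.etype == etype)
        ]


@dataclass
class GateFunction:
    """DNF gate of one L-node: OR over terms, term = AND over literals.

    ``terms`` of length zero is the constant-false gate; an empty literal
    set inside a term is the constant-true term. Literals are
    (input L-node id, polarity) with polarity False meaning negation.
    """

    lnode: str
    terms: tuple[frozenset[tuple[str, bool]], ...]
    itt_flag: bool = False
    source_table: TruthTable | None = None

    def literals(self) -> set[tuple[str, bool]]:
        return {lit for term in self.terms for lit in term}

    def inputs(self) -> set[str]:
        return {name for name, _ in self.literals()}


@dataclass
class LogicalModel:
    graph: InteractionGraph
    gates: dict[str, GateFunction | None]  # None: input node (basal)
    delayed_edges: list[Edge]

    @property
    def nodes(self) -> dict[str, LNode]:
        return self.graph.nodes

    def input_nodes(self) -> list[str]:
        return sorted(n for n, g in self.gates.items() if g is None)


# ---------------------------------------------------------------------------
# L-nodes and the corresponds-to relation
# ---------------------------------------------------------------------------


def _site_id(molecule: str, site: str) -> str:
    return f"{molecule}.{site}"


def _aux_id(molecule: str, site: str, pid: int) -> str:
    return f"{molecule}.{site}__p{pid}"


def _deg_id(molecule: str, pid: int) -> str:
    return f"{molecule}.deg_p{pid}"


def _prior_modification(pim: PIM, binding_id: int, refs) -> dict:
    """Map a binding site ref -> the modification process it requires (AON)."""
    out = {}
    for src, kind in pim.predecessors(binding_id):
        if kind != "all_or_none":
            continue
        proc = pim.process(src)
        if proc.ptype == "modification" and proc.assignments[0] in refs:
            out[proc.assignments[0]] = src
    return out


def derive_lnodes(
    pim: PIM, orientation: str = "second"
) -> tuple[list[LNode], CorrespondsTo]:
    """Create the L-nodes and the one-to-one P-node correspondence."""
    if orientation not in ("first", "second"):
        raise ValueError("orientation must be 'first' or 'second'")
    nodes: dict[str, LNode] = {}
    for mol in pim.molecules:
        nodes[mol.name] = LNode(mol.name, "basal", mol.name)
    for proc in pim.processes:
        for ref in proc.assignments:
            nid = _site_id(ref.molecule, ref.site)
            nodes.setdefault(nid, LNode(nid, "site", ref.molecule, ref.site))

    corr = CorrespondsTo()
    claimed: set[str] = set()

    def claim(pid: int, lnode_id: str, molecule: str, site: str | None) -> None:
        if lnode_id in claimed:
            aux = _aux_id(molecule, site, pid)
            nodes[aux] = LNode(aux, "auxiliary", molecule, site)
            corr.p_to_l[pid] = aux
            claimed.add(aux)
        else:
            corr.p_to_l[pid] = lnode_id
            claimed.add(lnode_id)

    for proc in sorted(pim.processes, key=lambda p: p.id):
        if proc.ptype in ("modification", "homodimerization"):
            ref = proc.assignments[0]
            claim(proc.id, _site_id(ref.molecule, ref.site), ref.molecule, ref.site)
        elif proc.ptype == "degradation":
            nid = _deg_id(proc.molecule, proc.id)
            nodes[nid] = LNode(nid, "degradation", proc.molecule)
            claim(proc.id, nid, proc.molecule, None)
        else:  # binding
            r1, r2 = proc.assignments
            prior = _prior_modification(pim, proc.id, set(proc.assignments))
            free = [r for r in (r1, r2) if r not in prior]
            if not free:
                # both sites modified beforehand: no free site remains
                aux = _aux_id(r1.molecule, r1.site, proc.id)
                nodes[aux] = LNode(aux, "auxiliary", r1.molecule, r1.site)
                corr.p_to_l[proc.id] = aux
                claimed.add(aux)
            elif len(free) == 1:
                ref = free[0]
                claim(proc.id, _site_id(ref.molecule, ref.site), ref.molecule, ref.site)
            else:
                chosen = r2 if orientation == "second" else r1
                other = r1 if chosen is r2 else r2
                claim(
                    proc.id,
                    _site_id(chosen.molecule, chosen.site),
                    chosen.molecule,
                    chosen.site,
                )
                corr.l_to_l.append(
                    (_site_id(other.molecule, other.site), corr.p_to_l[proc.id])
                )
    return list(nodes.values()), corr


def derive_interaction_graph(pim: PIM, orientation: str = "second") -> InteractionGraph:
    lnodes, corr = derive_lnodes(pim, orientation)
    nodes = {n.id: n for n in lnodes}
    edges: list[Edge] = []
    # molecule structure: basal activates every site-like node of the molecule
    for n in lnodes:
        if n.role in ("site", "auxiliary", "degradation"):
            edges.append(Edge(n.molecule, n.id, "activating"))
    # arbitrary-orientation pass-through
    for src, tgt in sorted(set(corr.l_to_l)):
        edges.append(Edge(src, tgt, "activating"))
    # unsigned edges: one per PIM influence
    for inf in sorted(pim.influences, key=lambda i: (i.source, i.target)):
        edges.append(
            Edge(corr.p_to_l[inf.source], corr.p_to_l[inf.target], "unsigned")
        )
    # degradation inhibits the basal activity, with a time delay
    for proc in pim.processes:
        if proc.ptype == "degradation":
            edges.append(
                Edge(corr.p_to_l[proc.id], proc.molecule, "inhibiting", delay=True)
            )
    return InteractionGraph(nodes=nodes, edges=edges, corresponds=corr)


# ---------------------------------------------------------------------------
# Gate synthesis
# ---------------------------------------------------------------------------


def gate_truth_table(pim: PIM, node: int) -> TruthTable:
    """Truth table of a process over *all* its predecessors.

    All-or-none inputs re-enter as explicit inputs whose 0-rows output 0
    (the process cannot have occurred without them); the remaining entries
    come from the discretized parameter table over the free inputs.
    """
    base = truth_table(pim, node)
    preds = pim.predecessors(node)
    inputs = tuple(p for p, _ in preds)
    aon = {p for p, kind in preds if kind == "all_or_none"}
    free = base.inputs
    rows: dict[tuple[int, ...], str] = {}
    for bits in itertools.product((0, 1), repeat=len(inputs)):
        assign = dict(zip(inputs, bits))
        if any(assign[p] == 0 for p in aon):
            rows[bits] = "0"
        else:
            rows[bits] = base.rows[tuple(assign[p] for p in free)]
    return TruthTable(node=node, inputs=inputs, rows=rows)


def synthesize_gate(
    tt: TruthTable,
    activating_inputs: list[str],
    input_names: list[str] | None = None,
    itt_policy: str = "conservative",
    lnode: str = "",
) -> GateFunction:
    """Minimal DNF over the truth table, AND-conjoined with every activating
    input. '*' rows are handled by the ITT policy: ``conservative`` treats
    them as don't-cares and flags the gate; ``star_as_0``/``star_as_1``
    resolve them to a definite value."""
    names = list(input_names) if input_names is not None else [
        str(i) for i in tt.inputs
    ]
    if len(names) != len(tt.inputs):
        raise ValueError("input_names must align with the table inputs")
    n = len(tt.inputs)
    rows = tt.rows
    if rows and all(v == "*" for v in rows.values()):
        raise ValueError("gate truth table is entirely unknown (all '*')")
    stars = [ctx for ctx, v in rows.items() if v == "*"]
    ones = [ctx for ctx, v in rows.items() if v == "1"]
    if itt_policy == "star_as_1":
        ones, stars = ones + stars, []
    elif itt_policy == "star_as_0":
        stars = []
    elif itt_policy != "conservative":
        raise ValueError(f"unknown ITT policy {itt_policy!r}")

    implicants = minimize(n, ones, stars)
    act = frozenset((a, True) for a in activating_inputs)
    terms: list[frozenset] = []
    for imp in implicants:
        lits = {(names[i], bool(b)) for i, b in enumerate(imp) if b is not None}
        terms.append(frozenset(lits) | act)
    if implicants == [tuple([None] * n)] or (n == 0 and implicants == [()]):
        terms = [act]  # tautological table: pure AND of activating inputs
    return GateFunction(
        lnode=lnode,
        terms=tuple(sorted(terms, key=sorted)),
        itt_flag=bool([ctx for ctx, v in rows.items() if v == "*"])
        and itt_policy == "conservative",
        source_table=tt,
    )


def derive_logical_model(
    pim: PIM,
    orientation: str = "second",
    itt_policy: str = "conservative",
) -> LogicalModel:
    """Interaction graph plus one DNF gate per non-input L-node."""
    report = validate_pim(pim)
    if not report.ok:
        raise ValueError(f"invalid PIM:\n{report}")
    graph = derive_interaction_graph(pim, orientation)
    corr = graph.corresponds
    gates: dict[str, GateFunction | None] = {}
    for nid, lnode in graph.nodes.items():
        if lnode.role == "basal":
            gates[nid] = None  # scenario input

    l_to_p = {l: p for p, l in corr.p_to_l.items()}
    for nid, lnode in sorted(graph.nodes.items()):
        if lnode.role == "basal":
            continue
        activating = sorted(
            e.source for e in graph.in_edges(nid, "activating")
        )
        pid = l_to_p.get(nid)
        if pid is None:
            # no associated process: value passes through activating inputs
            gates[nid] = GateFunction(
                lnode=nid,
                terms=(frozenset((a, True) for a in activating),),
            )
            continue
        tt = gate_truth_table(pim, pid)
        input_names = [corr.p_to_l[p] for p in tt.inputs]
        gates[nid] = synthesize_gate(
            tt, activating, input_names, itt_policy=itt_policy, lnode=nid
        )
    delayed = [e for e in graph.edges if e.delay]
    return LogicalModel(graph=graph, gates=gates, delayed_edges=delayed)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def effective_edges(model: LogicalModel) -> set[tuple[str, str, int]]:
    """Signed influences realized by the gates.

    Activating edges always appear (+1). An unsigned edge contributes only
    if its source occurs as a literal in the target's DNF; the sign follows
    the literal polarity (0 when both polarities occur). Delayed inhibiting
    edges are reported with sign -1.
    """
    out: set[tuple[str, str, int]] = set()
    for edge in model.graph.edges:
        if edge.etype == "activating":
            out.add((edge.source, edge.target, 1))
        elif edge.etype == "inhibiting":
            out.add((edge.source, edge.target, -1))
        else:
            gate = model.gates.get(edge.target)
            if gate is None:
                continue
            pols = {pol for name, pol in gate.literals() if name == edge.source}
            if pols == {True}:
                out.add((edge.source, edge.target, 1))
            elif pols == {False}:
                out.add((edge.source, edge.target, -1))
            elif pols:
                out.add((edge.source, edge.target, 0))
    return out


def export_logic(model: LogicalModel) -> dict[str, str]:
    """SIF edge list plus a TSV of DNF terms; deterministic output."""
    sif_lines = [
        f"{src}\t{sign}\t{tgt}"
        for src, tgt, sign in sorted(effective_edges(model))
    ]
    gate_lines = ["node\tterm\tliterals\titt"]
    for nid in sorted(model.gates):
        gate = model.gates[nid]
        if gate is None:
            gate_lines.append(f"{nid}\tinput\t\t")
            continue
        if not gate.terms:
            gate_lines.append(f"{nid}\t0\tFALSE\t{int(gate.itt_flag)}")
        for i, term in enumerate(gate.terms):
            lits = " & ".join(
                ("" if pol else "!") + name for name, pol in sorted(term)
            )
            gate_lines.append(f"{nid}\t{i}\t{lits or 'TRUE'}\t{int(gate.itt_flag)}")
    return {
        "model.sif": "\n".join(sif_lines) + "\n",
        "gates.tsv": "\n".join(gate_lines) + "\n",
    }


def export_dot(model: LogicalModel) -> str:
    lines = ["digraph logical_model {", "  rankdir=LR;"]
    shape = {"basal": "hexagon", "site": "box", "auxiliary": "ellipse",
             "degradation": "diamond"}
    for nid in sorted(model.nodes):
        node = model.nodes[nid]
        lines.append(f'  "{nid}" [shape={shape[node.role]}];')
    for src, tgt, sign in sorted(effective_edges(model)):
        style = "normal" if sign > 0 else ("tee" if sign < 0 else "diamond")
        lines.append(f'  "{src}" -> "{tgt}" [arrowhead={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
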