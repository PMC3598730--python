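"""Three-valued analysis of site-specific logical models.

States assign each L-node a value in {0, 1, *} (Kleene logic: * is
unknown). Steady states are computed by synchronous gate application
starting from all-unknown on the non-fixed nodes; because every gate is
monotone in the information order (* below 0 and 1), values only ever
resolve and the iteration reaches a fixed point in at most one pass per
node. Delay-flagged edges (degradation feedback onto basal activity) are
excluded, so the result is the pre-degradation response; the scenario
report lists the ignored edges.

Built on top of steady states:

* species equivalence classes — enumerate every completion of the
  undefined inputs, compute the steady states, and group L-nodes whose
  value vectors across completions coincide; nodes with a constant vector
  are input-independent and belong to no class;
* minimal intervention sets — exhaustive search over knockout subsets
  (nodes fixed to 0) that block a target node, reported as an
  inclusion-minimal antichain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .logicgen import GateFunction, LogicalModel

__all__ = [
    "Scenario",
    "evaluate_gate",
    "evaluate",
    "steady_state",
    "EquivalenceClasses",
    "equivalence_classes",
    "minimal_intervention_sets",
]

Value = str  # "0" | "1" | "*"


@dataclass(frozen=True)
class Scenario:
    """Input fixings plus (optional) knockouts for one analysis run.

    ``fixed`` maps L-nodes (typically basal activities) to 0/1/*; a value
    of '*' declares an undefined input enumerated by the equivalence-class
    analysis. ``interventions`` are knockouts, always to 0. ``stimuli``
    names the ligand inputs of the scenario; they are excluded from the
    intervention-candidate space.
    """

    fixed: dict[str, Value] = field(default_factory=dict)
    interventions: dict[str, Value] = field(default_factory=dict)
    stimuli: tuple[str, ...] = ()

    def with_knockouts(self, nodes) -> "Scenario":
        iv = dict(self.interventions)
        iv.update({n: "0" for n in nodes})
        return Scenario(dict(self.fixed), iv, self.stimuli)

    def clamped(self) -> dict[str, Value]:
        out = {k: v for k, v in self.fixed.items() if v != "*"}
        out.update(self.interventions)
        return out


def all_basal_on(model: LogicalModel, **overrides: Value) -> Scenario:
    """Every basal input 1, with keyword overrides (e.g. ``egf='0'``)."""
    fixed = {n: "1" for n in model.input_nodes()}
    for name, value in overrides.items():
        if name not in fixed:
            raise KeyError(f"{name} is not an input node")
        fixed[name] = value
    return Scenario(fixed=fixed)


def _and(values) -> Value:
    if any(v == "0" for v in values):
        return "0"
    if all(v == "1" for v in values):
        return "1"
    return "*"


def _or(values) -> Value:
    if any(v == "1" for v in values):
        return "1"
    if all(v == "0" for v in values):
        return "0"
    return "*"


def _not(v: Value) -> Value:
    return {"0": "1", "1": "0", "*": "*"}[v]


def evaluate_gate(gate: GateFunction, state: dict[str, Value]) -> Value:
    if not gate.terms:
        return "0"
    term_values = []
    for term in gate.terms:
        lits = [state[name] if pol else _not(state[name]) for name, pol in term]
        term_values.append(_and(lits) if lits else "1")
    return _or(term_values)


def evaluate(model: LogicalModel, state: dict[str, Value],
             fixed: set[str] | None = None) -> dict[str, Value]:
    """One synchronous application of every gate; fixed nodes unchanged."""
    fixed = fixed or set()
    new = dict(state)
    for nid, gate in model.gates.items():
        if gate is None or nid in fixed:
            continue
        new[nid] = evaluate_gate(gate, state)
    return new


def steady_state(model: LogicalModel, scenario: Scenario) -> dict[str, Value]:
    """Iterate from all-* under the scenario's clamps until a fixed point.

    Terminates in at most |nodes| sweeps: starting from all-unknown, values
    only move * -> 0/1; nodes on cycles that never resolve stay *.
    """
    clamps = scenario.clamped()
    state: dict[str, Value] = {nid: "*" for nid in model.nodes}
    state.update(clamps)
    fixed = set(clamps)
    for _ in range(len(state) + 1):
        new = evaluate(model, state, fixed)
        if new == state:
            return state
        state = new
    raise RuntimeError("steady-state iteration did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# Species equivalence classes
# ---------------------------------------------------------------------------


@dataclass
class EquivalenceClasses:
    """Partition of the input-dependent L-nodes by steady-state vector."""

    undefined_inputs: tuple[str, ...]
    completions: tuple[tuple[Value, ...], ...]
    classes: list[tuple[tuple[Value, ...], tuple[str, ...]]]
    input_independent: tuple[str, ...]

    def class_of(self, node: str) -> tuple[str, ...] | None:
        for _, members in self.classes:
            if node in members:
                return members
        return None


def equivalence_classes(model: LogicalModel, scenario: Scenario) -> EquivalenceClasses:
    """Group L-nodes sharing one steady-state value across all completions
    of the scenario's undefined ('*') inputs."""
    undef = tuple(sorted(n for n, v in scenario.fixed.items() if v == "*"))
    if len(undef) > 16:
        raise ValueError("too many undefined inputs (limit 16)")
    completions = tuple(
        itertools.product(("0", "1"), repeat=len(undef))
    )
    vectors: dict[str, list[Value]] = {nid: [] for nid in model.nodes}
    for combo in completions:
        fixed = dict(scenario.fixed)
        fixed.update(dict(zip(undef, combo)))
        sub = Scenario(fixed, dict(scenario.interventions), scenario.stimuli)
        ss = steady_state(model, sub)
        for nid, value in ss.items():
            vectors[nid].append(value)
    grouped: dict[tuple[Value, ...], list[str]] = {}
    constant: list[str] = []
    for nid in sorted(vectors):
        vec = tuple(vectors[nid])
        if len(set(vec)) <= 1:
            constant.append(nid)
        else:
            grouped.setdefault(vec, []).append(nid)
    classes = [(vec, tuple(members)) for vec, members in sorted(grouped.items())]
    return EquivalenceClasses(
        undefined_inputs=undef,
        completions=completions,
        classes=classes,
        input_independent=tuple(constant),
    )


# ---------------------------------------------------------------------------
# Minimal intervention sets
# ---------------------------------------------------------------------------


def minimal_intervention_sets(
    model: LogicalModel,
    scenario: Scenario,
    target: tuple[str, Value],
    k_max: int = 2,
    candidates: list[str] | None = None,
) -> list[tuple[str, ...]]:
    """Inclusion-minimal knockout sets (each node fixed to 0) that block the
    target: its steady-state value becomes the definite opposite of the
    value to prevent. Exhaustive over subsets of size <= k_max (<= 4)."""
    target_node, prevent = target
    if prevent not in ("0", "1"):
        raise ValueError("value to prevent must be 0 or 1")
    if k_max > 4:
        raise ValueError("brute-force search supports k_max <= 4")
    blocked_value = _not(prevent)
    if candidates is None:
        candidates = sorted(
            nid
            for nid, lnode in model.nodes.items()
            if lnode.role in ("site", "basal") and nid not in scenario.stimuli
        )
    if steady_state(model, scenario).get(target_node) == blocked_value:
        return [()]  # already blocked without intervention

    results: list[tuple[str, ...]] = []
    for size in range(1, k_max + 1):
        for combo in itertools.combinations(candidates, size):
            if any(set(prev) <= set(combo) for prev in results):
                continue
            ss = steady_state(model, scenario.with_knockouts(combo))
            if ss.get(target_node) == blocked_value:
                results.append(tuple(combo))
    return sorted(results, key=lambda s: (len(s), s))
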