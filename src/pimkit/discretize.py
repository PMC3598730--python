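"""Discretize parameter tables into three-valued truth tables.

The relative size of a context's equilibrium constant k_eq = k_fw/k_bw (for
irreversible processes, of k_fw itself) measures how strongly the context
favors the process. Two thresholds t1 < t2 turn this into a three-valued
output y: the process counts as occurred (y=1) when the constant is >= t2,
as not occurred (y=0) when it is <= t1, and as unknown (y='*') in between.
Both comparisons are inclusive; values are compared exactly as parsed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import PIM, ContextRow, Thresholds, enumerate_contexts, equilibrium_constant

__all__ = ["TruthTable", "discretize_row", "truth_table"]


@dataclass(frozen=True)
class TruthTable:
    """Three-valued truth table of one process node.

    ``inputs`` are the free (non-all-or-none) predecessor ids in canonical
    order; ``rows`` maps each admissible context to an output in {0, 1, '*'}.
    For homodimerization nodes only equal-monomer contexts appear, projected
    to a single copy of the inputs.
    """

    node: int
    inputs: tuple[int, ...]
    rows: dict[tuple[int, ...], str]

    def outputs(self) -> set[str]:
        return set(self.rows.values())


def discretize_row(row: ContextRow, th: Thresholds | tuple[float, float],
                   reversible: bool = True, node: int | None = None) -> str:
    """Three-valued output of one context row.

    An explicit ``y_override`` (used for mutual-exclusion rows, whose value
    cannot come from kinetics) wins unconditionally.
    """
    if row.y_override is not None:
        return row.y_override
    if isinstance(th, Thresholds):
        t1, t2 = th.for_node(node) if node is not None else (th.t1, th.t2)
    else:
        t1, t2 = th
    value = equilibrium_constant(row) if reversible else row.k_fw
    if value is None:
        raise ValueError("row has no kinetics and no y override")
    if value >= t2:
        return "1"
    if value <= t1:
        return "0"
    return "*"


def truth_table(pim: PIM, node: int) -> TruthTable:
    """Interpret the parameter table of ``node`` as a three-valued truth table.

    Every admissible context is discretized with the node's thresholds.
    Mutual-exclusion rows (inadmissible for the kinetic table) enter with
    their y override, defaulting to '*'. For homodimerization nodes only the
    rows with both monomers in the same state are kept, since in the logical
    view all representatives of a species share one state.
    """
    proc = pim.process(node)
    table = pim.tables.get(node)
    if table is None:
        raise KeyError(f"process {node} has no parameter table")
    t1, t2 = pim.thresholds.for_node(node)
    free = pim.free_inputs(node)

    rows: dict[tuple[int, ...], str] = {}
    if proc.ptype == "homodimerization":
        k = len(free)
        for ctx in enumerate_contexts(pim, node):
            a, b = ctx[:k], ctx[k:]
            if a != b:
                continue
            rows[a] = discretize_row(table.row_for(ctx), (t1, t2), proc.reversible)
    else:
        for ctx in enumerate_contexts(pim, node):
            rows[ctx] = discretize_row(table.row_for(ctx), (t1, t2), proc.reversible)
        # mutual-exclusion rows: both competitors active, value set directly
        kinetic = set(rows)
        for row in table.rows:
            if not row.is_kinetic and row.ctx not in kinetic:
                rows[row.ctx] = row.y_override if row.y_override is not None else "*"
        for bits in _full_cube(len(free)):
            rows.setdefault(bits, "*")
    return TruthTable(node=node, inputs=free, rows=rows)


def _full_cube(n: int):
    import itertools

    return itertools.product((0, 1), repeat=n)
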