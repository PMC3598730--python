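"""Generate a complete rule-based model (BNGL) from a PIM.

Every process node expands into one reaction rule per admissible context.
The node's assignments form the reaction center (the sites that change);
the occurrence pattern of preceding processes is written onto the patterns
of both rule sides as the reaction context, following the don't-care,
don't-write principle: sites not involved in center or context are omitted.

Modification sites use the uniform state labels ~U (unmodified) and ~M
(modified). An occurred binding predecessor shows the bound partner with an
explicit bond; a non-occurred one shows the site explicitly unbound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .core import PIM, ProcessNode, SiteRef, enumerate_contexts, validate_pim

__all__ = ["Rule", "rules_for_node", "export_bngl", "drop_molecule", "param_name"]


# ---------------------------------------------------------------------------
# Site patterns
# ---------------------------------------------------------------------------


@dataclass(eq=False)  # identity semantics: a complex may repeat equal patterns
class _MoleculeInstance:
    molecule: str
    # site -> [state, bond]; state in (None, "U", "M"), bond None | int
    components: dict[str, list] = field(default_factory=dict)

    def touch(self, site: str) -> list:
        return self.components.setdefault(site, [None, None])

    def render(self, site_order: dict[str, tuple[str, ...]]) -> str:
        order = site_order.get(self.molecule, ())
        ordered = [s for s in order if s in self.components]
        ordered += [s for s in self.components if s not in order]
        parts = []
        for s in ordered:
            state, bond = self.components[s]
            text = s
            if state is not None:
                text += f"~{state}"
            if bond is not None:
                text += f"!{bond}"
            parts.append(text)
        return f"{self.molecule}({','.join(parts)})"


def _render_side(
    instances: list[_MoleculeInstance],
    bonds: set[frozenset[int]],
    site_order: dict[str, tuple[str, ...]],
) -> str:
    """Group instances into complexes via bonds; '+'-join complexes."""
    n = len(instances)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for pair in bonds:
        a, b = sorted(pair)
        parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    complexes = sorted(groups.values(), key=lambda g: g[0])
    return " + ".join(
        ".".join(instances[i].render(site_order) for i in g) for g in complexes
    )


@dataclass(frozen=True)
class Rule:
    """One reaction rule with provenance back to its process node and context."""

    node: int
    ctx: tuple[int, ...]
    lhs: str
    rhs: str
    k_fw_name: str
    k_bw_name: str | None
    reversible: bool
    rate_prefix: str = ""  # "0.5*" for symmetric homodimer association

    def render(self) -> str:
        arrow = "<->" if self.reversible else "->"
        rates = f"{self.rate_prefix}{self.k_fw_name}"
        if self.reversible:
            rates += f", {self.k_bw_name}"
        return f"{self.lhs} {arrow} {self.rhs} {rates}"


def param_name(node: int, ctx: tuple[int, ...], direction: str) -> str:
    prefix = "kf" if direction == "fw" else "kb"
    if ctx:
        return f"{prefix}_n{node}_c{''.join(str(b) for b in ctx)}"
    return f"{prefix}_n{node}"


# ---------------------------------------------------------------------------
# Context encoding
# ---------------------------------------------------------------------------


def _apply_context(
    pim: PIM,
    centers: list[_MoleculeInstance],
    pred: ProcessNode,
    occurred: int,
    bonds: set[frozenset[int]],
    instances: list[_MoleculeInstance],
    next_bond: list[int],
    restrict_to: _MoleculeInstance | None = None,
    target_sites: frozenset[SiteRef] = frozenset(),
) -> None:
    """Write one predecessor's occurrence state onto the center patterns.

    ``restrict_to`` pins the context to one particular center instance (used
    for the per-monomer contexts of homodimerization rules). ``target_sites``
    are the reaction-center assignments: a binding context avoids attaching
    its bond to a site the rule itself is about to change (e.g. the shared
    ligand site of two receptor-binding processes - there the context lives
    on the receptor, occupied by a different ligand copy).
    """

    def center_for(mol: str) -> _MoleculeInstance | None:
        if restrict_to is not None:
            return restrict_to if restrict_to.molecule == mol else None
        for inst in centers:
            if inst.molecule == mol:
                return inst
        return None

    if pred.ptype == "modification":
        ref = pred.assignments[0]
        inst = center_for(ref.molecule)
        if inst is None:
            raise ValueError(
                f"context of process {pred.id} not expressible on reaction center"
            )
        comp = inst.touch(ref.site)
        comp[0] = "M" if occurred else "U"
    elif pred.ptype == "binding":
        on = [r for r in pred.assignments if center_for(r.molecule) is not None]
        if not on:
            raise ValueError(
                f"context of process {pred.id} not expressible on reaction center"
            )
        preferred = [r for r in on if r not in target_sites]
        ref_on = (preferred or on)[0]
        inst = center_for(ref_on.molecule)
        comp = inst.touch(ref_on.site)
        other = [r for r in pred.assignments if r != ref_on][0]
        other_center = (
            center_for(other.molecule) if other not in target_sites else None
        )
        if occurred:
            label = next_bond[0]
            next_bond[0] += 1
            comp[1] = label
            if other_center is not None and other_center is not inst:
                # predecessor binds the two center molecules to each other
                other_center.touch(other.site)[1] = label
                partner = other_center
            else:
                partner = _MoleculeInstance(other.molecule)
                partner.touch(other.site)[1] = label
                instances.append(partner)
            bonds.add(
                frozenset((instances.index(inst), instances.index(partner)))
            )
        else:
            # explicitly unbound: the site is written without a bond (touch
            # already did that); a bond a competing occurred-context placed
            # on the shared site is left alone - it already implies that this
            # predecessor has not occurred
            if other_center is not None and other_center is not inst:
                other_center.touch(other.site)
    elif pred.ptype == "homodimerization":
        ref = pred.assignments[0]
        inst = center_for(ref.molecule)
        if inst is None:
            raise ValueError(
                f"context of process {pred.id} not expressible on reaction center"
            )
        comp = inst.touch(ref.site)
        if occurred:
            label = next_bond[0]
            next_bond[0] += 1
            comp[1] = label
            partner = _MoleculeInstance(ref.molecule)
            partner.touch(ref.site)[1] = label
            instances.append(partner)
            bonds.add(
                frozenset((instances.index(inst), instances.index(partner)))
            )
        else:
            comp[1] = None
    else:  # pragma: no cover - degradation sources rejected by validation
        raise ValueError("degradation cannot serve as reaction context")


def _full_context(pim: PIM, node: int, ctx: tuple[int, ...]) -> list[tuple[int, int]]:
    """Pair every predecessor with its occurrence (AON inputs fixed to 1)."""
    free = pim.free_inputs(node)
    assign = dict(zip(free, ctx))
    out = []
    for p, kind in pim.predecessors(node):
        out.append((p, 1 if kind == "all_or_none" else assign[p]))
    return out


# ---------------------------------------------------------------------------
# Rule construction
# ---------------------------------------------------------------------------


def rules_for_node(pim: PIM, node: int) -> list[Rule]:
    """One rule per admissible context, in canonical context order."""
    proc = pim.process(node)
    table = pim.tables[node]
    site_order = {m.name: m.sites for m in pim.molecules}
    rules = []
    for ctx in enumerate_contexts(pim, node):
        if proc.ptype == "homodimerization":
            rules.append(_homodimer_rule(pim, proc, ctx, site_order))
        else:
            rules.append(_plain_rule(pim, proc, ctx, site_order))
        table.row_for(ctx)  # provenance check: kinetics must exist
    return rules


def _build_side(pim, proc, ctx, center_mols, modify_center):
    """Assemble instances/bonds for one rule side; modify_center mutates
    the center components between reactant and product side."""
    centers = [_MoleculeInstance(m) for m in center_mols]
    instances = list(centers)
    bonds: set[frozenset[int]] = set()
    next_bond = [2]  # bond !1 is reserved for the reaction center
    target_sites = frozenset(proc.assignments)
    for pred_id, occurred in _full_context(pim, proc.id, ctx):
        _apply_context(
            pim, centers, pim.process(pred_id), occurred, bonds, instances,
            next_bond, target_sites=target_sites,
        )
    modify_center(centers, instances, bonds)
    return instances, bonds


def _plain_rule(pim: PIM, proc: ProcessNode, ctx, site_order) -> Rule:
    if proc.ptype == "modification":
        ref = proc.assignments[0]

        def lhs_center(centers, instances, bonds):
            centers[0].touch(ref.site)[0] = "U"

        def rhs_center(centers, instances, bonds):
            centers[0].touch(ref.site)[0] = "M"

        center_mols = [ref.molecule]
    elif proc.ptype == "binding":
        r1, r2 = proc.assignments

        def lhs_center(centers, instances, bonds):
            centers[0].touch(r1.site)
            centers[1].touch(r2.site)

        def rhs_center(centers, instances, bonds):
            centers[0].touch(r1.site)[1] = 1
            centers[1].touch(r2.site)[1] = 1
            bonds.add(frozenset((instances.index(centers[0]),
                                 instances.index(centers[1]))))

        center_mols = [r1.molecule, r2.molecule]
    elif proc.ptype == "degradation":

        def lhs_center(centers, instances, bonds):
            pass

        rhs_center = None
        center_mols = [proc.molecule]
    else:  # pragma: no cover
        raise ValueError(proc.ptype)

    lhs_inst, lhs_bonds = _build_side(pim, proc, ctx, center_mols, lhs_center)
    lhs = _render_side(lhs_inst, lhs_bonds, site_order)
    if proc.ptype == "degradation":
        rhs = "0"
    else:
        rhs_inst, rhs_bonds = _build_side(pim, proc, ctx, center_mols, rhs_center)
        rhs = _render_side(rhs_inst, rhs_bonds, site_order)
    return Rule(
        node=proc.id,
        ctx=ctx,
        lhs=lhs,
        rhs=rhs,
        k_fw_name=param_name(proc.id, ctx, "fw"),
        k_bw_name=param_name(proc.id, ctx, "bw") if proc.reversible else None,
        reversible=proc.reversible,
    )


def _homodimer_rule(pim: PIM, proc: ProcessNode, ctx, site_order) -> Rule:
    ref = proc.assignments[0]
    free = pim.free_inputs(proc.id)
    k = len(free)
    ctx_a, ctx_b = ctx[:k], ctx[k:]

    def build(join: bool):
        monomers = [_MoleculeInstance(ref.molecule), _MoleculeInstance(ref.molecule)]
        instances = list(monomers)
        bonds: set[frozenset[int]] = set()
        next_bond = [2]
        for mono, mctx in zip(monomers, (ctx_a, ctx_b)):
            assign = dict(zip(free, mctx))
            for p, kind in pim.predecessors(proc.id):
                occ = 1 if kind == "all_or_none" else assign[p]
                _apply_context(
                    pim, monomers, pim.process(p), occ, bonds, instances,
                    next_bond, restrict_to=mono,
                    target_sites=frozenset(proc.assignments),
                )
        for mono in monomers:
            comp = mono.touch(ref.site)
            if join:
                comp[1] = 1
        if join:
            bonds.add(frozenset((0, 1)))
        return _render_side(instances, bonds, site_order)

    symmetric = ctx_a == ctx_b
    return Rule(
        node=proc.id,
        ctx=ctx,
        lhs=build(False),
        rhs=build(True),
        k_fw_name=param_name(proc.id, ctx, "fw"),
        k_bw_name=param_name(proc.id, ctx, "bw") if proc.reversible else None,
        reversible=proc.reversible,
        rate_prefix="0.5*" if symmetric else "",
    )


def _modification_sites(pim: PIM) -> set[SiteRef]:
    return {
        p.assignments[0] for p in pim.processes if p.ptype == "modification"
    }


# ---------------------------------------------------------------------------
# Whole-model export
# ---------------------------------------------------------------------------


def export_bngl(pim: PIM) -> str:
    """Deterministic BNGL document: parameters, molecule types, seed species
    (basic molecules, all sites unbound and unmodified, concentration 1) and
    reaction rules in ascending node/context order."""
    report = validate_pim(pim)
    if not report.ok:
        raise ValueError(f"invalid PIM:\n{report}")
    mod_sites = _modification_sites(pim)

    lines = [
        "# generated by pimkit from a Process-Interaction-Model",
        "# modification sites use states ~U (unmodified) / ~M (modified)",
        "begin model",
        "",
        "begin parameters",
    ]
    for proc in sorted(pim.processes, key=lambda p: p.id):
        table = pim.tables[proc.id]
        for ctx in enumerate_contexts(pim, proc.id):
            row = table.row_for(ctx)
            lines.append(f"  {param_name(proc.id, ctx, 'fw')} {row.k_fw:g}")
            if proc.reversible:
                lines.append(f"  {param_name(proc.id, ctx, 'bw')} {row.k_bw:g}")
    lines.append("end parameters")
    lines.append("")
    lines.append("begin molecule types")
    for mol in sorted(pim.molecules, key=lambda m: m.name):
        comps = []
        for s in mol.sites:
            ref = SiteRef(mol.name, s)
            comps.append(f"{s}~U~M" if ref in mod_sites else s)
        lines.append(f"  {mol.name}({','.join(comps)})")
    lines.append("end molecule types")
    lines.append("")
    lines.append("begin seed species")
    for mol in sorted(pim.molecules, key=lambda m: m.name):
        comps = []
        for s in mol.sites:
            ref = SiteRef(mol.name, s)
            comps.append(f"{s}~U" if ref in mod_sites else s)
        lines.append(
            f"  {mol.name}({','.join(comps)}) 1  # adjust before simulation"
        )
    lines.append("end seed species")
    lines.append("")
    lines.append("begin reaction rules")
    for proc in sorted(pim.processes, key=lambda p: p.id):
        for rule in rules_for_node(pim, proc.id):
            lines.append(f"  {rule.render()}")
    lines.append("end reaction rules")
    lines.append("")
    lines.append("end model")
    return "\n".join(lines) + "\n"


def count_rules(pim: PIM) -> int:
    return sum(len(enumerate_contexts(pim, p.id)) for p in pim.processes)


# ---------------------------------------------------------------------------
# Scenario support: molecule knockout
# ---------------------------------------------------------------------------


def drop_molecule(pim: PIM, molecule: str) -> PIM:
    """Remove a molecule, its processes, and their influences.

    Downstream parameter tables lose the removed predecessors' columns; only
    the rows with those predecessors at 0 are kept (the removed process can
    no longer occur). Processes depending on a removed process through an
    all-or-none influence become impossible and are removed in cascade.
    """
    pim.molecule(molecule)  # raises on unknown name
    removed = {p.id for p in pim.processes if molecule in p.molecules}
    # cascade over AON dependencies
    while True:
        extra = {
            i.target
            for i in pim.influences
            if i.kind == "all_or_none" and i.source in removed
            and i.target not in removed
        }
        if not extra:
            break
        removed |= extra

    new = pim.copy()
    new.molecules = [m for m in pim.molecules if m.name != molecule]
    new.processes = [p for p in pim.processes if p.id not in removed]
    new.influences = [
        i for i in pim.influences if i.source not in removed and i.target not in removed
    ]
    new.thresholds = type(pim.thresholds)(
        pim.thresholds.t1,
        pim.thresholds.t2,
        {n: tp for n, tp in pim.thresholds.per_process.items() if n not in removed},
    )

    tables = {}
    for proc in new.processes:
        old_table = pim.tables[proc.id]
        old_free = pim.free_inputs(proc.id)
        keep_pos = [i for i, p in enumerate(old_free) if p not in removed]
        reps = 2 if proc.ptype == "homodimerization" else 1
        k = len(old_free)

        def collapse(ctx: tuple[int, ...]):
            chunks = [ctx[r * k : (r + 1) * k] for r in range(reps)]
            for chunk in chunks:
                for i, p in enumerate(old_free):
                    if p in removed and chunk[i] != 0:
                        return None
            return tuple(
                itertools.chain.from_iterable(
                    tuple(chunk[i] for i in keep_pos) for chunk in chunks
                )
            )

        rows = []
        seen = set()
        for row in old_table.rows:
            ctx = collapse(row.ctx)
            if ctx is None or ctx in seen:
                continue
            seen.add(ctx)
            rows.append(
                type(row)(ctx, row.k_fw, row.k_bw, row.y_override)
            )
        inputs = tuple(p for p, _ in new.predecessors(proc.id))
        tables[proc.id] = type(old_table)(proc.id, inputs, tuple(rows))
    new.tables = tables
    return new
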