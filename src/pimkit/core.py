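"""Domain types and structural operations for Process-Interaction-Models.

A PIM is a directed graph whose nodes are signaling *processes* (binding,
covalent modification, homodimerization, degradation) and whose edges are
kinetic *influences*: an edge ``i -> j`` states that process ``j`` occurs with
different kinetic parameters depending on whether process ``i`` has occurred.
Each process node carries a parameter table with one row per admissible
reaction context (a 0/1 assignment over its preceding processes), holding the
mass-action forward/backward rate constants for that context.

Two influence kinds exist: ``plain`` (the context merely changes the rate)
and ``all_or_none`` (AON: the target process can occur *only after* the
source has occurred, e.g. binding at a site that must first be
phosphorylated). A bidirectional interaction is stored as two plain
influences, one per direction.

This module owns validation, canonical predecessor ordering, admissible
context enumeration (including the mutual-exclusion and homodimerization
special cases) and the derived equilibrium constant.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "SiteRef",
    "MoleculeDef",
    "ProcessNode",
    "Influence",
    "ContextRow",
    "ParameterTable",
    "Thresholds",
    "PIM",
    "ValidationReport",
    "validate_pim",
    "predecessors",
    "mutually_exclusive_inputs",
    "enumerate_contexts",
    "equilibrium_constant",
    "IDENT_RE",
]

#: BNGL-safe identifier: letter followed by letters, digits or underscores.
IDENT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

PROCESS_TYPES = ("binding", "modification", "homodimerization", "degradation")
INFLUENCE_KINDS = ("plain", "all_or_none")


@dataclass(frozen=True, order=True)
class SiteRef:
    """Reference to one site of one molecule, written ``molecule.site``."""

    molecule: str
    site: str

    @classmethod
    def parse(cls, text: str) -> "SiteRef":
        mol, dot, site = text.partition(".")
        if not dot or not mol or not site:
            raise ValueError(f"site reference must be 'molecule.site', got {text!r}")
        return cls(mol, site)

    def __str__(self) -> str:
        return f"{self.molecule}.{self.site}"


@dataclass(frozen=True)
class MoleculeDef:
    """A molecule with an ordered list of interaction sites (domains)."""

    name: str
    sites: tuple[str, ...]


@dataclass(frozen=True)
class ProcessNode:
    """One reaction center, aggregating all rules that share it.

    ``assignments`` holds the affected sites: two for binding, one for
    modification and homodimerization. Degradation affects a whole molecule
    and stores it in ``molecule`` with empty ``assignments``; degradation is
    always irreversible.
    """

    id: int
    ptype: str
    assignments: tuple[SiteRef, ...] = ()
    reversible: bool = True
    molecule: str | None = None  # degradation only

    @property
    def molecules(self) -> tuple[str, ...]:
        """Molecules touched by the reaction center, in assignment order."""
        if self.ptype == "degradation":
            return (self.molecule,) if self.molecule else ()
        seen: list[str] = []
        for ref in self.assignments:
            if ref.molecule not in seen:
                seen.append(ref.molecule)
        return tuple(seen)


@dataclass(frozen=True)
class Influence:
    source: int
    target: int
    kind: str = "plain"


@dataclass(frozen=True)
class ContextRow:
    """One admissible reaction context of a process node.

    ``ctx`` assigns 0/1 to the *free* inputs of the node (predecessors that
    are not all-or-none), in canonical ascending-id order; for a
    homodimerization node the tuple concatenates the assignments of the two
    monomers. Rows excluded from the kinetic table by mutual exclusion carry
    no rates but may fix the logical output directly through ``y_override``.
    """

    ctx: tuple[int, ...]
    k_fw: float | None = None
    k_bw: float | None = None
    y_override: str | None = None  # one of "0", "1", "*"

    @property
    def is_kinetic(self) -> bool:
        return self.k_fw is not None


@dataclass(frozen=True)
class ParameterTable:
    node: int
    inputs: tuple[int, ...]  # all predecessors, ascending id
    rows: tuple[ContextRow, ...]

    def kinetic_rows(self) -> tuple[ContextRow, ...]:
        return tuple(r for r in self.rows if r.is_kinetic)

    def row_for(self, ctx: tuple[int, ...]) -> ContextRow:
        for row in self.rows:
            if row.ctx == ctx:
                return row
        raise KeyError(f"no row for context {ctx} in table of node {self.node}")


@dataclass(frozen=True)
class Thresholds:
    """Discretization cutoffs ``t1 < t2`` for k_eq (or k_fw, irreversible).

    ``per_process`` optionally overrides the global pair for individual
    process nodes, supporting per-process threshold refinement.
    """

    t1: float
    t2: float
    per_process: dict[int, tuple[float, float]] = field(default_factory=dict)

    def for_node(self, node: int) -> tuple[float, float]:
        return self.per_process.get(node, (self.t1, self.t2))


@dataclass
class PIM:
    molecules: list[MoleculeDef]
    processes: list[ProcessNode]
    influences: list[Influence]
    tables: dict[int, ParameterTable]
    thresholds: Thresholds

    # -- lookups ----------------------------------------------------------
    def process(self, node: int) -> ProcessNode:
        for p in self.processes:
            if p.id == node:
                return p
        raise KeyError(f"unknown process id {node}")

    def molecule(self, name: str) -> MoleculeDef:
        for m in self.molecules:
            if m.name == name:
                return m
        raise KeyError(f"unknown molecule {name!r}")

    def has_process(self, node: int) -> bool:
        return any(p.id == node for p in self.processes)

    # -- structure --------------------------------------------------------
    def predecessors(self, node: int) -> list[tuple[int, str]]:
        return predecessors(self, node)

    def free_inputs(self, node: int) -> tuple[int, ...]:
        """Predecessors that contribute a table column (non-AON), ascending."""
        return tuple(p for p, kind in predecessors(self, node) if kind == "plain")

    def aon_inputs(self, node: int) -> tuple[int, ...]:
        return tuple(p for p, kind in predecessors(self, node) if kind == "all_or_none")

    def copy(self) -> "PIM":
        return PIM(
            molecules=list(self.molecules),
            processes=list(self.processes),
            influences=list(self.influences),
            tables=dict(self.tables),
            thresholds=replace(
                self.thresholds, per_process=dict(self.thresholds.per_process)
            ),
        )


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------


def predecessors(pim: PIM, node: int) -> list[tuple[int, str]]:
    """All influence sources targeting ``node``, ascending id, tagged by kind."""
    pim.process(node)  # raises on unknown id
    preds = [(i.source, i.kind) for i in pim.influences if i.target == node]
    preds.sort(key=lambda t: t[0])
    return preds


def mutually_exclusive_inputs(pim: PIM, node: int) -> set[frozenset[int]]:
    """Predecessor pairs that can never have occurred on one molecule instance.

    Two preceding *binding* processes are mutually exclusive when they compete
    for a common binding site on a molecule that also carries the influenced
    process: a single instance of that molecule cannot hold both contexts at
    once. (A shared site on the *partner* molecule — e.g. one ligand species
    binding two receptor sites — involves two distinct partner copies and is
    not exclusive.)
    """
    target = pim.process(node)
    target_mols = set(target.molecules)
    preds = [pim.process(p) for p, _ in predecessors(pim, node)]
    bindings = [p for p in preds if p.ptype == "binding"]
    pairs: set[frozenset[int]] = set()
    for a, b in itertools.combinations(bindings, 2):
        shared = set(a.assignments) & set(b.assignments)
        if any(ref.molecule in target_mols for ref in shared):
            pairs.add(frozenset((a.id, b.id)))
    return pairs


def _admissible_single(pim: PIM, node: int) -> list[tuple[int, ...]]:
    """Admissible 0/1 assignments over the free inputs of ``node``."""
    free = pim.free_inputs(node)
    excl = mutually_exclusive_inputs(pim, node)
    out: list[tuple[int, ...]] = []
    for bits in itertools.product((0, 1), repeat=len(free)):
        assign = dict(zip(free, bits))
        if any(all(assign.get(p, 1) == 1 for p in pair) for pair in excl):
            continue
        out.append(bits)
    return out


def enumerate_contexts(pim: PIM, node: int) -> list[tuple[int, ...]]:
    """Deterministic list of admissible contexts for a process node.

    Contexts assign 0/1 to the free inputs (all-or-none predecessors are
    implicitly 1 and contribute no column), in binary-counting order on
    ascending predecessor ids. Assignments activating both members of a
    mutually exclusive pair are excluded. For homodimerization nodes the
    inputs are duplicated per monomer and symmetric duplicates collapsed:
    each context is the concatenation of the two per-monomer assignments
    with the lexicographically smaller monomer first.
    """
    proc = pim.process(node)
    singles = _admissible_single(pim, node)
    if proc.ptype != "homodimerization":
        return singles
    out: list[tuple[int, ...]] = []
    for i, a in enumerate(singles):
        for b in singles[i:]:
            out.append(a + b)
    return out


def equilibrium_constant(row: ContextRow) -> float:
    """k_eq = k_fw / k_bw for a reversible context row."""
    if row.k_fw is None:
        raise ValueError("row has no kinetics")
    if row.k_bw is None:
        raise ValueError("k_eq undefined for irreversible process")
    if row.k_bw == 0:
        raise ValueError("k_eq undefined: k_bw is zero")
    return row.k_fw / row.k_bw


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"error: {e}" for e in self.errors]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "ok"


def context_conflicts(src: ProcessNode, tgt: ProcessNode) -> bool:
    """True when ``src`` can never have occurred in a rule of ``tgt``.

    A preceding binding (or homodimerization) process whose only anchor on
    the target's molecules is a site the target itself is about to bind
    cannot be written as a context: the center requires that site free.
    (If the predecessor also touches a non-center site of a target molecule,
    the context is anchored there instead and no conflict arises.)
    """
    if src.ptype not in ("binding", "homodimerization"):
        return False
    if tgt.ptype not in ("binding", "homodimerization"):
        return False
    tgt_mols = set(tgt.molecules)
    anchors = [r for r in src.assignments if r.molecule in tgt_mols]
    center = set(tgt.assignments)
    return bool(anchors) and all(r in center for r in anchors)


def _expected_arity(ptype: str) -> int:
    return {"binding": 2, "modification": 1, "homodimerization": 1, "degradation": 0}[
        ptype
    ]


def validate_pim(pim: PIM) -> ValidationReport:
    """Check every structural invariant; the PIM is accepted iff no errors."""
    rep = ValidationReport()
    err, warn = rep.errors.append, rep.warnings.append

    # molecules
    if not pim.molecules:
        err("no molecules declared")
    seen_mols: set[str] = set()
    for mol in pim.molecules:
        if not IDENT_RE.match(mol.name):
            err(f"molecule name {mol.name!r} is not a valid identifier")
        if mol.name in seen_mols:
            err(f"duplicate molecule name {mol.name!r}")
        seen_mols.add(mol.name)
        seen_sites: set[str] = set()
        for s in mol.sites:
            if not IDENT_RE.match(s):
                err(f"site name {mol.name}.{s} is not a valid identifier")
            if s in seen_sites:
                err(f"duplicate site {s!r} on molecule {mol.name}")
            seen_sites.add(s)

    def site_exists(ref: SiteRef) -> bool:
        return any(
            m.name == ref.molecule and ref.site in m.sites for m in pim.molecules
        )

    # processes
    seen_ids: set[int] = set()
    for proc in pim.processes:
        if proc.id <= 0:
            err(f"process id {proc.id} is not a positive integer")
        if proc.id in seen_ids:
            err(f"duplicate process id {proc.id}")
        seen_ids.add(proc.id)
        if proc.ptype not in PROCESS_TYPES:
            err(f"process {proc.id}: unknown type {proc.ptype!r}")
            continue
        if proc.ptype == "degradation":
            if proc.molecule is None or proc.molecule not in seen_mols:
                err(f"process {proc.id}: degradation of unknown molecule")
            if proc.reversible:
                err(f"process {proc.id}: degradation is an irreversible process")
            if proc.assignments:
                err(f"process {proc.id}: degradation takes a molecule, not sites")
        else:
            if len(proc.assignments) != _expected_arity(proc.ptype):
                err(
                    f"process {proc.id}: {proc.ptype} needs "
                    f"{_expected_arity(proc.ptype)} site assignment(s)"
                )
            for ref in proc.assignments:
                if not site_exists(ref):
                    err(f"process {proc.id}: dangling site reference {ref}")
            if proc.ptype == "binding" and len(set(proc.assignments)) == 1:
                err(f"process {proc.id}: binding needs two distinct sites")

    # influences
    seen_edges: set[tuple[int, int]] = set()
    for inf in pim.influences:
        if inf.kind not in INFLUENCE_KINDS:
            err(f"influence {inf.source}->{inf.target}: unknown kind {inf.kind!r}")
        if inf.source == inf.target:
            err(f"influence {inf.source}->{inf.target}: self-loop")
        if (inf.source, inf.target) in seen_edges:
            err(f"influence {inf.source}->{inf.target}: duplicate edge")
        seen_edges.add((inf.source, inf.target))
        for end in (inf.source, inf.target):
            if end not in seen_ids:
                err(f"influence {inf.source}->{inf.target}: unknown process {end}")
    if rep.errors:
        return rep  # structure broken; later checks would cascade confusingly

    # influence expressibility: the context of a rule must be writable on a
    # molecule of the reaction center
    for inf in pim.influences:
        src, tgt = pim.process(inf.source), pim.process(inf.target)
        if src.ptype == "degradation":
            err(
                f"influence {inf.source}->{inf.target}: a degradation process "
                "cannot be a reaction context (the molecule is gone)"
            )
        elif not set(src.molecules) & set(tgt.molecules):
            err(
                f"influence {inf.source}->{inf.target}: processes share no "
                "molecule, context not expressible in a rule pattern"
            )
        elif context_conflicts(src, tgt):
            err(
                f"influence {inf.source}->{inf.target}: source competes for "
                "the target's own binding site, context not expressible"
            )

    # thresholds
    pairs = [(None, (pim.thresholds.t1, pim.thresholds.t2))] + [
        (n, tp) for n, tp in sorted(pim.thresholds.per_process.items())
    ]
    for scope, (t1, t2) in pairs:
        where = "global" if scope is None else f"process {scope}"
        if t1 <= 0 or t2 <= 0:
            err(f"thresholds ({where}): must be positive")
        if not t1 < t2:
            err(f"thresholds ({where}): not strictly ordered (t1 < t2 required)")
    for scope in pim.thresholds.per_process:
        if scope not in seen_ids:
            err(f"threshold override for unknown process {scope}")

    # parameter tables
    for proc in pim.processes:
        table = pim.tables.get(proc.id)
        if table is None:
            err(f"process {proc.id}: missing parameter table")
            continue
        expected_inputs = tuple(p for p, _ in predecessors(pim, proc.id))
        if table.inputs != expected_inputs:
            err(
                f"process {proc.id}: table inputs {table.inputs} do not match "
                f"predecessors {expected_inputs}"
            )
            continue
        admissible = set(enumerate_contexts(pim, proc.id))
        width = len(next(iter(admissible))) if admissible else 0
        kin: set[tuple[int, ...]] = set()
        for row in table.rows:
            if len(row.ctx) != width:
                err(
                    f"process {proc.id}: row context {row.ctx} has wrong width "
                    f"(expected {width})"
                )
                continue
            if any(v not in (0, 1) for v in row.ctx):
                err(f"process {proc.id}: context values must be 0/1, got {row.ctx}")
            if row.y_override is not None and row.y_override not in ("0", "1", "*"):
                err(
                    f"process {proc.id}: y override must be 0/1/*, "
                    f"got {row.y_override!r}"
                )
            if row.is_kinetic:
                if row.k_fw is not None and row.k_fw <= 0:
                    err(
                        f"process {proc.id}, context {row.ctx}: the forward rate "
                        "constant must not be zero"
                    )
                if proc.reversible and (row.k_bw is None or row.k_bw <= 0):
                    err(
                        f"process {proc.id}, context {row.ctx}: reversible process "
                        "needs a positive backward rate constant"
                    )
                if not proc.reversible and row.k_bw is not None:
                    err(
                        f"process {proc.id}, context {row.ctx}: irreversible "
                        "process must not carry a backward rate constant"
                    )
                if row.ctx in kin:
                    err(f"process {proc.id}: duplicate row for context {row.ctx}")
                kin.add(row.ctx)
                if row.ctx not in admissible:
                    err(
                        f"process {proc.id}: kinetic row for inadmissible "
                        f"context {row.ctx}"
                    )
            else:
                if row.ctx in admissible:
                    err(
                        f"process {proc.id}: row {row.ctx} is admissible and "
                        "needs kinetic parameters"
                    )
        missing = admissible - kin
        if missing:
            err(
                f"process {proc.id}: missing table rows for contexts "
                f"{sorted(missing)}"
            )

    # orphan sites are legal but suspicious
    referenced = {
        ref for proc in pim.processes for ref in proc.assignments
    }
    for mol in pim.molecules:
        for s in mol.sites:
            if SiteRef(mol.name, s) not in referenced:
                warn(f"site {mol.name}.{s} is not referenced by any process")

    return rep
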