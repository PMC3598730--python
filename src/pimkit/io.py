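"""Read/write the PIM document format (YAML) and provide model fixtures.

Document layout::

    molecules:
      - {name: R, sites: [b1, p1, p2]}
    processes:
      - {id: 1, type: binding, sites: [A.b1, R.b1], reversible: true}
      - {id: 9, type: degradation, molecule: A}
    influences:
      - {source: 1, target: 2, kind: plain}        # plain | bidirectional
      - {source: 2, target: 4, kind: all_or_none}  #       | all_or_none
    parameters:
      2:
        inputs: [1, 3]
        rows:
          - {ctx: [0, 0], kfw: 0.001, kbw: 1.0}
          - {ctx: [1, 1], y: "*"}      # mutual-exclusion row, no kinetics
    thresholds:
      t1: 0.01
      t2: 0.1
      per_process:
        4: {t1: 0.05, t2: 0.2}

``kind: bidirectional`` is sugar for two plain influences, one per
direction; parameter tables consume directed predecessors only. Row
contexts assign 0/1 to the non-all-or-none predecessors in ascending-id
order (all-or-none inputs are implicitly 1); homodimerization rows
concatenate the assignments of the two monomers. Loading canonicalizes
order (molecules by name, processes by id), so write->read round-trips to
an equal model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import yaml

from .core import (
    PIM,
    ContextRow,
    Influence,
    MoleculeDef,
    ParameterTable,
    ProcessNode,
    SiteRef,
    Thresholds,
    context_conflicts,
    enumerate_contexts,
    predecessors,
    validate_pim,
)

__all__ = [
    "read_pim",
    "write_pim",
    "load_pim",
    "save_pim",
    "build_small_example",
    "build_egf_insulin",
    "RandomPimConfig",
    "random_pim",
]


class PimFormatError(ValueError):
    """Raised when a PIM document cannot be parsed."""


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _as_row(item: dict, where: str) -> ContextRow:
    if not isinstance(item, dict) or "ctx" not in item:
        raise PimFormatError(f"{where}: row needs a 'ctx' list")
    ctx = tuple(int(v) for v in item["ctx"])
    y = item.get("y")
    return ContextRow(
        ctx=ctx,
        k_fw=float(item["kfw"]) if "kfw" in item else None,
        k_bw=float(item["kbw"]) if "kbw" in item else None,
        y_override=str(y) if y is not None else None,
    )


def read_pim(text: str) -> PIM:
    """Parse a PIM document. Semantic problems are left to ``validate_pim``."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # line context comes from PyYAML
        raise PimFormatError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise PimFormatError("document must be a mapping")

    mol_items = doc.get("molecules") or []
    if not mol_items:
        raise PimFormatError("no molecules declared")
    molecules = [
        MoleculeDef(name=str(m["name"]), sites=tuple(str(s) for s in m.get("sites", [])))
        for m in mol_items
    ]
    molecules.sort(key=lambda m: m.name)

    processes = []
    for p in doc.get("processes") or []:
        ptype = str(p.get("type", ""))
        reversible = bool(p.get("reversible", ptype != "degradation"))
        if ptype == "degradation":
            reversible = bool(p.get("reversible", False))
        processes.append(
            ProcessNode(
                id=int(p["id"]),
                ptype=ptype,
                assignments=tuple(SiteRef.parse(str(s)) for s in p.get("sites", [])),
                reversible=reversible,
                molecule=str(p["molecule"]) if "molecule" in p else None,
            )
        )
    processes.sort(key=lambda p: p.id)

    influences: list[Influence] = []
    for e in doc.get("influences") or []:
        src, tgt = int(e["source"]), int(e["target"])
        kind = str(e.get("kind", "plain"))
        if kind == "bidirectional":
            influences.append(Influence(src, tgt, "plain"))
            influences.append(Influence(tgt, src, "plain"))
        else:
            influences.append(Influence(src, tgt, kind))
    influences.sort(key=lambda i: (i.source, i.target))

    tables: dict[int, ParameterTable] = {}
    for key, spec in (doc.get("parameters") or {}).items():
        node = int(key)
        rows = tuple(
            _as_row(r, f"parameters[{node}]") for r in (spec.get("rows") or [])
        )
        tables[node] = ParameterTable(
            node=node,
            inputs=tuple(int(i) for i in spec.get("inputs", [])),
            rows=rows,
        )

    th = doc.get("thresholds") or {}
    per_process = {
        int(k): (float(v["t1"]), float(v["t2"]))
        for k, v in (th.get("per_process") or {}).items()
    }
    thresholds = Thresholds(
        t1=float(th.get("t1", 0.01)),
        t2=float(th.get("t2", 0.1)),
        per_process=per_process,
    )
    return PIM(molecules, processes, influences, tables, thresholds)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _num(x: float):
    return int(x) if float(x).is_integer() else float(x)


def write_pim(pim: PIM) -> str:
    """Serialize canonically: sorted ids, stable row order, stable keys."""
    report = validate_pim(pim)
    if not report.ok:
        raise ValueError(f"refusing to write invalid PIM:\n{report}")
    doc: dict = {}
    doc["molecules"] = [
        {"name": m.name, "sites": list(m.sites)}
        for m in sorted(pim.molecules, key=lambda m: m.name)
    ]
    procs = []
    for p in sorted(pim.processes, key=lambda p: p.id):
        entry: dict = {"id": p.id, "type": p.ptype}
        if p.ptype == "degradation":
            entry["molecule"] = p.molecule
        else:
            entry["sites"] = [str(s) for s in p.assignments]
        entry["reversible"] = p.reversible
        procs.append(entry)
    doc["processes"] = procs
    doc["influences"] = [
        {"source": i.source, "target": i.target, "kind": i.kind}
        for i in sorted(pim.influences, key=lambda i: (i.source, i.target))
    ]
    params: dict = {}
    for node in sorted(pim.tables):
        table = pim.tables[node]
        rows = []
        for row in sorted(table.rows, key=lambda r: (r.is_kinetic is False, r.ctx)):
            item: dict = {"ctx": list(row.ctx)}
            if row.k_fw is not None:
                item["kfw"] = _num(row.k_fw)
            if row.k_bw is not None:
                item["kbw"] = _num(row.k_bw)
            if row.y_override is not None:
                item["y"] = row.y_override
            rows.append(item)
        params[node] = {"inputs": list(table.inputs), "rows": rows}
    doc["parameters"] = params
    th: dict = {"t1": _num(pim.thresholds.t1), "t2": _num(pim.thresholds.t2)}
    if pim.thresholds.per_process:
        th["per_process"] = {
            n: {"t1": _num(a), "t2": _num(b)}
            for n, (a, b) in sorted(pim.thresholds.per_process.items())
        }
    doc["thresholds"] = th
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def load_pim(path) -> PIM:
    with open(path, encoding="utf-8") as fh:
        return read_pim(fh.read())


def save_pim(pim: PIM, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_pim(pim))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _table(node: int, inputs: tuple[int, ...], rows) -> ParameterTable:
    built = []
    for item in rows:
        if len(item) == 2:  # (ctx, keq) with kbw = 1
            ctx, keq = item
            built.append(ContextRow(ctx=tuple(ctx), k_fw=float(keq), k_bw=1.0))
        else:  # (ctx, None, y) override row
            ctx, _, y = item
            built.append(ContextRow(ctx=tuple(ctx), y_override=y))
    return ParameterTable(node=node, inputs=inputs, rows=tuple(built))


def build_small_example() -> PIM:
    """Four-process introductory system: A and B binding a receptor R.

    Process 1 binds A.b1 to R.b1; processes 2 and 3 phosphorylate R.p1 and
    R.p2; process 4 binds B.b1 to R.p1 and requires the prior
    phosphorylation (all-or-none). Process 2 depends on 1 and 3, processes
    2 and 3 influence each other. Rates are chosen so that, at the default
    thresholds (t1=0.01, t2=0.1), process 2 discretizes to an OR over its
    two inputs and process 3 to the identity on process 2.
    """
    molecules = [
        MoleculeDef("A", ("b1",)),
        MoleculeDef("B", ("b1",)),
        MoleculeDef("R", ("b1", "p1", "p2")),
    ]
    processes = [
        ProcessNode(1, "binding", (SiteRef("A", "b1"), SiteRef("R", "b1"))),
        ProcessNode(2, "modification", (SiteRef("R", "p1"),)),
        ProcessNode(3, "modification", (SiteRef("R", "p2"),)),
        ProcessNode(4, "binding", (SiteRef("B", "b1"), SiteRef("R", "p1"))),
    ]
    influences = [
        Influence(1, 2, "plain"),
        Influence(2, 3, "plain"),
        Influence(3, 2, "plain"),
        Influence(2, 4, "all_or_none"),
    ]
    tables = {
        1: _table(1, (), [((), 1.0)]),
        2: _table(
            2,
            (1, 3),
            [((0, 0), 0.001), ((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), 2.0)],
        ),
        3: _table(3, (2,), [((0,), 0.001), ((1,), 1.0)]),
        4: _table(4, (2,), [((), 1.0)]),
    }
    influences.sort(key=lambda i: (i.source, i.target))
    return PIM(molecules, processes, influences, tables, Thresholds(0.01, 0.1))


def build_egf_insulin() -> PIM:
    """18-process PIM of the early EGF/insulin receptor crosstalk.

    Synthetic reconstruction of the published crosstalk network: the original
    per-rule kinetic constants are not reprinted here, so the tables carry
    representative equilibrium constants from the ladder {0.001, 0.01, 0.1,
    0.25, 1} chosen to realize the documented qualitative structure:

    * the two insulin-binding processes (1, 2) influence each other and both
      receptor phosphorylation processes (3, 4);
    * Shc and IRS dock onto phosphorylated receptor sites (all-or-none);
    * Shc is phosphorylated after binding either receptor (crosstalk), Grb2
      binds phospho-Shc; Grb2 is also recruited to both phospho-IRS sites
      through one SH2 site (the shared-site special case);
    * EGF binding and EGFR homodimerization influence each other;
      receptor phosphorylation requires the dimer.

    At thresholds t1=0.01/t2=0.1 this yields the reference logical model M.
    Raising to 0.1/0.25 makes dimerization necessary for EGF binding and the
    two insulin sites mutually inhibiting; lowering to 0.001/0.01 removes
    the binding requirement from the IRS/Shc phosphorylation processes.
    """
    molecules = [
        MoleculeDef("egf", ("b1",)),
        MoleculeDef("egfr", ("b_egf", "d1", "p1", "p2")),
        MoleculeDef("grb2", ("b_shc", "b_irs", "b_egfr")),
        MoleculeDef("ins", ("b1",)),
        MoleculeDef("ir", ("b_ins", "b_ins2", "p1", "p2")),
        MoleculeDef("irs", ("b_ir", "p1", "p2")),
        MoleculeDef("shc", ("b_ir", "b_egfr", "p1")),
    ]
    S = SiteRef
    processes = [
        ProcessNode(1, "binding", (S("ins", "b1"), S("ir", "b_ins"))),
        ProcessNode(2, "binding", (S("ins", "b1"), S("ir", "b_ins2"))),
        ProcessNode(3, "modification", (S("ir", "p1"),)),
        ProcessNode(4, "modification", (S("ir", "p2"),)),
        ProcessNode(5, "binding", (S("shc", "b_ir"), S("ir", "p1"))),
        ProcessNode(6, "binding", (S("irs", "b_ir"), S("ir", "p2"))),
        ProcessNode(7, "modification", (S("irs", "p1"),)),
        ProcessNode(8, "binding", (S("grb2", "b_irs"), S("irs", "p1"))),
        ProcessNode(9, "modification", (S("shc", "p1"),)),
        ProcessNode(10, "binding", (S("grb2", "b_shc"), S("shc", "p1"))),
        ProcessNode(11, "binding", (S("egf", "b1"), S("egfr", "b_egf"))),
        ProcessNode(12, "homodimerization", (S("egfr", "d1"),)),
        ProcessNode(13, "modification", (S("egfr", "p1"),)),
        ProcessNode(14, "binding", (S("shc", "b_egfr"), S("egfr", "p1"))),
        ProcessNode(15, "modification", (S("egfr", "p2"),)),
        ProcessNode(16, "binding", (S("grb2", "b_egfr"), S("egfr", "p2"))),
        ProcessNode(17, "modification", (S("irs", "p2"),)),
        ProcessNode(18, "binding", (S("grb2", "b_irs"), S("irs", "p2"))),
    ]
    influences = [
        Influence(1, 2, "plain"),
        Influence(2, 1, "plain"),
        Influence(1, 3, "plain"),
        Influence(2, 3, "plain"),
        Influence(1, 4, "plain"),
        Influence(2, 4, "plain"),
        Influence(3, 5, "all_or_none"),
        Influence(4, 6, "all_or_none"),
        Influence(6, 7, "plain"),
        Influence(7, 8, "all_or_none"),
        Influence(5, 9, "plain"),
        Influence(14, 9, "plain"),
        Influence(9, 10, "all_or_none"),
        Influence(11, 12, "plain"),
        Influence(12, 11, "plain"),
        Influence(12, 13, "plain"),
        Influence(13, 14, "all_or_none"),
        Influence(12, 15, "plain"),
        Influence(15, 16, "all_or_none"),
        Influence(6, 17, "plain"),
        Influence(17, 18, "all_or_none"),
    ]
    tables = {
        1: _table(1, (2,), [((0,), 1.0), ((1,), 0.1)]),
        2: _table(2, (1,), [((0,), 1.0), ((1,), 0.1)]),
        3: _table(
            3,
            (1, 2),
            [((0, 0), 0.001), ((0, 1), 0.25), ((1, 0), 0.25), ((1, 1), 1.0)],
        ),
        4: _table(
            4,
            (1, 2),
            [((0, 0), 0.001), ((0, 1), 0.25), ((1, 0), 0.25), ((1, 1), 1.0)],
        ),
        5: _table(5, (3,), [((), 1.0)]),
        6: _table(6, (4,), [((), 1.0)]),
        7: _table(7, (6,), [((0,), 0.01), ((1,), 1.0)]),
        8: _table(8, (7,), [((), 1.0)]),
        9: _table(
            9,
            (5, 14),
            [((0, 0), 0.01), ((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), 1.0)],
        ),
        10: _table(10, (9,), [((), 1.0)]),
        11: _table(11, (12,), [((0,), 0.1), ((1,), 1.0)]),
        12: _table(
            12, (11,), [((0, 0), 0.001), ((0, 1), 0.25), ((1, 1), 1.0)]
        ),
        13: _table(13, (12,), [((0,), 0.001), ((1,), 1.0)]),
        14: _table(14, (13,), [((), 1.0)]),
        15: _table(15, (12,), [((0,), 0.001), ((1,), 1.0)]),
        16: _table(16, (15,), [((), 1.0)]),
        17: _table(17, (6,), [((0,), 0.01), ((1,), 1.0)]),
        18: _table(18, (17,), [((), 1.0)]),
    }
    influences.sort(key=lambda i: (i.source, i.target))
    return PIM(molecules, processes, influences, tables, Thresholds(0.01, 0.1))


# ---------------------------------------------------------------------------
# Random generator for property tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomPimConfig:
    seed: int
    n_molecules: int = 4
    n_processes: int = 7
    edge_prob: float = 0.45
    max_free_inputs: int = 4
    allow_special: bool = True  # homodimerization / degradation nodes

    def __post_init__(self):
        if self.n_molecules < 2 or self.n_processes < 1:
            raise ValueError("infeasible random-PIM configuration")


_KEQ_LADDER = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 10.0)


def random_pim(config: RandomPimConfig) -> PIM:
    """Reproducible random PIM honoring every structural invariant.

    All-or-none influences are only placed from a modification process onto a
    binding process whose bound site is exactly the modified site; plain
    influences only between processes sharing a molecule (so every context
    stays expressible as a rule pattern). Mutual-exclusion rows of the
    kinetic tables are sometimes given explicit logical overrides.
    """
    rng = random.Random(config.seed)
    mols = [f"M{i}" for i in range(config.n_molecules)]
    sites: dict[str, list[str]] = {m: [] for m in mols}

    def new_site(mol: str, prefix: str) -> str:
        name = f"{prefix}{len(sites[mol])}"
        sites[mol].append(name)
        return name

    processes: list[ProcessNode] = []
    mod_of: dict[SiteRef, int] = {}  # modified site -> modification process id
    used_mod_sites: set[SiteRef] = set()
    for pid in range(1, config.n_processes + 1):
        kinds = ["binding", "modification"]
        if config.allow_special:
            kinds += ["homodimerization", "degradation"]
        weights = [4, 4, 1, 1][: len(kinds)]
        ptype = rng.choices(kinds, weights=weights)[0]
        if ptype == "modification":
            mol = rng.choice(mols)
            ref = SiteRef(mol, new_site(mol, "p"))
            processes.append(ProcessNode(pid, "modification", (ref,)))
            mod_of[ref] = pid
            used_mod_sites.add(ref)
        elif ptype == "binding":
            a, b = rng.sample(mols, 2)
            # sometimes bind at an existing modification site (AON candidate)
            mod_sites_b = [r for r in mod_of if r.molecule == b]
            if mod_sites_b and rng.random() < 0.5:
                ref_b = rng.choice(mod_sites_b)
            else:
                ref_b = SiteRef(b, new_site(b, "b"))
            ref_a = SiteRef(a, new_site(a, "b"))
            processes.append(ProcessNode(pid, "binding", (ref_a, ref_b)))
        elif ptype == "homodimerization":
            mol = rng.choice(mols)
            ref = SiteRef(mol, new_site(mol, "d"))
            processes.append(ProcessNode(pid, "homodimerization", (ref,)))
        else:
            mol = rng.choice(mols)
            processes.append(
                ProcessNode(pid, "degradation", (), reversible=False, molecule=mol)
            )

    influences: list[Influence] = []
    edge_set: set[tuple[int, int]] = set()
    free_count: dict[int, int] = {p.id: 0 for p in processes}

    def add_edge(src: int, tgt: int, kind: str) -> None:
        if src == tgt or (src, tgt) in edge_set:
            return
        influences.append(Influence(src, tgt, kind))
        edge_set.add((src, tgt))
        if kind == "plain":
            free_count[tgt] += 1

    # AON edges: modification -> binding at the modified site
    for proc in processes:
        if proc.ptype != "binding":
            continue
        for ref in proc.assignments:
            if ref in mod_of and rng.random() < 0.8:
                add_edge(mod_of[ref], proc.id, "all_or_none")

    # plain edges between molecule-sharing processes
    pairs = [
        (a, b)
        for a in processes
        for b in processes
        if a.id != b.id
        and a.ptype != "degradation"
        and set(a.molecules) & set(b.molecules)
        and not context_conflicts(a, b)
    ]
    rng.shuffle(pairs)
    for a, b in pairs:
        weight = 2 if b.ptype == "homodimerization" else 1
        if free_count[b.id] + weight > config.max_free_inputs:
            continue
        if rng.random() < config.edge_prob:
            add_edge(a.id, b.id, "plain")
    influences.sort(key=lambda i: (i.source, i.target))

    thresholds = Thresholds(0.01, 0.1)
    pim = PIM(list(mols_defs(mols, sites)), processes, influences, {}, thresholds)
    for proc in processes:
        ctxs = enumerate_contexts(pim, proc.id)
        rows = []
        for ctx in ctxs:
            kfw = rng.choice(_KEQ_LADDER)
            rows.append(
                ContextRow(
                    ctx=ctx,
                    k_fw=kfw,
                    k_bw=1.0 if proc.reversible else None,
                )
            )
        # logical overrides for mutual-exclusion rows
        if proc.ptype != "homodimerization":
            free = pim.free_inputs(proc.id)
            admissible = set(ctxs)
            import itertools as _it

            for bits in _it.product((0, 1), repeat=len(free)):
                if bits not in admissible and rng.random() < 0.5:
                    rows.append(
                        ContextRow(bits, y_override=rng.choice(("0", "1", "*")))
                    )
        inputs = tuple(p for p, _ in predecessors(pim, proc.id))
        pim.tables[proc.id] = ParameterTable(proc.id, inputs, tuple(rows))
    return pim


def mols_defs(mols: list[str], sites: dict[str, list[str]]):
    for m in mols:
        yield MoleculeDef(m, tuple(sites[m]) or ("s0",))
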