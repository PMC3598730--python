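import pytest

from pimkit import build_egf_insulin, build_small_example
from pimkit.core import (
    PIM,
    ContextRow,
    Influence,
    MoleculeDef,
    ParameterTable,
    ProcessNode,
    SiteRef,
    Thresholds,
)


@pytest.fixture
def small():
    return build_small_example()


@pytest.fixture
def egf_insulin():
    return build_egf_insulin()


def _rows(node, inputs, entries):
    rows = []
    for item in entries:
        if len(item) == 2:
            ctx, keq = item
            rows.append(ContextRow(tuple(ctx), k_fw=float(keq), k_bw=1.0))
        else:
            ctx, _, y = item
            rows.append(ContextRow(tuple(ctx), y_override=y))
    return ParameterTable(node, tuple(inputs), tuple(rows))


@pytest.fixture
def competing_binders():
    """Two ligands competing for one receptor site, both influencing a third
    binding process (the mutual-exclusion constellation)."""
    molecules = [
        MoleculeDef("A", ("b1",)),
        MoleculeDef("B", ("b1",)),
        MoleculeDef("C", ("b1",)),
        MoleculeDef("R", ("b1", "b2")),
    ]
    processes = [
        ProcessNode(1, "binding", (SiteRef("A", "b1"), SiteRef("R", "b1"))),
        ProcessNode(2, "binding", (SiteRef("B", "b1"), SiteRef("R", "b1"))),
        ProcessNode(3, "binding", (SiteRef("C", "b1"), SiteRef("R", "b2"))),
    ]
    influences = [Influence(1, 3, "plain"), Influence(2, 3, "plain")]
    tables = {
        1: _rows(1, (), [((), 1.0)]),
        2: _rows(2, (), [((), 1.0)]),
        3: _rows(
            3,
            (1, 2),
            [((0, 0), 0.001), ((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), None, "1")],
        ),
    }
    return PIM(molecules, processes, influences, tables, Thresholds(0.01, 0.1))


@pytest.fixture
def double_docking():
    """One molecule binding two previously phosphorylated sites through a
    single site: forces the auxiliary L-node."""
    molecules = [MoleculeDef("A", ("b1",)), MoleculeDef("R", ("p1", "p2"))]
    processes = [
        ProcessNode(1, "modification", (SiteRef("R", "p1"),)),
        ProcessNode(2, "modification", (SiteRef("R", "p2"),)),
        ProcessNode(3, "binding", (SiteRef("A", "b1"), SiteRef("R", "p1"))),
        ProcessNode(4, "binding", (SiteRef("A", "b1"), SiteRef("R", "p2"))),
    ]
    influences = [Influence(1, 3, "all_or_none"), Influence(2, 4, "all_or_none")]
    tables = {
        1: _rows(1, (), [((), 1.0)]),
        2: _rows(2, (), [((), 1.0)]),
        3: _rows(3, (1,), [((), 1.0)]),
        4: _rows(4, (2,), [((), 1.0)]),
    }
    return PIM(molecules, processes, influences, tables, Thresholds(0.01, 0.1))


@pytest.fixture
def dimerizer():
    """Receptor whose homodimerization is influenced by phosphorylation."""
    molecules = [MoleculeDef("A", ("p1", "d1"))]
    processes = [
        ProcessNode(1, "modification", (SiteRef("A", "p1"),)),
        ProcessNode(2, "homodimerization", (SiteRef("A", "d1"),)),
    ]
    influences = [Influence(1, 2, "plain")]
    tables = {
        1: _rows(1, (), [((), 1.0)]),
        2: _rows(2, (1,), [((0, 0), 0.001), ((0, 1), 0.05), ((1, 1), 1.0)]),
    }
    return PIM(molecules, processes, influences, tables, Thresholds(0.01, 0.1))


@pytest.fixture
def ubiquitin_degradation():
    """Degradation of A gated by its prior ubiquitination."""
    molecules = [MoleculeDef("A", ("b1", "u")), MoleculeDef("R", ("b1",))]
    processes = [
        ProcessNode(1, "binding", (SiteRef("A", "b1"), SiteRef("R", "b1"))),
        ProcessNode(2, "modification", (SiteRef("A", "u"),)),
        ProcessNode(
            3, "degradation", (), reversible=False, molecule="A"
        ),
    ]
    influences = [Influence(2, 3, "plain")]
    tables = {
        1: _rows(1, (), [((), 1.0)]),
        2: _rows(2, (), [((), 1.0)]),
        3: ParameterTable(
            3,
            (2,),
            (
                ContextRow((0,), k_fw=0.001),
                ContextRow((1,), k_fw=1.0),
            ),
        ),
    }
    return PIM(molecules, processes, influences, tables, Thresholds(0.01, 0.1))
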