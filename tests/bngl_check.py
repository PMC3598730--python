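"""Minimal BNGL grammar checker used as an in-repo export oracle.

Validates block structure, parameter references, molecule/site declarations
and bond pairing; returns parsed rules for structural assertions. This is a
checker for the subset of BNGL the generator emits, not a full parser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

MOL_RE = re.compile(r"^([A-Za-z]\w*)\(([^()]*)\)$")
COMP_RE = re.compile(r"^([A-Za-z]\w*)(~[A-Za-z0-9]+)?(!\d+)?$")
PARAM_RE = re.compile(r"^([A-Za-z]\w*)\s+([0-9.eE+-]+)$")


@dataclass
class ParsedMolecule:
    name: str
    comps: list  # (site, state|None, bond|None)


def parse_pattern(text: str) -> list[list[ParsedMolecule]]:
    """'A(x!1).B(y!1) + C(z)' -> list of complexes of molecules."""
    complexes = []
    for chunk in text.split(" + "):
        mols = []
        for token in chunk.split("."):
            m = MOL_RE.match(token.strip())
            assert m, f"bad molecule pattern: {token!r}"
            comps = []
            body = m.group(2)
            if body:
                for comp in body.split(","):
                    c = COMP_RE.match(comp)
                    assert c, f"bad component: {comp!r} in {token!r}"
                    comps.append(
                        (
                            c.group(1),
                            c.group(2)[1:] if c.group(2) else None,
                            int(c.group(3)[1:]) if c.group(3) else None,
                        )
                    )
            mols.append(ParsedMolecule(m.group(1), comps))
        complexes.append(mols)
    return complexes


@dataclass
class ParsedRule:
    lhs: str
    rhs: str
    reversible: bool
    rates: list[str]


def check_bngl(text: str) -> list[ParsedRule]:
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    assert lines[0] == "begin model" and lines[-1] == "end model"

    blocks: dict[str, list[str]] = {}
    current = None
    for ln in lines[1:-1]:
        if ln.startswith("begin "):
            current = ln[6:]
            blocks[current] = []
        elif ln.startswith("end "):
            assert current == ln[4:], f"mismatched block end: {ln}"
            current = None
        else:
            assert current is not None, f"content outside block: {ln}"
            blocks[current].append(ln)
    for required in ("parameters", "molecule types", "seed species",
                     "reaction rules"):
        assert required in blocks, f"missing block {required}"

    params = {}
    for ln in blocks["parameters"]:
        m = PARAM_RE.match(ln)
        assert m, f"bad parameter line: {ln!r}"
        params[m.group(1)] = float(m.group(2))

    types: dict[str, dict[str, bool]] = {}  # molecule -> site -> has states
    for ln in blocks["molecule types"]:
        m = MOL_RE.match(ln)
        assert m, f"bad molecule type: {ln!r}"
        sites = {}
        if m.group(2):
            for comp in m.group(2).split(","):
                name, _, states = comp.partition("~")
                sites[name] = bool(states)
        types[m.group(1)] = sites

    def check_pattern(text: str, allow_zero=False):
        if allow_zero and text == "0":
            return []
        complexes = parse_pattern(text)
        bonds: dict[int, int] = {}
        for cplx in complexes:
            for mol in cplx:
                assert mol.name in types, f"undeclared molecule {mol.name}"
                for site, state, bond in mol.comps:
                    assert site in types[mol.name], (
                        f"undeclared site {mol.name}.{site}"
                    )
                    if state is not None:
                        assert types[mol.name][site], (
                            f"state on stateless site {mol.name}.{site}"
                        )
                    if bond is not None:
                        bonds[bond] = bonds.get(bond, 0) + 1
        for label, count in bonds.items():
            assert count == 2, f"bond !{label} appears {count} times"
        return complexes

    for ln in blocks["seed species"]:
        body = ln.split("#")[0].strip()
        pattern, conc = body.rsplit(" ", 1)
        float(conc)
        check_pattern(pattern.strip())

    rules = []
    for ln in blocks["reaction rules"]:
        arrow = "<->" if "<->" in ln else "->"
        lhs, rest = ln.split(arrow)
        tokens = rest.strip().split()
        n_rates = 2 if arrow == "<->" else 1
        rhs = " ".join(tokens[:-n_rates]).rstrip(",")
        rates = [t.rstrip(",") for t in tokens[-n_rates:]]
        for rate in rates:
            base = rate.split("*")[-1]
            assert base in params, f"undeclared rate parameter {base!r}"
        check_pattern(lhs.strip())
        check_pattern(rhs.strip(), allow_zero=True)
        rules.append(
            ParsedRule(lhs.strip(), rhs.strip(), arrow == "<->", rates)
        )
    return rules
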