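"""Quine-McCluskey two-level minimization with don't-care support.

Used to turn the 0/1 rows of a discretized parameter table into a minimal
disjunctive normal form. Implicants are tuples over the variables with
entries 0, 1 or None (variable eliminated). Exact cover: essential prime
implicants first, then the smallest completing subset of the remaining
primes (tables here are small; at most ten inputs are supported).
"""

from __future__ import annotations

__all__ = ["minimize", "implicant_covers"]

Implicant = tuple  # of 0 | 1 | None


def implicant_covers(imp: Implicant, minterm: tuple[int, ...]) -> bool:
    return all(b is None or b == v for b, v in zip(imp, minterm))


def _combine(a: tuple[int, int], b: tuple[int, int], n: int):
    """Merge (bits, mask) pairs differing in exactly one cared-about bit."""
    bits_a, mask_a = a
    bits_b, mask_b = b
    if mask_a != mask_b:
        return None
    diff = bits_a ^ bits_b
    if diff and diff & (diff - 1) == 0 and not diff & mask_a:
        return (bits_a & ~diff, mask_a | diff)
    return None


def _to_tuple(bits: int, mask: int, n: int) -> Implicant:
    out = []
    for i in reversed(range(n)):
        if mask >> i & 1:
            out.append(None)
        else:
            out.append(bits >> i & 1)
    return tuple(out)


def minimize(
    n: int,
    minterms: list[tuple[int, ...]],
    dontcares: list[tuple[int, ...]] = (),
) -> list[Implicant]:
    """Minimal sum-of-products covering ``minterms``, free over ``dontcares``.

    Returns a deterministically ordered list of implicants; an empty list is
    the constant-false function, a single all-None implicant constant true.
    """
    if n > 10:
        raise ValueError("minimization supported for at most 10 inputs")
    if not minterms:
        return []
    mt = sorted({sum(v << i for i, v in enumerate(reversed(m))) for m in minterms})
    dc = sorted({sum(v << i for i, v in enumerate(reversed(m))) for m in dontcares})
    dc = [d for d in dc if d not in set(mt)]
    if len(mt) + len(dc) == 1 << n:
        return [tuple([None] * n)] if n else [()]
    if n == 0:
        return [()]

    current = {(m, 0) for m in mt + dc}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        items = sorted(current)
        by_count: dict[int, list[tuple[int, int]]] = {}
        for item in items:
            by_count.setdefault(bin(item[0]).count("1"), []).append(item)
        for c in sorted(by_count):
            for a in by_count[c]:
                for b in by_count.get(c + 1, ()):
                    combo = _combine(a, b, n)
                    if combo is not None:
                        merged.add(combo)
                        used.add(a)
                        used.add(b)
        primes |= current - used
        current = merged

    # cover table over the required minterms only
    prime_list = sorted(primes)

    def covers(p: tuple[int, int], m: int) -> bool:
        bits, mask = p
        return (m & ~mask) == bits

    chart = {m: frozenset(p for p in prime_list if covers(p, m)) for m in mt}
    chosen: list[tuple[int, int]] = []
    uncovered = set(mt)
    # essential primes: minterms covered by a single prime
    changed = True
    while changed and uncovered:
        changed = False
        for m in sorted(uncovered):
            cands = [p for p in chart[m] if p not in chosen]
            if len(cands) == 1:
                p = cands[0]
                chosen.append(p)
                uncovered -= {mm for mm in uncovered if covers(p, mm)}
                changed = True
                break
    if uncovered:
        chosen.extend(_branch_cover(uncovered, chart, covers))
    return [_to_tuple(bits, mask, n) for bits, mask in sorted(set(chosen))]


def _branch_cover(uncovered, chart, covers, _node_budget=20000):
    """Minimum-cardinality prime cover by branch and bound.

    Branches on the minterm with the fewest covering primes; falls back to a
    greedy completion if the (generous) node budget runs out.
    """
    best: list | None = None
    budget = [_node_budget]

    def greedy(unc):
        out = []
        unc = set(unc)
        while unc:
            counts: dict = {}
            for m in unc:
                for p in chart[m]:
                    counts[p] = counts.get(p, 0) + 1
            p = max(sorted(counts), key=lambda q: counts[q])
            out.append(p)
            unc = {m for m in unc if not covers(p, m)}
        return out

    def recurse(unc, acc):
        nonlocal best
        if best is not None and len(acc) >= len(best):
            return
        if not unc:
            best = list(acc)
            return
        if budget[0] <= 0:
            cand = acc + greedy(unc)
            if best is None or len(cand) < len(best):
                best = cand
            return
        budget[0] -= 1
        m = min(unc, key=lambda mm: (len(chart[mm]), mm))
        for p in sorted(chart[m]):
            recurse({mm for mm in unc if not covers(p, mm)}, acc + [p])

    recurse(set(uncovered), [])
    return best
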