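"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's algorithms: residue matching by a
full-table scan, chain enumeration without maximality shortcuts, longest
path by exhaustive simple-path enumeration, and MIC by scanning every
concentration suffix.
"""

from __future__ import annotations

import itertools


def brute_match(delta: float, tol: float, labels: dict[str, float]) -> list[tuple[str, float]]:
    """Full scan of the (merged-label) residue table, sorted like the package."""
    hits = [(lab, abs(delta - m)) for lab, m in labels.items() if abs(delta - m) <= tol]
    coreport = {"Gln", "Lys"}
    if any(lab in coreport for lab, _ in hits):
        for lab in coreport:
            if lab in labels and lab not in [h[0] for h in hits]:
                hits.append((lab, abs(delta - labels[lab])))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def brute_chains(
    mzs: list[float], spacing: float, tol: float, min_length: int
) -> set[tuple[float, ...]]:
    """All maximal near-equally-spaced chains, by exhaustive path enumeration."""
    mzs = sorted(mzs)
    ok = lambda a, b: abs((b - a) - spacing) <= tol

    paths: set[tuple[float, ...]] = set()

    def grow(path: tuple[float, ...]) -> None:
        extended = False
        for m in mzs:
            if m > path[-1] and ok(path[-1], m):
                grow(path + (m,))
                extended = True
        if not extended:
            paths.add(path)

    for a, b in itertools.combinations(mzs, 2):
        if ok(a, b):
            # only start from pairs with no valid predecessor -> maximal starts
            if not any(m < a and ok(m, a) for m in mzs):
                grow((a, b))
    chains = {p for p in paths if len(p) >= min_length}
    return {
        c
        for c in chains
        if not any(c != d and _contig_sub(c, d) for d in chains)
    }


def _contig_sub(short: tuple[float, ...], long: tuple[float, ...]) -> bool:
    return len(short) < len(long) and any(
        long[i : i + len(short)] == short for i in range(len(long) - len(short) + 1)
    )


def brute_longest_path(
    nodes: dict[float, float], edges: set[tuple[float, float]]
) -> tuple[float, ...]:
    """Best path by enumerating every simple path (nodes: mz -> intensity).

    Ranking mirrors the documented tie-breaks: most rungs, then total
    intensity, then lower starting m/z, then lexicographically smaller rungs.
    """
    succ: dict[float, list[float]] = {u: [] for u in nodes}
    for u, v in edges:
        succ[u].append(v)
    all_paths: list[tuple[float, ...]] = []

    def walk(path: tuple[float, ...]) -> None:
        all_paths.append(path)
        for v in succ[path[-1]]:
            walk(path + (v,))

    for u in nodes:
        walk((u,))
    candidates = [p for p in all_paths if len(p) >= 2]
    if not candidates:
        return ()
    key = lambda p: (
        len(p),
        sum(nodes[m] for m in p),
        -p[0],
        tuple(-m for m in p),
    )
    return max(candidates, key=key)


def brute_mic(rows: list[tuple[float, bool]]):
    """Lowest concentration c with no growth in any row of concentration >= c."""
    best = None
    for c, _ in rows:
        if all(not growth for conc, growth in rows if conc >= c):
            if best is None or c < best:
                best = c
    return best
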