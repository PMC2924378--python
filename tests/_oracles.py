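"""Brute-force oracles, independent of the package's graph algorithms.

These work directly on a {child: [parents]} adjacency map and enumerate
ancestors by exhaustive upward recursion, so they share no code with the
BFS-based implementation they cross-check.
"""

from __future__ import annotations


def ancestors_by_paths(parent_map: dict[str, list[str]], term: str) -> dict[str, int]:
    """Minimal distance to every ancestor via exhaustive upward recursion."""
    memo: dict[str, dict[str, int]] = {}

    def walk(t: str) -> dict[str, int]:
        if t in memo:
            return memo[t]
        dists = {t: 0}
        for p in parent_map.get(t, ()):
            for anc, d in walk(p).items():
                cand = d + 1
                if anc not in dists or cand < dists[anc]:
                    dists[anc] = cand
        memo[t] = dists
        return dists

    return walk(term)


def pair_distance_bruteforce(
    parent_map: dict[str, list[str]], a: str, b: str
) -> int | None:
    """Min over every common ancestor of the summed upward distances."""
    da = ancestors_by_paths(parent_map, a)
    db = ancestors_by_paths(parent_map, b)
    common = set(da) & set(db)
    if not common:
        return None
    return min(da[c] + db[c] for c in common)


def parent_map_of(graph) -> dict[str, list[str]]:
    """Extract {child: [parents]} from an OntologyGraph's records."""
    return {t: [p for p, _ in rec.parents] for t, rec in graph.records.items()}
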