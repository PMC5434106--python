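"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (enumeration,
naive dynamic programming, path sums on explicit trees) and share no code
with the package internals they check.
"""

from __future__ import annotations

import itertools

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
       "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
       "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def expand_degenerate(seq: str) -> list[str]:
    return ["".join(p) for p in itertools.product(*[IUPAC[c] for c in seq])]


def sites_by_expansion(probe: str, target: str) -> list[int]:
    """All 1-based start positions via full expansion + exact substring search."""
    hits: set[int] = set()
    for variant in expand_degenerate(probe):
        start = 0
        while True:
            i = target.find(variant, start)
            if i < 0:
                break
            hits.add(i + 1)
            start = i + 1
    return sorted(hits)


def gotoh_score(a: str, b: str, match: int = 1, mismatch: int = -1,
                gap_open: int = -2, gap_extend: int = -1) -> float:
    """Optimal global affine-gap alignment score by straightforward DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with positive edge lengths.

    Returns ``(leaves, edges)`` where edges is a list of ``(u, v, length)``
    over string node names; leaves are ``L0..L{n-1}``.
    """
    def elen() -> float:
        return float(rng.uniform(0.01, 1.0))

    edges: list[tuple[str, str, float]] = [
        ("I0", "L0", elen()), ("I0", "L1", elen()), ("I0", "L2", elen())
    ]
    n_internal = 1
    for k in range(3, n_taxa):
        ei = int(rng.integers(0, len(edges)))
        u, v, w = edges.pop(ei)
        new_i = f"I{n_internal}"
        n_internal += 1
        f = float(rng.uniform(0.2, 0.8))
        edges.append((u, new_i, w * f))
        edges.append((new_i, v, w * (1 - f)))
        edges.append((new_i, f"L{k}", elen()))
    leaves = [f"L{i}" for i in range(n_taxa)]
    return leaves, edges


def tree_distances(leaves: list[str], edges: list[tuple[str, str, float]]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix computed by BFS over the explicit tree."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((len(leaves), len(leaves)))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return (D + D.T) / 2.0  # exact symmetry despite float path-sum order


def tree_splits_with_lengths(
    leaves: list[str], edges: list[tuple[str, str, float]]
) -> dict:
    """Map every edge to its bipartition: internal edges keyed by the
    canonical pair of leaf sets, leaf edges keyed by ``("tip", name)``."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    universe = frozenset(leaves)

    def side(u: str, v: str) -> frozenset[str]:
        # leaves reachable from v without crossing the edge (u, v)
        seen = {u, v}
        stack = [v]
        found = set()
        while stack:
            node = stack.pop()
            if node in universe:
                found.add(node)
            for nbr, _ in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(found)

    out = {}
    for u, v, w in edges:
        if v in universe:
            out[("tip", v)] = w
        elif u in universe:
            out[("tip", u)] = w
        else:
            s = side(u, v)
            out[frozenset([s, universe - s])] = w
    return out


def nj_tree_splits_with_lengths(tree) -> dict:
    """Same keying as :func:`tree_splits_with_lengths` for an skbio NJ tree."""
    universe = frozenset(t.name for t in tree.tips())
    out = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            out[("tip", node.name)] = node.length
        else:
            s = frozenset(t.name for t in node.tips())
            out[frozenset([s, universe - s])] = node.length
    return out
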