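"""Distance-based phylogenetics: Jukes-Cantor distances, neighbor joining with
bootstrap bipartition support, and the type-strain monophyly rule used to
validate genus membership.

Trees are :class:`skbio.TreeNode` objects.  The NJ tree is unrooted and is
represented with a trifurcating root; internal nodes carry a ``support``
attribute (percentage of bootstrap replicates containing the same
bipartition) once :func:`bootstrap_support` has run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core_io import MultipleAlignment

__all__ = [
    "CladeReport",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "check_monophyly",
    "tree_to_newick",
]

log = logging.getLogger(__name__)


def distance_matrix(
    aln: MultipleAlignment,
    correction: str = "jukes_cantor",
) -> DistanceMatrix:
    """Pairwise distances (substitutions per site) from an alignment.

    Columns where either sequence of a pair has a gap are excluded pairwise
    (pairwise deletion).  ``correction="none"`` gives the p-distance
    (mismatches / compared columns); ``"jukes_cantor"`` applies
    d = -(3/4) ln(1 - 4p/3), which diverges as p -> 0.75, so saturated pairs
    (p >= 0.75) raise rather than silently producing infinities.
    """
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(aln) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    mat = np.array([list(r) for r in aln.rows])
    nongap = mat != "-"
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            ncols = int(both.sum())
            if ncols == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            p = float((mat[i, both] != mat[j, both]).sum()) / ncols
            if correction == "jukes_cantor":
                if p >= 0.75:
                    raise ValueError(
                        f"saturated pair {aln.ids[i]!r}/{aln.ids[j]!r}: "
                        f"p-distance {p:.3f} >= 0.75 not correctable"
                    )
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=list(aln.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie handling.

    At each step the pair minimizing the Q-criterion is joined; ties are
    broken by the lexicographically smallest index pair (i, j) in the current
    working order.  Negative estimated branch lengths are clamped to zero
    with the deficit moved to the sister branch, preserving the pair's summed
    length.  The returned tree is unrooted (trifurcating root).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        # argmin over the upper triangle in row-major order implements the
        # smallest-(i, j) tie-break
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp(li, lj)
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent.append(ni)
        parent.append(nj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    # final star join of the three remaining nodes
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    root = TreeNode()
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = float(max(length, 0.0))
        root.append(node)
    root.length = None
    return root


def _leafset(node: TreeNode) -> frozenset[str]:
    if node.is_tip():
        return frozenset([node.name])
    return frozenset(t.name for t in node.tips())


def _internal_splits(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Map each non-trivial bipartition (as the child-side leaf set) to its node."""
    universe = _leafset(tree)
    splits: dict[frozenset[str], TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        s = _leafset(node)
        if 1 < len(s) < len(universe) - 1:
            splits[s] = node
    return splits


def _canonical_splits(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    universe = _leafset(tree)
    out = set()
    for s in _internal_splits(tree):
        out.add(frozenset([s, universe - s]))
    return out


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 100,
    seed: int | None = None,
    correction: str = "jukes_cantor",
) -> TreeNode:
    """NJ tree of the full alignment with per-edge bootstrap support.

    Alignment columns are resampled with replacement ``n_reps`` times; support
    of each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition.  With ``n_reps=0`` the
    full-data tree is returned with supports unset (``None``).  Replicates
    whose resampled columns yield a saturated/degenerate distance matrix are
    skipped (support is the percentage over the replicates actually built).
    """
    tree = neighbor_joining(distance_matrix(aln, correction))
    for node in tree.traverse(include_self=True):
        node.support = None
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    universe = _leafset(tree)
    counts: dict[frozenset[str], int] = {s: 0 for s in _internal_splits(tree)}
    width = aln.width
    mat = np.array([list(r) for r in aln.rows])
    built = 0
    for _ in range(n_reps):
        idx = rng.integers(0, width, size=width)
        rep_rows = tuple("".join(row[idx]) for row in mat)
        rep_aln = MultipleAlignment(ids=aln.ids, rows=rep_rows)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep_aln, correction))
        except ValueError:
            log.warning("bootstrap replicate skipped (degenerate distances)")
            continue
        built += 1
        rep_splits = {frozenset([s, universe - s]) for s in _internal_splits(rep_tree)}
        for s in counts:
            if frozenset([s, universe - s]) in rep_splits:
                counts[s] += 1
    denom = max(built, 1)
    for s, node in _internal_splits(tree).items():
        node.support = 100.0 * counts[s] / denom
    return tree


def tree_to_newick(tree: TreeNode, include_support: bool = True) -> str:
    """Serialize to newick; integer bootstrap supports become internal labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            sup = getattr(node, "support", None)
            label = "" if (sup is None or not include_support) else str(int(round(sup)))
            label = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    return fmt(tree) + ";"


@dataclass(frozen=True)
class CladeReport:
    """Result of the monophyly rule for one genus.

    ``clade_member_ids`` is the smallest outgroup-rooted clade containing all
    type-strain anchors together with every leaf labeled with the genus; the
    genus is monophyletic when every leaf inside it carries the anchor genus
    label or is unlabeled at genus rank.  When the clade is contaminated by
    another labeled genus, only the anchors themselves are selected
    (conservative fallback).
    """

    genus: str
    anchor_ids: tuple[str, ...]
    is_monophyletic: bool
    clade_member_ids: frozenset[str]
    support: float | None
    selected_ids: frozenset[str]


def check_monophyly(
    tree: TreeNode,
    genus: str,
    anchor_ids: Sequence[str],
    outgroup_id: str,
    genus_labels: Mapping[str, str],
) -> CladeReport:
    """Apply the type-strain monophyly rule on an outgroup-rooted view of the tree.

    The tree is conceptually rooted on the edge leading to ``outgroup_id``;
    the candidate clade is the smallest rooted clade containing every anchor.
    Leaves with an empty genus label (environmental sequences unclassified at
    genus rank) never break monophyly.  ``support`` is the bootstrap value of
    the edge subtending the clade, when available.
    """
    if not anchor_ids:
        raise ValueError(f"genus {genus!r}: no anchor (type-strain) ids given")
    tips = {t.name: t for t in tree.tips()}
    missing = [a for a in anchor_ids if a not in tips]
    if missing:
        raise ValueError(f"genus {genus!r}: anchors not in tree: {missing}")
    if outgroup_id not in tips:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")

    # adjacency over the unrooted tree; edge attributes live on the child node
    adj: dict[TreeNode, list[TreeNode]] = {}
    for node in tree.traverse(include_self=True):
        for child in node.children:
            adj.setdefault(node, []).append(child)
            adj.setdefault(child, []).append(node)

    out_tip = tips[outgroup_id]
    # orient every node away from the outgroup tip and collect leaf sets
    root = adj[out_tip][0]
    parent: dict[TreeNode, TreeNode] = {root: out_tip}
    order: list[TreeNode] = [root]
    stack = [root]
    while stack:
        node = stack.pop()
        for nbr in adj[node]:
            if nbr is parent.get(node):
                continue
            parent[nbr] = node
            order.append(nbr)
            stack.append(nbr)
    below: dict[TreeNode, frozenset[str]] = {}
    for node in reversed(order):
        kids = [n for n in adj[node] if parent.get(n) is node]
        if not kids:
            below[node] = frozenset([node.name]) if node.name else frozenset()
        else:
            s: frozenset[str] = frozenset()
            for k in kids:
                s |= below[k]
            below[node] = s

    def label(sid: str) -> str:
        return genus_labels.get(sid, "")

    anchors = frozenset(anchor_ids)
    # the clade must gather all anchors plus every genus-labeled leaf: walk
    # up from one anchor until both are covered
    targets = anchors | {sid for sid in below[root] if label(sid) == genus}
    node = tips[anchor_ids[0]]
    while not targets <= below[node]:
        node = parent[node]
        if node is out_tip:
            raise ValueError(
                f"genus {genus!r}: anchors not on one side of the outgroup"
            )
    clade = below[node]

    is_mono = all(label(sid) in ("", genus) for sid in clade)
    selected = clade if is_mono else anchors
    # support of the edge subtending the clade: every edge of the unrooted
    # tree is a parent-child edge in the original layout, and support is
    # stored on the child node
    p = parent[node]
    if getattr(node, "parent", None) is p:
        support = getattr(node, "support", None)
    elif getattr(p, "parent", None) is node:
        support = getattr(p, "support", None)
    else:
        support = None
    return CladeReport(
        genus=genus,
        anchor_ids=tuple(anchor_ids),
        is_monophyletic=is_mono,
        clade_member_ids=clade,
        support=support,
        selected_ids=frozenset(selected),
    )
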