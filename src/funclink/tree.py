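"""Neighbour-joining functional trees and branch-set utilities.

The functional tree places species at the tips of a tree built from their
pairwise trait distances; branch lengths are the functional-diversity
units that the alpha and beta stages aggregate.  Trees are stored rooted at
the final three-way join node of the agglomeration (the reference root used
by the branch-based beta decomposition), but all path-based quantities are
orientation independent.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field

import numpy as np
import skbio

from .io import FormatError
from .traits import DistanceMatrix

logger = logging.getLogger("funclink")

__all__ = [
    "FunctionalTree",
    "nj_build",
    "induced_branches",
    "patristic",
    "random_additive_tree",
]


@dataclass
class FunctionalTree:
    """Rooted tree with non-negative branch lengths and labelled leaves.

    ``children[u]`` lists ``(child, edge_id)``; ``lengths[edge_id]`` is the
    branch length of the edge above ``edges[edge_id][1]``.
    """

    root: int
    children: dict[int, list[tuple[int, int]]]
    edges: list[tuple[int, int]]  # edge_id -> (parent, child)
    lengths: np.ndarray
    leaf_name: dict[int, str]
    clamped_negative_length: float = 0.0
    _postorder: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.lengths < 0).any():
            raise FormatError("negative branch length")
        self.name_leaf = {v: k for k, v in self.leaf_name.items()}
        if len(self.name_leaf) != len(self.leaf_name):
            raise FormatError("duplicate leaf labels")
        # iterative postorder (trees can be caterpillar-shaped)
        order: list[int] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            for c, _ in self.children.get(u, ()):  # noqa: B007
                stack.append(c)
        self._postorder = order[::-1]
        if len(order) != len(self.edges) + 1:
            raise FormatError("tree is not connected/acyclic")

    # -- basic accessors -------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return [self.leaf_name[n] for n in sorted(self.leaf_name)]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_name)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def parent_edge(self) -> dict[int, int]:
        """node -> id of the edge above it."""
        return {child: eid for eid, (_, child) in enumerate(self.edges)}

    def leaf_counts(self, selected: set[int]) -> np.ndarray:
        """Number of selected leaf nodes in the subtree below each edge."""
        below = np.zeros(max(self.children.keys() | self.leaf_name.keys()) + 1, dtype=int)
        for u in self._postorder:
            if u in self.leaf_name and u in selected:
                below[u] += 1
            for c, _ in self.children.get(u, ()):
                below[u] += below[c]
        counts = np.zeros(len(self.edges), dtype=int)
        for eid, (_, child) in enumerate(self.edges):
            counts[eid] = below[child]
        return counts

    def _nodes_for(self, leaves) -> set[int]:
        unknown = [name for name in leaves if name not in self.name_leaf]
        if unknown:
            raise FormatError(f"unknown leaf labels: {unknown}")
        return {self.name_leaf[name] for name in leaves}

    # -- newick ----------------------------------------------------------
    def to_newick(self) -> str:
        def render(u: int) -> str:
            kids = self.children.get(u, [])
            if not kids:
                return self.leaf_name[u]
            inner = ",".join(
                f"{render(c)}:{self.lengths[eid]:.17g}" for c, eid in kids
            )
            return f"({inner})"

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, source: str) -> "FunctionalTree":
        """Parse a Newick string or file path (quoted labels accepted)."""
        text = source
        if "(" not in source:  # looks like a path
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        sk = skbio.TreeNode.read(_stdio.StringIO(text))
        counter = [0]
        children: dict[int, list[tuple[int, int]]] = {}
        edges: list[tuple[int, int]] = []
        lengths: list[float] = []
        leaf_name: dict[int, str] = {}

        def build(node, my_id: int) -> None:
            if node.is_tip():
                leaf_name[my_id] = str(node.name)
                return
            children[my_id] = []
            for ch in node.children:
                counter[0] += 1
                cid = counter[0]
                eid = len(edges)
                edges.append((my_id, cid))
                lengths.append(float(ch.length or 0.0))
                children[my_id].append((cid, eid))
                build(ch, cid)

        build(sk, 0)
        return cls(0, children, edges, np.asarray(lengths), leaf_name)


def nj_build(d: DistanceMatrix) -> FunctionalTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    On additive input distances the patristic distances of the output
    reproduce the input exactly.  Negative branch-length estimates are
    clamped to zero and the clamped mass recorded.  Ties in the Q-criterion
    are broken by the smallest (i, j) pair in input label order.  With two
    labels the single edge is split at its midpoint by the root node.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise FormatError("neighbour joining needs at least 2 labels")
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    children: dict[int, list[tuple[int, int]]] = {}
    edges: list[tuple[int, int]] = []
    lengths: list[float] = []
    leaf_name = {i: lab for i, lab in enumerate(labels)}
    next_id = n

    def add_edge(parent: int, child: int, length: float) -> None:
        children.setdefault(parent, []).append((child, len(edges)))
        edges.append((parent, child))
        lengths.append(clamp(length))

    if n == 2:
        root = next_id
        add_edge(root, 0, d.values[0, 1] / 2.0)
        add_edge(root, 1, d.values[0, 1] / 2.0)
        return FunctionalTree(root, children, edges, np.asarray(lengths), leaf_name, clamped)

    active = list(range(n))  # node ids, in input order
    D = d.values.astype(float).copy()  # indexed by position in `active`

    while len(active) > 3:
        r = len(active)
        row = D.sum(axis=1)
        Q = (r - 2) * D - row[:, None] - row[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) in current order on ties: argmin scans row-major
        flat = int(np.argmin(Q))
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        vi = 0.5 * dij + (row[i] - row[j]) / (2.0 * (r - 2))
        vj = dij - vi
        new = next_id
        next_id += 1
        add_edge(new, active[i], vi)
        add_edge(new, active[j], vj)
        dk = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dk[keep][None, :]])
        D = np.hstack([D, np.append(dk[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new]

    (a, b, c) = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = next_id
    add_edge(root, a, (dab + dac - dbc) / 2.0)
    add_edge(root, b, (dab + dbc - dac) / 2.0)
    add_edge(root, c, (dac + dbc - dab) / 2.0)
    if clamped:
        logger.warning("clamped %.6g of negative NJ branch length to zero", clamped)
    return FunctionalTree(root, children, edges, np.asarray(lengths), leaf_name, clamped)


def induced_branches(tree: FunctionalTree, leaves) -> list[tuple[int, float]]:
    """Branches of the minimal spanning subtree connecting ``leaves``.

    Returns ``(edge_id, length)`` pairs; empty for a singleton.  An edge
    belongs to the induced subtree iff it separates the leaf subset, i.e.
    both of its sides contain at least one selected leaf.
    """
    sel = tree._nodes_for(leaves)
    if not sel:
        raise FormatError("empty leaf subset")
    k = len(sel)
    counts = tree.leaf_counts(sel)
    return [
        (eid, float(tree.lengths[eid]))
        for eid in range(len(tree.edges))
        if 0 < counts[eid] < k
    ]


def root_path_branches(tree: FunctionalTree, leaves) -> np.ndarray:
    """Boolean mask over edges on root-to-leaf paths of ``leaves``."""
    sel = tree._nodes_for(leaves)
    counts = tree.leaf_counts(sel)
    return counts > 0


def patristic(tree: FunctionalTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    na, nb = (tree._nodes_for([x]).pop() for x in (a, b))
    if na == nb:
        return 0.0
    parent = {child: (par, eid) for eid, (par, child) in enumerate(tree.edges)}
    path_a: dict[int, float] = {na: 0.0}
    node, acc = na, 0.0
    while node in parent:
        par, eid = parent[node]
        acc += tree.lengths[eid]
        path_a[par] = acc
        node = par
    node, acc = nb, 0.0
    while node not in path_a:
        par, eid = parent[node]
        acc += tree.lengths[eid]
        node = par
    return float(acc + path_a[node])


def patristic_matrix(tree: FunctionalTree) -> DistanceMatrix:
    """All pairwise leaf-to-leaf path lengths."""
    leaves = tree.leaves
    n = len(leaves)
    out = np.zeros((n, n))
    # depth of every node plus MRCA via leaf-count trick would be faster,
    # but trees here are small; reuse the pairwise path walk.
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = patristic(tree, leaves[i], leaves[j])
    return DistanceMatrix(leaves, out)


def random_additive_tree(
    n_leaves: int, rng: np.random.Generator, min_len: float = 0.1, max_len: float = 1.0
) -> FunctionalTree:
    """Random binary tree with uniform branch lengths (test/oracle support).

    Built by attaching each new leaf to a uniformly chosen existing edge,
    which yields a uniform-ish distribution over topologies and strictly
    positive internal branches, so its patristic matrix is additive.
    """
    if n_leaves < 3:
        raise FormatError("need at least 3 leaves")
    labels = [f"t{i}" for i in range(n_leaves)]
    # edge list as (u, v, length) on an unrooted tree; start from a star on 3
    nodes = n_leaves  # next internal node id
    ed: list[list] = []
    center = nodes
    nodes += 1
    for i in range(3):
        ed.append([center, i, rng.uniform(min_len, max_len)])
    for leaf in range(3, n_leaves):
        k = int(rng.integers(len(ed)))
        u, v, ln = ed[k]
        mid = nodes
        nodes += 1
        split = rng.uniform(0.2, 0.8) * ln
        ed[k] = [u, mid, split]
        ed.append([mid, v, ln - split])
        ed.append([mid, leaf, rng.uniform(min_len, max_len)])
    # root at `center`, orient edges
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, ln in ed:
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    children: dict[int, list[tuple[int, int]]] = {}
    edges: list[tuple[int, int]] = []
    lengths: list[float] = []
    stack = [(center, -1)]
    while stack:
        u, par = stack.pop()
        for v, ln in adj[u]:
            if v == par:
                continue
            children.setdefault(u, []).append((v, len(edges)))
            edges.append((u, v))
            lengths.append(ln)
            stack.append((v, u))
    leaf_name = {i: labels[i] for i in range(n_leaves)}
    return FunctionalTree(center, children, edges, np.asarray(lengths), leaf_name)
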