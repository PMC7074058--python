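"""Neighbor-joining trees, bootstrap support, midpoint rooting, Newick I/O.

The tree machinery is deliberately self-contained and deterministic:

* NJ joins are chosen by minimum Q; ties are broken by the lexicographically
  smallest pair of cluster representatives (the smallest leaf label inside
  each cluster), so the same matrix always yields the same tree on any
  platform.
* Negative branch-length estimates are clamped to zero and the deficit moved
  to the sister branch, the convention popular desktop phylogenetics
  packages use.
* Bootstrap resampling operates on alignment columns of the concatenated
  marker profiles (or on whole markers with ``resample="marker"``).
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .matrix import DistanceMatrix
from .mlsa import MARKER_ORDER

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "to_newick",
    "neighbor_joining",
    "bootstrap_support",
    "midpoint_root",
    "patristic_distances",
]


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]


class PhyloTree:
    """A (possibly unrooted) tree; unrooted trees use a trifurcating root."""

    def __init__(self, root: Node, rooted: bool) -> None:
        self.root = root
        self.rooted = rooted
        names = [l.name for l in root.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def bipartitions(self) -> dict[Node, frozenset]:
        """Canonical leaf-set bipartition per internal edge.

        The canonical side is the one *not* containing the smallest leaf
        label, so identical splits compare equal across rerootings.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[Node, frozenset] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(l.name for l in node.leaves())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out[node] = side
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_node(self.root), self.rooted)


def _copy_node(node: Node) -> Node:
    new = Node(node.name, node.length, node.support)
    for c in node.children:
        new.add(_copy_node(c))
    return new


# ---------------------------------------------------------------------------
# Newick


class NewickError(ValueError):
    """Malformed Newick input; carries the character position."""

    def __init__(self, message: str, pos: int) -> None:
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def parse_newick(text: str) -> PhyloTree:
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick string must end with ';'", len(text))
    pos = 0

    def error(msg):
        raise NewickError(msg, pos)

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.add(parse_clade())
                if pos >= len(text):
                    error("unexpected end of input inside '('")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                error(f"expected ',' or ')', found {text[pos]!r}")
        label = _scan_label()
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            num = _scan_label()
            try:
                node.length = float(num)
            except ValueError:
                error(f"invalid branch length {num!r}")
            if node.length < 0:
                error("negative branch length")
        return node

    def _scan_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos]

    root = parse_clade()
    if pos != len(text) - 1 or text[pos] != ";":
        raise NewickError("trailing characters after tree", pos)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted)


def _fmt_num(x: float) -> str:
    return format(x, ".10g")


def to_newick(tree: PhyloTree) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += _fmt_num(node.support)
            elif node.name:
                s += node.name
        if node.length is not None:
            s += ":" + _fmt_num(node.length)
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# neighbor-joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical NJ on a distance-mode matrix (unrooted result).

    Exact on additive matrices; deterministic under the lexicographic
    tie-break.  Requires at least three taxa.
    """
    if dm.mode != "distance":
        raise ValueError("neighbor_joining requires a distance-mode matrix")
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes = [Node(name=l) for l in dm.labels]
    reprs = list(dm.labels)  # smallest leaf label per active cluster
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        na = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best_q = np.inf
        best_pair = None
        best_key = None
        for a in range(na):
            for b in range(a + 1, na):
                q = (na - 2) * sub[a, b] - r[a] - r[b]
                key = tuple(sorted((reprs[active[a]], reprs[active[b]])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and key < best_key
                ):
                    best_q = q
                    best_pair = (a, b)
                    best_key = key
        a, b = best_pair
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (na - 2))
        lj = dij - li
        # clamp negatives, compensating on the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Node()
        ca, cb = nodes[i], nodes[j]
        ca.length, cb.length = li, lj
        parent.add(ca)
        parent.add(cb)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0])
        for c in range(na):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        reprs[i] = min(reprs[i], reprs[j])
        D[i, :] = new_row
        D[:, i] = new_row
        active.remove(j)

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    la = (dij + dik - djk) / 2.0
    lb = (dij + djk - dik) / 2.0
    lc = (dik + djk - dij) / 2.0
    root = Node()
    for idx, ln in zip((i, j, k), (la, lb, lc)):
        child = nodes[idx]
        child.length = max(ln, 0.0)
        root.add(child)
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap


def _profile_matrix(profiles) -> tuple[list[str], np.ndarray, list[tuple[int, int]]]:
    """Stack marker profiles into a byte matrix (positional columns).

    All profiles must carry the four standard markers with equal per-marker
    lengths; the sequences are treated as a trivially columnar alignment
    (appropriate for pre-aligned or indel-free data).
    """
    labels = [p.strain_id for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strain ids")
    blocks = []
    spans = []
    offset = 0
    for marker in MARKER_ORDER:
        seqs = []
        for p in profiles:
            if marker not in p.sequences:
                raise ValueError(f"profile {p.strain_id} lacks marker {marker}")
            seqs.append(p.sequences[marker].upper())
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"marker {marker} has unequal lengths across strains; "
                "column bootstrap requires positionally comparable sequences"
            )
        L = lengths.pop()
        arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        blocks.append(arr.reshape(len(profiles), L))
        spans.append((offset, offset + L))
        offset += L
    return labels, np.hstack(blocks), spans


def _pdistance_matrix(M: np.ndarray) -> np.ndarray:
    diff = M[:, None, :] != M[None, :, :]
    return diff.mean(axis=2)


def _p_to_jc(p: np.ndarray) -> np.ndarray:
    capped = np.minimum(p, 0.7499)
    if (p >= 0.75).any():
        warnings.warn("p-distance at or beyond JC saturation; capped at 0.7499")
    return -0.75 * np.log1p(-4.0 * capped / 3.0)


def bootstrap_support(
    profiles: Sequence,
    n_replicates: int = 1000,
    seed: int = 0,
    distance: str = "jc",
    resample: str = "column",
) -> PhyloTree:
    """NJ tree of the concatenated markers with bootstrap support.

    Columns (or whole markers) are resampled with replacement, the distance
    matrix and NJ tree recomputed per replicate, and each internal edge of
    the point-estimate tree annotated with the percentage of replicates
    containing its bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if resample not in ("column", "marker"):
        raise ValueError("resample must be 'column' or 'marker'")
    labels, M, spans = _profile_matrix(profiles)

    def tree_from(Msub: np.ndarray) -> PhyloTree:
        p = _pdistance_matrix(Msub)
        d = _p_to_jc(p) if distance == "jc" else p
        np.fill_diagonal(d, 0.0)
        return neighbor_joining(DistanceMatrix(labels, d, "distance"))

    main = tree_from(M)
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    L = M.shape[1]
    for _ in range(n_replicates):
        if resample == "column":
            idx = rng.integers(0, L, size=L)
        else:
            picks = rng.integers(0, len(spans), size=len(spans))
            idx = np.concatenate([np.arange(*spans[p]) for p in picks])
        rep = tree_from(M[:, idx])
        counts.update(set(rep.bipartitions().values()))
    for node, split in main.bipartitions().items():
        node.support = 100.0 * counts[split] / n_replicates
    return main


# ---------------------------------------------------------------------------
# midpoint rooting


def _adjacency(tree: PhyloTree):
    """Undirected edge map: node -> [(neighbor, length, support)]."""
    adj: dict[Node, list[tuple[Node, float, float | None]]] = {}
    for node in tree.root.walk():
        for child in node.children:
            ln = child.length if child.length is not None else 0.0
            adj.setdefault(node, []).append((child, ln, child.support))
            adj.setdefault(child, []).append((node, ln, child.support))
    return adj


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths along the tree."""
    adj = _adjacency(tree)
    leaves = sorted(tree.leaves(), key=lambda l: l.name)
    labels = [l.name for l in leaves]
    index = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    vals = np.zeros((n, n))
    for leaf in leaves:
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, ln, _ in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        i = index[leaf]
        for other, d in dist.items():
            if other.is_leaf:
                vals[i, index[other]] = d
    return DistanceMatrix(labels, (vals + vals.T) / 2.0, "distance")


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties on the longest path are broken by the lexicographically smallest
    leaf pair.  If every branch has zero length the tree is rooted at the
    first-ranked leaf's edge with a warning.
    """
    adj = _adjacency(tree)
    leaves = sorted(tree.leaves(), key=lambda l: l.name)

    def paths_from(start: Node):
        dist = {start: 0.0}
        prev: dict[Node, Node] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, ln, _ in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = (-1.0, None, None, None)
    for leaf in leaves:
        dist, prev = paths_from(leaf)
        for other in leaves:
            if other.name <= leaf.name:
                continue
            d = dist[other]
            key = (leaf.name, other.name)
            if d > best[0] + 1e-15 or (
                abs(d - best[0]) <= 1e-15 and best[1] is not None and key < (best[1].name, best[2].name)
            ):
                best = (d, leaf, other, prev)
    total, end_a, end_b, prev = best
    if total <= 0:
        warnings.warn("all branch lengths are zero; rooting at first-ranked leaf")
        total = 0.0
    # path from end_a to end_b (prev maps back toward end_a)
    path = [end_b]
    while path[-1] is not end_a:
        path.append(prev[path[-1]])
    path.reverse()
    half = total / 2.0
    # walk from end_a along the path
    edge_len = {}
    edge_sup = {}
    for u in adj:
        for v, ln, sup in adj[u]:
            edge_len[(u, v)] = ln
            edge_sup[(u, v)] = sup
    acc = 0.0
    for a, b in zip(path, path[1:]):
        ln = edge_len[(a, b)]
        if acc + ln >= half - 1e-15:
            offset = half - acc
            return _reroot_on_edge(tree, adj, a, b, offset, edge_sup)
        acc += ln
    return _reroot_on_edge(tree, adj, path[-2], path[-1], edge_len[(path[-2], path[-1])], edge_sup)


def _reroot_on_edge(tree, adj, a: Node, b: Node, offset: float, edge_sup) -> PhyloTree:
    """Place the root on edge (a, b) at ``offset`` from ``a``."""
    ln = dict(((u, v), l) for u in adj for v, l, _ in adj[u])[(a, b)]
    offset = min(max(offset, 0.0), ln)

    def build(node: Node, came_from: Node | None) -> Node:
        new = Node(node.name if node.is_leaf else None)
        if came_from is not None:
            new.length = ln_map[(came_from, node)]
            new.support = edge_sup[(came_from, node)]
        subs = []
        for nbr, _, _ in adj[node]:
            if nbr is came_from or nbr in exclude.get(node, ()):  # noqa: B023
                continue
            subs.append(build(nbr, node))
        if not node.is_leaf and len(subs) == 1:
            # splice out unifurcations (old degree-2 roots)
            only = subs[0]
            if new.length is not None:
                only.length = (only.length or 0.0) + new.length
            return only
        for s in sorted(subs, key=_sort_key):
            new.add(s)
        return new

    ln_map = {(u, v): l for u in adj for v, l, _ in adj[u]}
    exclude: dict[Node, tuple] = {a: (b,), b: (a,)}
    root = Node()
    side_a = build(a, None)
    # a spliced side already carries its inner edge length; add, don't replace
    side_a.length = (side_a.length or 0.0) + offset
    side_b = build(b, None)
    side_b.length = (side_b.length or 0.0) + (ln - offset)
    for side in (side_a, side_b):
        if side.support is None:
            side.support = edge_sup[(a, b)]
    for s in sorted((side_a, side_b), key=_sort_key):
        root.add(s)
    return PhyloTree(root, rooted=True)


def _sort_key(node: Node) -> str:
    return min(l.name for l in node.leaves())
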