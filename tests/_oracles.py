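"""Independent brute-force oracles used only by the test suite.

These are deliberately naive quadratic dynamic programs and enumerations,
written without reference to the package's own alignment/tree code, so the
implementation and its check never share a code path.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def nw_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_first: float = 5.0,
    gap_extend: float = 2.0,
) -> float:
    """Optimal global affine-gap alignment score (first gap column costs
    ``gap_first``, each further column ``gap_extend``; end gaps penalized)."""
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]  # ends in residue-residue
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # ends in gap in b (consumes a)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # ends in gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = -gap_first - gap_extend * (i - 1)
    for j in range(1, n + 1):
        Y[0][j] = -gap_first - gap_extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] - gap_first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_first)
            Y[i][j] = max(M[i][j - 1] - gap_first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_first)
    return max(M[m][n], X[m][n], Y[m][n])


def alignment_score(
    ga: str,
    gb: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_first: float = 5.0,
    gap_extend: float = 2.0,
) -> float:
    """Score of one explicit gapped alignment under the same convention."""
    score = 0.0
    prev_gap = None  # which sequence had the gap in the previous column
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            raise ValueError("double-gap column")
        if x == "-" or y == "-":
            cur = "a" if x == "-" else "b"
            score -= gap_extend if prev_gap == cur else gap_first
            prev_gap = cur
        else:
            score += match if x == y else mismatch
            prev_gap = None
    return score


def sw_score_matrix(
    a: np.ndarray,
    b: np.ndarray,
    smat: np.ndarray,
    gap_first: float,
    gap_extend: float,
) -> float:
    """Optimal local affine-gap score over encoded sequences (plain loops)."""
    m, n = a.size, b.size
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_first, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_first, F[i - 1, j] - gap_extend)
            H[i, j] = max(
                0.0, H[i - 1, j - 1] + smat[a[i - 1], b[j - 1]], E[i, j], F[i, j]
            )
            best = max(best, H[i, j])
    return best


# ---------------------------------------------------------------------------
# exhaustive unrooted topology enumeration (for NJ consistency checks)


def all_unrooted_topologies(labels: list[str]):
    """Yield every unrooted binary topology as a set of bipartitions.

    Built by stepwise leaf addition: (2n-5)!! topologies for n leaves.
    Each topology is represented by its set of non-trivial splits, each
    split being the frozenset side not containing ``labels[0]``.
    """
    if len(labels) < 4:
        yield frozenset()
        return
    # tree as edge list over nodes; leaves are labels, internals ints
    base_edges = [("#0", labels[0]), ("#0", labels[1]), ("#0", labels[2])]

    def add_leaf(edges, leaf, counter):
        for k in range(len(edges)):
            u, v = edges[k]
            new = f"#{counter}"
            yield (
                edges[:k]
                + edges[k + 1 :]
                + [(u, new), (new, v), (new, leaf)]
            )

    stack = [(base_edges, 3, 1)]
    while stack:
        edges, next_leaf, counter = stack.pop()
        if next_leaf == len(labels):
            yield _splits_of(edges, labels)
            continue
        for grown in add_leaf(edges, labels[next_leaf], counter):
            stack.append((grown, next_leaf + 1, counter + 1))


def _splits_of(edges, labels):
    from collections import defaultdict

    adj = defaultdict(list)
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    leafset = set(labels)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) is cut
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in leafset:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < len(labels) - 1:
            if labels[0] in side:
                side = leafset - side
            splits.add(frozenset(side))
    return frozenset(splits)


def random_additive_tree(labels: list[str], rng: np.random.Generator):
    """Random binary topology with uniform(0.1, 1) lengths; returns
    (newick, patristic matrix as dict of frozenset pairs)."""
    items = [{"nwk": l, "leaves": {l: 0.0}} for l in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a = items.pop(j)
        b = items.pop(i)
        la = round(float(rng.uniform(0.1, 1.0)), 6)
        lb = round(float(rng.uniform(0.1, 1.0)), 6)
        merged = {
            "nwk": f"({a['nwk']}:{la},{b['nwk']}:{lb})",
            "leaves": {
                **{k: v + la for k, v in a["leaves"].items()},
                **{k: v + lb for k, v in b["leaves"].items()},
            },
        }
        # record cross distances
        for k, v in a["leaves"].items():
            for k2, v2 in b["leaves"].items():
                merged.setdefault("pairs", {})[frozenset((k, k2))] = v + la + v2 + lb
        for prev in (a, b):
            for key, val in prev.get("pairs", {}).items():
                merged["pairs"][key] = val
        items.append(merged)
    root = items[0]
    n = len(labels)
    D = np.zeros((n, n))
    for i, x in enumerate(labels):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = root["pairs"][frozenset((x, labels[j]))]
    return root["nwk"] + ";", D
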