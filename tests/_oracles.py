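"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by the most direct method
available (exhaustive enumeration, per-cell dynamic programming, linear
least squares over all topologies) without sharing code with the package
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

NEG = float("-inf")


def affine_dp_score(a: str, b: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Gotoh three-state DP, plain per-cell loops.

    gap_open is the score of a length-1 gap (length-k gap scores
    gap_open + (k-1)*gap_extend).
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def p_distance_bruteforce(row_a: str, row_b: str) -> float:
    """Per-column counter: compare only unambiguous-base columns."""
    compared = 0
    mismatched = 0
    for x, y in zip(row_a, row_b):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            if x != y:
                mismatched += 1
    return mismatched / compared if compared else float("nan")


# --- unrooted binary topologies ------------------------------------------

def enumerate_topologies(leaves: list) -> list[list[tuple]]:
    """All unrooted binary topologies as edge lists.

    Nodes are leaf labels or ('i', k) internal tags; edges are unordered
    pairs. n leaves -> (2n-5)!! topologies.
    """
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    base = [("i", 0)]
    trees = [[(leaves[0], base[0]), (leaves[1], base[0]), (leaves[2], base[0])]]
    counter = 1
    for leaf in leaves[3:]:
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                tag = ("i", counter + k)  # unique within this expansion
                new = [e for idx, e in enumerate(edges) if idx != k]
                new += [(u, tag), (tag, v), (leaf, tag)]
                new_trees.append(new)
        counter += 10 * len(leaves)
        trees = new_trees
    return trees


def topology_bipartitions(edges: list[tuple], leaves: list) -> frozenset:
    """Nontrivial bipartitions (as frozensets of one side) of an edge list."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    leafset = frozenset(leaves)
    out = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) is cut
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in leafset:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < len(leaves) - 1:
            out.add(canonical_side(frozenset(side), leafset))
    return frozenset(out)


def canonical_side(side: frozenset, leafset: frozenset) -> frozenset:
    """Pick one representative side of a bipartition deterministically."""
    other = leafset - side
    return min(side, other, key=lambda s: (len(s), sorted(map(str, s))))


def ols_fit_residual(edges: list[tuple], leaves: list,
                     dm: np.ndarray) -> float:
    """Least-squares residual of fitting the distance matrix on a topology.

    Unconstrained OLS on edge lengths; an additive matrix has (near) zero
    residual only on its generating topology.
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append((v, (u, v)))
        adj.setdefault(v, []).append((u, (u, v)))
    edge_idx = {e: i for i, e in enumerate(edges)}

    def path_edges(src, dst):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, path = stack.pop()
            if node == dst:
                return path
            for nb, e in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, e, path + [e]))
        raise RuntimeError("disconnected")

    pairs = list(itertools.combinations(range(len(leaves)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in path_edges(leaves[i], leaves[j]):
            A[row, edge_idx[e]] = 1.0
        y[row] = dm[i, j]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


def random_tree_matrix(n: int, rng: np.random.Generator
                       ) -> tuple[np.ndarray, frozenset, list]:
    """Random binary tree with random branch lengths -> additive matrix.

    Returns (distance matrix, bipartition set, leaf labels).
    """
    leaves = [f"t{i}" for i in range(n)]
    # random topology by inserting each leaf on a uniformly chosen edge
    edges = [(leaves[0], ("i", 0)), (leaves[1], ("i", 0)),
             (leaves[2], ("i", 0))]
    for idx, leaf in enumerate(leaves[3:], start=1):
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        tag = ("i", idx)
        edges += [(u, tag), (tag, v), (leaf, tag)]
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append((v, lengths[(u, v)]))
        adj.setdefault(v, []).append((u, lengths[(u, v)]))

    def dist(src, dst):
        stack = [(src, 0.0)]
        seen = {src}
        while stack:
            node, d = stack.pop()
            if node == dst:
                return d
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, d + w))
        raise RuntimeError("disconnected")

    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = dist(leaves[i], leaves[j])
    return dm, topology_bipartitions(edges, leaves), leaves


def wilcoxon_enumeration(diffs: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p by literally enumerating all 2^n sign vectors."""
    from scipy.stats import rankdata

    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        n_le += w <= w_obs + 1e-12
        n_ge += w >= w_obs - 1e-12
    total = 2 ** n
    if alternative == "greater":
        return n_ge / total
    if alternative == "less":
        return n_le / total
    return min(1.0, 2 * min(n_le / total, n_ge / total))
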