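"""Neighbor joining, bootstrap monophyly, and tree-based species resolution.

A species is *resolved* by the tree method when its accessions form a
monophyletic group in the NJ tree built from the full alignment AND that
grouping is supported in at least 50% of column-resampled bootstrap
replicates (the usual majority-support convention; the cutoff is
inclusive). Support is computed per species directly on the replicate
trees, which at the 50% threshold is equivalent to reading it off a
majority-rule consensus; a consensus writer is provided for figures.

The NJ implementation is the classical Saitou-Nei agglomeration with
explicit deterministic semantics: Q-matrix ties go to the lexicographically
smallest (i, j) pair, negative branch lengths are clamped to zero with the
deficit moved to the sister edge, and missing distances are imputed as the
matrix's maximum observed distance (conservative against spurious
monophyly) with a warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from barcodekit.align import Alignment
from barcodekit.distance import DistanceMatrix, encode_rows

logger = logging.getLogger(__name__)


class Node:
    """Tree node; the tree is unrooted but stored rooted at the final join."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name: Hashable = None,
                 children: list | None = None, support: float | None = None):
        self.name = name
        self.children: list[tuple["Node", float, float | None]] = children or []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[Hashable]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _bl, _sup in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree with leaves labeled by sample id."""

    root: Node

    @property
    def leaf_names(self) -> list[Hashable]:
        return self.root.leaves()

    def bipartitions(self) -> list[frozenset]:
        """One leaf-set per internal edge (the side not containing the
        storage root), trivial single-leaf sides excluded."""
        out = []

        def walk(node: Node) -> None:
            for child, _bl, _sup in node.children:
                if not child.is_leaf:
                    out.append(frozenset(child.leaves()))
                    walk(child)

        walk(self.root)
        return out

    def is_monophyletic(self, leaf_set: set) -> bool:
        """True iff some edge separates exactly ``leaf_set`` from the rest."""
        target = frozenset(leaf_set)
        all_leaves = frozenset(self.leaf_names)
        if not target <= all_leaves:
            raise ValueError("leaf set not contained in tree")
        if len(target) <= 1 or target == all_leaves:
            return True
        complement = all_leaves - target
        for side in self.bipartitions():
            if side == target or side == complement:
                return True
        # pendant edges: a 1-leaf side's complement
        if len(complement) == 1:
            return True
        return False

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node, bl: float | None, sup: float | None) -> str:
            if node.is_leaf:
                core = str(node.name)
            else:
                inner = ",".join(fmt(c, b, s) for c, b, s in node.children)
                label = ""
                if with_support and sup is not None:
                    label = f"{sup:g}"
                core = f"({inner}){label}"
            if bl is not None:
                core += f":{bl:.6f}"
            return core

        inner = ",".join(fmt(c, b, s) for c, b, s in self.root.children)
        return f"({inner});"


def nj(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining on a p-distance matrix.

    Requires >= 3 taxa. Missing entries are imputed as the maximum observed
    distance (with a warning). Internal nodes of the result have degree 3.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = np.array(dm.values, dtype=float)
    if np.isnan(D).any():
        finite = D[~np.isnan(D)]
        impute = float(finite.max()) if finite.size else 0.0
        logger.warning("imputing %d missing distance(s) as max observed %.4f",
                       int(np.isnan(D).sum() // 2), impute)
        D[np.isnan(D)] = impute
        np.fill_diagonal(D, 0.0)

    nodes: list[Node] = [Node(name=sid) for sid in dm.ids]
    # parallel arrays of active indices into D
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin over i<j == lexicographically smallest tie
        iu = np.triu_indices(r, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = sub[i, j]
        li = dij / 2 + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[(nodes[active[i]], float(li), None),
                                (nodes[active[j]], float(lj), None)])
        # distances from the new node to the rest
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        # reuse slot gi for the new node
        for idx, g in enumerate(active):
            D[gi, g] = D[g, gi] = new_d[idx]
        D[gi, gi] = 0.0
        nodes[gi] = parent
        active.remove(gj)

    # final three (or fewer) nodes joined at one internal vertex
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    root = Node(children=[(nodes[a], float(la), None),
                          (nodes[b], float(lb), None),
                          (nodes[c], float(lc), None)])
    return Tree(root=root)


@dataclass
class MonophylyResult:
    """Per-species outcome of the tree-based resolution test."""

    species: str
    n_accessions: int
    monophyletic_in_original: bool
    bootstrap_support: float
    resolved: bool


def _species_sets(species_of: Mapping[Hashable, str],
                  ids: Sequence[Hashable]) -> dict[str, frozenset]:
    by_sp: dict[str, set] = {}
    for sid in ids:
        by_sp.setdefault(species_of[sid], set()).add(sid)
    return {sp: frozenset(v) for sp, v in by_sp.items() if len(v) >= 2}


def _replicate_matrix(X: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """p-distance matrix on resampled columns; missing imputed as the
    replicate's max observed distance."""
    Xb = X[:, cols]
    valid = Xb >= 0
    comp = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    diff = ((Xb[:, None, :] != Xb[None, :, :])
            & valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    d = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        finite = d[~np.isnan(d)]
        d[np.isnan(d)] = finite.max() if finite.size else 0.0
        np.fill_diagonal(d, 0.0)
    return d


def bootstrap_support(
    aln: Alignment,
    species_of: Mapping[Hashable, str],
    n_reps: int = 1000,
    seed: int = 0,
    support_cutoff: float = 50.0,
    resolution_mode: str = "original_and_support",
) -> list[MonophylyResult]:
    """Column-bootstrap NJ monophyly support per multi-accession species.

    Each replicate resamples alignment columns with replacement, rebuilds
    the p-distance matrix and the NJ tree, and tests each species' leaves
    for monophyly; support is the percentage of replicates in which they
    form a clade. Replicate ``r`` uses the RNG stream ``(seed, r)``, so
    results do not depend on evaluation order. Singleton species are
    excluded.

    ``resolution_mode``: ``"original_and_support"`` (default) requires
    monophyly in the full-alignment tree and support >= cutoff;
    ``"support_only"`` uses the support threshold alone.
    """
    if len(aln) < 3:
        raise ValueError("need >= 3 rows for tree bootstrap")
    if resolution_mode not in ("original_and_support", "support_only"):
        raise ValueError(f"unknown resolution_mode {resolution_mode!r}")
    sp_sets = _species_sets(species_of, aln.ids)
    if not sp_sets:
        raise ValueError("no multi-accession species to test")
    X = encode_rows(aln.rows)
    L = X.shape[1]

    original = nj(DistanceMatrix(ids=list(aln.ids),
                                 values=_replicate_matrix(X, np.arange(L))))
    mono_orig = {sp: original.is_monophyletic(set(s))
                 for sp, s in sp_sets.items()}

    hits = {sp: 0 for sp in sp_sets}
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, L, size=L)
        tree = nj(DistanceMatrix(ids=list(aln.ids),
                                 values=_replicate_matrix(X, cols)))
        sides = set(tree.bipartitions())
        all_leaves = frozenset(aln.ids)
        for sp, leaf_set in sp_sets.items():
            comp = all_leaves - leaf_set
            if leaf_set in sides or comp in sides or len(comp) == 1:
                hits[sp] += 1

    results = []
    for sp in sorted(sp_sets):
        support = 100.0 * hits[sp] / n_reps
        if resolution_mode == "support_only":
            resolved = support >= support_cutoff
        else:
            resolved = mono_orig[sp] and support >= support_cutoff
        results.append(MonophylyResult(
            species=sp,
            n_accessions=len(sp_sets[sp]),
            monophyletic_in_original=mono_orig[sp],
            bootstrap_support=support,
            resolved=resolved,
        ))
    return results


def species_resolution_tree(results: Sequence[MonophylyResult]) -> float:
    """Percentage of multi-accession species resolved by the tree method."""
    if not results:
        raise ValueError("no monophyly results")
    return 100.0 * sum(r.resolved for r in results) / len(results)


def consensus_tree(trees: Sequence[Tree], min_frequency: float = 0.5) -> Tree:
    """Majority-rule consensus of replicate trees (1.0 -> strict consensus).

    Bipartitions occurring in > ``min_frequency`` of trees (>= for strict)
    are kept, annotated with their percentage occurrence, and assembled
    into a (possibly multifurcating) tree without branch lengths.
    """
    if not trees:
        raise ValueError("no trees")
    leaves = frozenset(trees[0].leaf_names)
    for t in trees[1:]:
        if frozenset(t.leaf_names) != leaves:
            raise ValueError("trees have different leaf sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        seen = set()
        for side in t.bipartitions():
            canon = min(side, leaves - side, key=lambda s: (len(s), sorted(map(str, s))))
            if canon not in seen:
                seen.add(canon)
                counts[canon] = counts.get(canon, 0) + 1
    n = len(trees)
    if min_frequency >= 1.0:
        keep = {s: c for s, c in counts.items() if c == n}
    else:
        keep = {s: c for s, c in counts.items() if c / n > min_frequency}
    # assemble: insert clades smallest-last so nesting works greedily
    root = Node(children=[(Node(name=l), None, None) for l in sorted(leaves, key=str)])
    for clade in sorted(keep, key=len):
        support = 100.0 * keep[clade] / n
        _insert_clade(root, clade, support)
    return Tree(root=root)


def _insert_clade(root: Node, clade: frozenset, support: float) -> None:
    """Group the children of the smallest node containing ``clade``."""

    def find(node: Node) -> Node | None:
        for child, _bl, _sup in node.children:
            if not child.is_leaf and clade <= frozenset(child.leaves()):
                return find(child)
        return node if clade <= frozenset(node.leaves()) else None

    host = find(root)
    if host is None:
        return
    inside, outside = [], []
    for entry in host.children:
        child = entry[0]
        if frozenset(child.leaves()) <= clade:
            inside.append(entry)
        else:
            outside.append(entry)
    if len(inside) < 2:
        return  # incompatible or already nested
    new = Node(children=inside, support=support)
    host.children = outside + [(new, None, support)]
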