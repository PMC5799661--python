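"""Neighbor-joining phylogeny with bootstrap support and clade calling.

Distances are p-distances over pairwise-deleted columns (gap treatment of
standard protein NJ workflows); trees are built by the Saitou–Nei algorithm
with negative branch lengths clamped to zero, support values are the
percentage of bootstrap replicates (column resampling with replacement)
containing the same bipartition, and clades are called from the maximal
supported bipartitions at a support threshold (70 by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Tree",
    "CladeCall",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "call_clades",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset({self.name})
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaves()
        return frozenset(out)


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root node."""

    root: Node
    taxa: list[str]
    support: dict[frozenset[str], float] = field(default_factory=dict)
    clamped_deficit: float = 0.0

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each as its canonical (smaller or
        lexicographically first) side."""
        all_taxa = frozenset(self.taxa)
        out: set[frozenset[str]] = set()

        def walk(node: Node):
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(_canonical(side, all_taxa))
                walk(child)

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        all_taxa = frozenset(self.taxa)

        def fmt(node: Node, length: float | None) -> str:
            if not node.children:
                core = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if with_support:
                    side = node.leaves()
                    if 1 < len(side) < len(all_taxa) - 1:
                        sup = self.support.get(_canonical(side, all_taxa))
                        if sup is not None:
                            label = f"{sup:g}"
                core = f"({inner}){label}"
            return core if length is None else f"{core}:{length:.6f}"

        return fmt(self.root, None) + ";"


@dataclass
class CladeCall:
    clades: list[frozenset[str]]
    orphans: list[str]


def _canonical(side: frozenset[str], all_taxa: frozenset[str]) -> frozenset[str]:
    other = all_taxa - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return min(side, other, key=lambda s: sorted(s))


def p_distance(alignment: dict[str, str], gap_chars: str = "-.") -> DistanceMatrix:
    """Pairwise fraction of differing residues with pairwise gap deletion."""
    taxa = list(alignment)
    rows = [alignment[t].upper() for t in taxa]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows differ in length")
    gaps = set(gap_chars)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        comparable = diff = 0
        for a, b in zip(rows[i], rows[j]):
            if a in gaps or b in gaps:
                continue
            comparable += 1
            if a != b:
                diff += 1
        if comparable == 0:
            raise ValueError(f"no comparable columns between {taxa[i]} and {taxa[j]}")
        d[i, j] = d[j, i] = diff / comparable
    return DistanceMatrix(taxa=taxa, d=d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei NJ; ties broken at the lowest (row, column) index pair.

    Negative branch lengths are clamped to 0 and the total clamped deficit
    is recorded on the tree.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node(
        children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj)), (nodes[k], clamp(lk))]
    )
    if deficit:
        logger.info("clamped %.4g of negative branch length to zero", deficit)
    return Tree(root=root, taxa=list(dm.taxa), clamped_deficit=deficit)


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    distance=p_distance,
) -> Tree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement; an edge's
    support is the percentage of replicate trees containing its bipartition.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    tree = neighbor_joining(distance(alignment))
    target = tree.bipartitions()
    if not target:
        logger.warning("fewer than 4 taxa: no internal edges to support")
        return tree
    taxa = list(alignment)
    length = len(alignment[taxa[0]])
    rng = np.random.default_rng(seed)
    counts = {bp: 0 for bp in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {t: "".join(alignment[t][c] for c in cols) for t in taxa}
        try:
            rep_tree = neighbor_joining(distance(resampled))
        except ValueError:
            continue  # e.g. a pair with no comparable resampled columns
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    tree.support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    return tree


def call_clades(tree: Tree, threshold: float = 70.0) -> CladeCall:
    """Maximal supported bipartition sides as clades; the rest are orphans.

    Each supported internal edge contributes its smaller side (both sides
    for an even split) as a candidate clade; candidates nested inside a
    larger candidate are absorbed, so the called clades are disjoint.
    """
    all_taxa = frozenset(tree.taxa)
    candidates: set[frozenset[str]] = set()
    for bp, sup in tree.support.items():
        if sup < threshold:
            continue
        other = all_taxa - bp
        if len(bp) < len(other):
            candidates.add(bp)
        elif len(other) < len(bp):
            candidates.add(other)
        else:
            candidates.update((bp, other))
    maximal = [
        c
        for c in candidates
        if not any(c < o for o in candidates)
    ]
    kept: list[frozenset[str]] = []
    for c in sorted(maximal, key=len, reverse=True):
        if all(c.isdisjoint(k) for k in kept):
            kept.append(c)
    covered = frozenset().union(*kept) if kept else frozenset()
    return CladeCall(
        clades=sorted(kept, key=lambda s: sorted(s)),
        orphans=sorted(all_taxa - covered),
    )


def clades_table(call: CladeCall) -> pd.DataFrame:
    rows = [
        {"clade": i + 1, "n_taxa": len(clade), "taxa": ",".join(sorted(clade))}
        for i, clade in enumerate(call.clades)
    ]
    rows.append({"clade": 0, "n_taxa": len(call.orphans), "taxa": ",".join(call.orphans)})
    return pd.DataFrame(rows)
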