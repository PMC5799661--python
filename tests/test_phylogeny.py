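"""Neighbor joining, bootstrap supports and clade calling."""

import numpy as np
import pytest

from genefam import phylogeny


def random_additive_tree(n_taxa: int, rng):
    """A random binary tree with positive branch lengths and its leaf-to-leaf
    additive distance matrix (independent of the NJ implementation)."""
    nodes = [{"name": f"t{i}", "children": []} for i in range(n_taxa)]
    lengths = {}
    pool = list(range(n_taxa))
    all_nodes = [dict(n) for n in nodes]
    children_of = {}
    next_id = n_taxa
    parent_len = {}
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), 2, replace=False))
        a, b = pool[i], pool[j]
        children_of[next_id] = (a, b)
        parent_len[a] = float(rng.uniform(0.05, 0.5))
        parent_len[b] = float(rng.uniform(0.05, 0.5))
        pool = [x for x in pool if x not in (a, b)] + [next_id]
        next_id += 1
    root = pool[0]

    def leaves_below(v):
        if v < n_taxa:
            return {v: 0.0}
        out = {}
        for c in children_of[v]:
            for leaf, dist in leaves_below(c).items():
                out[leaf] = dist + parent_len[c]
        return out

    # distances via lowest common ancestor sums
    d = np.zeros((n_taxa, n_taxa))

    def fill(v):
        if v < n_taxa:
            return
        a, b = children_of[v]
        la, lb = leaves_below(a), leaves_below(b)
        for x, dx in la.items():
            for y, dy in lb.items():
                dist = dx + parent_len[a] + dy + parent_len[b]
                d[x, y] = d[y, x] = dist
        fill(a)
        fill(b)

    fill(root)
    taxa = [f"t{i}" for i in range(n_taxa)]

    def bipartitions():
        out = set()
        for v, (a, b) in children_of.items():
            for side in (a, b):
                leaves = frozenset(f"t{x}" for x in leaves_below(side))
                if 1 < len(leaves) < n_taxa - 1:
                    other = frozenset(taxa) - leaves
                    out.add(leaves if len(leaves) < len(other) else
                            (other if len(other) < len(leaves) else min(leaves, other, key=sorted)))
        return out

    return taxa, d, bipartitions()


class TestPDistance:
    def test_identical_rows(self):
        dm = phylogeny.p_distance({"a": "MKV", "b": "MKV"})
        assert dm.d[0, 1] == 0.0

    def test_fraction_of_differing_columns(self):
        a = "A" * 95 + "C" * 5
        b = "A" * 100
        dm = phylogeny.p_distance({"a": a, "b": b})
        assert dm.d[0, 1] == pytest.approx(0.05)

    def test_pairwise_gap_deletion_matches_column_walk(self, rng):
        aas = "ACDEFG-"
        rows = {f"t{i}": "".join(aas[k] for k in rng.integers(0, 7, 200)) for i in range(4)}
        dm = phylogeny.p_distance(rows)
        taxa = list(rows)
        for i in range(4):
            for j in range(i + 1, 4):
                comp = [(x, y) for x, y in zip(rows[taxa[i]], rows[taxa[j]]) if "-" not in (x, y)]
                expected = sum(x != y for x, y in comp) / len(comp)
                assert dm.d[i, j] == pytest.approx(expected)

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            phylogeny.p_distance({"a": "AC--", "b": "--AC"})


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = phylogeny.DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = phylogeny.neighbor_joining(dm)
        lengths = {child.name: bl for child, bl in tree.root.children}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0), "C": pytest.approx(3.0)}

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_additive_metric_round_trip(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        taxa, d, true_bps = random_additive_tree(n_taxa, rng)
        tree = phylogeny.neighbor_joining(phylogeny.DistanceMatrix(taxa, d))
        assert tree.bipartitions() == true_bps
        assert tree.clamped_deficit == pytest.approx(0.0)

    def test_matches_skbio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        taxa, d, _ = random_additive_tree(7, rng)
        ours = phylogeny.neighbor_joining(phylogeny.DistanceMatrix(taxa, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
        ref_bps = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = frozenset(taxa) - side
            if 1 < len(side) < len(taxa) - 1:
                ref_bps.add(side if len(side) < len(other) else
                            (other if len(other) < len(side) else min(side, other, key=sorted)))
        assert ours.bipartitions() == ref_bps

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(23)
        taxa, d, _ = random_additive_tree(6, rng)
        t1 = phylogeny.neighbor_joining(phylogeny.DistanceMatrix(taxa, d))
        perm = rng.permutation(6)
        taxa2 = [taxa[i] for i in perm]
        d2 = d[np.ix_(perm, perm)]
        t2 = phylogeny.neighbor_joining(phylogeny.DistanceMatrix(taxa2, d2))
        assert t1.bipartitions() == t2.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylogeny.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


def grouped_alignment(rng, n_groups=3, per_group=4, n_random=2, length=120, mut=6):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    aln = {}
    for g in range(n_groups):
        anc = "".join(aas[i] for i in rng.integers(0, 20, length))
        for k in range(per_group):
            s = list(anc)
            for pos in rng.choice(length, mut, replace=False):
                s[pos] = aas[rng.integers(20)]
            aln[f"g{g}t{k}"] = "".join(s)
    for r in range(n_random):
        aln[f"r{r}"] = "".join(aas[i] for i in rng.integers(0, 20, length))
    return aln


class TestBootstrap:
    def test_identical_pair_has_full_support(self, rng):
        aln = grouped_alignment(rng, n_groups=1, per_group=2, n_random=3, mut=0)
        tree = phylogeny.bootstrap_support(aln, n_replicates=50, seed=3)
        cherry = frozenset({"g0t0", "g0t1"})
        assert tree.support[cherry] == pytest.approx(100.0)

    def test_single_replicate_support_binary(self, rng):
        aln = grouped_alignment(rng)
        tree = phylogeny.bootstrap_support(aln, n_replicates=1, seed=1)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_seed_determinism(self, rng):
        aln = grouped_alignment(rng)
        t1 = phylogeny.bootstrap_support(aln, n_replicates=30, seed=7)
        t2 = phylogeny.bootstrap_support(aln, n_replicates=30, seed=7)
        assert t1.support == t2.support


class TestCladeCalls:
    def _tree_with_uniform_support(self, rng, support):
        aln = grouped_alignment(rng)
        tree = phylogeny.bootstrap_support(aln, n_replicates=10, seed=2)
        tree.support = {bp: support for bp in tree.support}
        return tree

    def test_full_support_no_orphans(self, rng):
        tree = self._tree_with_uniform_support(rng, 100.0)
        call = phylogeny.call_clades(tree, 70.0)
        covered = set().union(*call.clades)
        assert call.orphans == []
        assert covered == set(tree.taxa)

    def test_no_support_all_orphans(self, rng):
        tree = self._tree_with_uniform_support(rng, 10.0)
        call = phylogeny.call_clades(tree, 70.0)
        assert call.clades == []
        assert sorted(call.orphans) == sorted(tree.taxa)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(1)
        aln = grouped_alignment(rng, n_groups=3, per_group=6, n_random=2)
        tree = phylogeny.bootstrap_support(aln, n_replicates=100, seed=5)
        call = phylogeny.call_clades(tree, 70.0)
        expected = [frozenset(f"g{g}t{k}" for k in range(6)) for g in range(3)]
        assert sorted(map(sorted, call.clades)) == sorted(map(sorted, expected))
        assert call.orphans == ["r0", "r1"]

    def test_clades_and_orphans_partition_taxa(self, rng):
        aln = grouped_alignment(rng)
        tree = phylogeny.bootstrap_support(aln, n_replicates=50, seed=11)
        call = phylogeny.call_clades(tree, 70.0)
        members = [t for c in call.clades for t in c]
        assert len(members) == len(set(members))  # disjoint
        assert sorted(members + call.orphans) == sorted(tree.taxa)
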