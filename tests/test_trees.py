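import itertools

import numpy as np
import pytest

from barcodiag.distances import DistanceMatrix, distance_matrix
from barcodiag.seqio import Library, collapse_haplotypes
from barcodiag.simulate import SimConfig, inject_shared_haplotype, simulate_library
from barcodiag.trees import (
    bipartitions,
    bootstrap_supports,
    differentiation_report,
    is_monophyletic,
    nj,
    root_tree,
)

from conftest import make_record


def dm_from_array(labels, arr):
    arr = np.asarray(arr, dtype=float)
    false = np.zeros(arr.shape, dtype=bool)
    return DistanceMatrix(list(labels), arr, np.full(arr.shape, 100, dtype=np.int64),
                          false.copy(), false.copy())


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive edge lengths; returns the
    leaf-to-leaf path-distance matrix plus the set of true bipartitions."""
    # grow an unrooted tree by attaching taxa to random edges, tracked as an
    # adjacency map over node ids
    next_id = [n_taxa]
    adj = {}  # node -> {neighbor: length}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def disconnect(a, b):
        del adj[a][b]
        del adj[b][a]

    w = lambda: float(rng.uniform(0.05, 1.0))
    # start with a 3-star
    center = next_id[0]
    next_id[0] += 1
    for leaf in range(3):
        connect(center, leaf, w())
    edges = [(center, 0), (center, 1), (center, 2)]
    for leaf in range(3, n_taxa):
        a, b = edges[int(rng.integers(len(edges)))]
        length = adj[a][b]
        mid = next_id[0]
        next_id[0] += 1
        split = float(rng.uniform(0.2, 0.8)) * length
        disconnect(a, b)
        connect(a, mid, max(split, 0.05))
        connect(mid, b, max(length - split, 0.05))
        connect(mid, leaf, w())
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (mid, leaf)]

    # all-pairs path lengths by BFS from each leaf
    labels = [f"t{i}" for i in range(n_taxa)]
    dmat = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, length in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + length
                    stack.append(v)
        for dst in range(n_taxa):
            dmat[src, dst] = dist[dst]
    dmat = (dmat + dmat.T) / 2.0  # exact symmetry despite float summation order

    # true bipartitions from internal edges
    leafset = frozenset(labels)
    ref = min(leafset)
    parts = set()
    internal = [(a, b) for a in adj for b in adj[a] if a < b and a >= n_taxa and b >= n_taxa]
    for a, b in internal:
        disconnect(a, b)
        side = set()
        stack = [a]
        seen = {a}
        while stack:
            u = stack.pop()
            if u < n_taxa:
                side.add(labels[u])
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        connect(a, b, 1.0)
        s = frozenset(side)
        if 2 <= len(s) <= n_taxa - 2:
            parts.add(s if ref not in s else leafset - s)
    return labels, dmat, parts


def tree_path_distances(tree, labels):
    """Leaf-to-leaf path lengths on a reconstructed tree."""
    n = len(labels)
    out = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = tips[a].distance(tips[labels[j]])
            out[i, j] = out[j, i] = d
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = dm_from_array("ABC", [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        tree = nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0}
        assert len(tree.children) == 3  # unrooted trifurcation

    def test_four_taxon_additive_matrix(self):
        dm = dm_from_array("ABCD", [[0, 3, 5, 6],
                                    [3, 0, 6, 7],
                                    [5, 6, 0, 7],
                                    [6, 7, 0, 0]])
        dm.values[2, 3] = dm.values[3, 2] = 7
        dm.values[3, 0] = 6
        tree = nj(dm)
        parts = bipartitions(tree)
        assert parts == {frozenset({"C", "D"})}  # AB|CD split
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0, abs=1e-12)
        assert lengths["B"] == pytest.approx(2.0, abs=1e-12)
        assert lengths["C"] == pytest.approx(3.0, abs=1e-12)
        assert lengths["D"] == pytest.approx(4.0, abs=1e-12)
        # internal edge of length 1
        got = tree_path_distances(tree, list("ABCD"))
        assert np.allclose(got, dm.values, atol=1e-12)

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 13))
            labels, dmat, want_parts = random_additive_tree(rng, n)
            tree = nj(dm_from_array(labels, dmat))
            assert bipartitions(tree) == want_parts
            assert np.allclose(tree_path_distances(tree, labels), dmat, atol=1e-9)

    def test_agrees_with_skbio_reference(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        labels, dmat, _ = random_additive_tree(rng, 8)
        ours = nj(dm_from_array(labels, dmat))
        theirs = skbio_nj(SkbioDM(dmat, ids=labels))
        assert bipartitions(ours) == bipartitions(theirs)

    def test_label_order_invariance(self, rng):
        labels, dmat, _ = random_additive_tree(rng, 7)
        parts = bipartitions(nj(dm_from_array(labels, dmat)))
        perm = list(rng.permutation(len(labels)))
        dm2 = dm_from_array([labels[i] for i in perm], dmat[np.ix_(perm, perm)])
        assert bipartitions(nj(dm2)) == parts

    def test_too_few_labels_rejected(self):
        dm = dm_from_array("AB", [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            nj(dm)

    def test_undefined_distances_named_in_error(self):
        dm = dm_from_array("ABC", [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        dm.undefined[0, 1] = dm.undefined[1, 0] = True
        with pytest.raises(ValueError, match="'A', 'B'"):
            nj(dm)

    def test_branch_lengths_non_negative(self, small_library):
        lib, _ = small_library
        tree = nj(distance_matrix(lib))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, small_library):
        lib, _ = small_library
        tree = bootstrap_supports(lib, replicates=1, seed=0)
        sups = [n.support for n in tree.non_tips(include_self=False) if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_reproducible(self, small_library):
        lib, _ = small_library
        t1 = bootstrap_supports(lib, replicates=10, seed=42)
        t2 = bootstrap_supports(lib, replicates=10, seed=42)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if n.support is not None)
        assert s1 == s2

    def test_supports_bounded(self, small_library):
        lib, _ = small_library
        tree = bootstrap_supports(lib, replicates=10, seed=1)
        for n in tree.non_tips(include_self=False):
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_well_separated_clades_have_high_support(self, seed):
        # two clades of 3, separated by ~20 substitutions over 300 sites
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), size=300))
        other = list(base)
        for pos in rng.choice(300, size=20, replace=False):
            other[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[pos]]
        other = "".join(other)

        def jitter(seq, k):
            s = list(seq)
            for pos in rng.choice(300, size=k, replace=False):
                s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            return "".join(s)

        recs = [make_record(f"a{i}", jitter(base, 1), "spA") for i in range(3)]
        recs += [make_record(f"b{i}", jitter(other, 1), "spB") for i in range(3)]
        lib = Library(recs)
        tree = bootstrap_supports(lib, replicates=100, seed=seed)
        clade_a = frozenset(f"a{i}" for i in range(3))
        clade_b = frozenset(f"b{i}" for i in range(3))
        leaves = frozenset(lib.ids)
        ref = min(leaves)
        for node in tree.non_tips(include_self=False):
            s = frozenset(t.name for t in node.tips())
            canon = s if ref not in s else leaves - s
            if canon in (clade_a, clade_b) or (leaves - canon) in (clade_a, clade_b):
                assert node.support >= 95


class TestMonophyly:
    def tree_fixture(self):
        # ((A1,A2),(B1,(A3,B2))) with unit branch lengths, via distances
        from skbio import TreeNode
        return TreeNode.read(["((A1:1,A2:1):1,(B1:1,(A3:1,B2:1):1):1):0;"])

    def test_all_leaves_trivially_monophyletic(self):
        t = self.tree_fixture()
        assert is_monophyletic(t, ["A1", "A2", "A3", "B1", "B2"], rooted=True)

    def test_paraphyletic_set_detected(self):
        t = self.tree_fixture()
        assert not is_monophyletic(t, ["A1", "A2", "A3"], rooted=True)
        assert is_monophyletic(t, ["A1", "A2"], rooted=True)
        assert is_monophyletic(t, ["A3", "B2"], rooted=True)

    def test_unknown_label_rejected(self):
        t = self.tree_fixture()
        with pytest.raises(ValueError, match="missing"):
            is_monophyletic(t, ["A1", "missing"], rooted=True)

    def test_outgroup_rooting_changes_verdict(self):
        # unrooted quartet (A,B|C,D): {B, C, D} is a clade when rooted at A
        # but not when rooted at C
        dm = dm_from_array("ABCD", [[0, 2, 5, 5],
                                    [2, 0, 5, 5],
                                    [5, 5, 0, 2],
                                    [5, 5, 2, 0]])
        tree = nj(dm)
        assert is_monophyletic(tree, ["B", "C", "D"], outgroup="A")
        assert not is_monophyletic(tree, ["B", "C", "D"], outgroup="C")


class TestDifferentiation:
    def test_fully_separated_library_succeeds(self, small_library):
        lib, _ = small_library
        tree = nj(distance_matrix(lib))
        haps, _ = collapse_haplotypes(lib)
        rep = differentiation_report(tree, haps, lib.species_of)
        assert rep.success_fraction == 1.0

    def test_shared_haplotype_fails_both_species(self, small_library):
        lib, _ = small_library
        shared = inject_shared_haplotype(lib, "species_01", "species_02")
        tree = nj(distance_matrix(shared))
        haps, _ = collapse_haplotypes(shared)
        rep = differentiation_report(tree, haps, shared.species_of)
        df = rep.per_species
        assert not df.loc[df.species == "species_01", "success"].item()
        assert not df.loc[df.species == "species_02", "success"].item()
        # (n-2)/n when the two sharing species are the only failures;
        # the donor copy may also break species_02's monophyly, which is
        # already covered by the shared-haplotype failure
        assert rep.n_success <= rep.n_species - 2

    def test_engineered_paraphyly_is_the_single_failure(self, paraphyly_library):
        lib, _ = paraphyly_library
        tree = nj(distance_matrix(lib))
        haps, _ = collapse_haplotypes(lib)
        rep = differentiation_report(tree, haps, lib.species_of)
        assert rep.n_species == 36
        assert rep.n_success == 35
        df = rep.per_species
        failed = df[~df.success]
        assert list(failed.species) == ["species_35"]
        assert failed.status.item() == "non-monophyletic"
        # the nested singleton passes on the shared-haplotype criterion alone
        single = df[df.species == "species_36"]
        assert single.status.item() == "singleton" and single.success.item()
        assert rep.success_fraction == pytest.approx(35 / 36)
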