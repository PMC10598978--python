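"""Identity matrices, UPGMA/NJ vs independent oracles, Robinson-Foulds and
the label-concordance permutation test."""

import itertools

import dendropy
import numpy as np
import pytest

from cassette_scan.phylo import (
    ConcordanceResult,
    DistanceMatrix,
    global_identity,
    identity_matrix,
    label_concordance,
    neighbor_joining,
    robinson_foulds,
    tanglegram_table,
    upgma,
)


def random_dm(n, rng, labels=None):
    vals = rng.uniform(1, 100, size=(n, n))
    D = np.triu(vals, 1)
    D = D + D.T
    return DistanceMatrix(labels or [f"t{i}" for i in range(n)], D)


def patristic(tree):
    """Leaf-to-leaf path lengths of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for a, b in itertools.combinations(sorted(tree.taxon_namespace, key=lambda t: t.label), 2):
        out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


def upgma_oracle_cophenetic(dm):
    """Average linkage straight from the definition: cluster distance is the
    mean over all leaf-pair distances; returns cophenetic distances."""
    clusters = [frozenset([i]) for i in range(len(dm))]
    coph = {}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([dm.values[i, j] for i in a for j in b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in a:
            for j in b:
                coph[frozenset((i, j))] = d
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return coph


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("MKTAYIAK", "MKTAYIAK") == 100.0

    def test_hand_alignment(self):
        # AAAA vs AAAT aligns end-to-end: 3 matches over 4 columns
        assert global_identity("AAAA", "AAAT") == 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(aas[i] for i in rng.integers(20, size=rng.integers(3, 15)))
            b = "".join(aas[i] for i in rng.integers(20, size=rng.integers(3, 15)))
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            global_identity("", "MK")


class TestIdentityMatrix:
    def test_identical_records_zero_distance(self):
        dm = identity_matrix({"a": "MKTA", "b": "MKTA"})
        assert np.allclose(dm.values, 0)

    def test_generator_blocks_separate(self, small_dataset):
        """Within-bacteriocin mean distance of the E protein is below the
        between-bacteriocin mean distance."""
        carriers = [t for t in small_dataset.truth if "mr10E" in t.gene_coords]
        prots = {t.genome_id: small_dataset.strain_proteins[t.genome_id]["mr10E"]
                 for t in carriers}
        labels = {t.genome_id: t.bacteriocin_label for t in carriers}
        dm = identity_matrix(prots)
        within, between = [], []
        ids = dm.labels
        for i, j in itertools.combinations(range(len(ids)), 2):
            (within if labels[ids[i]] == labels[ids[j]] else between).append(dm.values[i, j])
        assert np.mean(within) < np.mean(between)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        dm = random_dm(4, rng)
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)


class TestUpgma:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float))
        tree = upgma(dm)
        p = patristic(tree)
        assert p[("a", "b")] == pytest.approx(2.0)  # merged at height 1
        assert p[("a", "c")] == pytest.approx(8.0)  # c joins at height 4
        root_children = tree.seed_node.child_nodes()
        assert len(root_children) == 2

    def test_ultrametric_fixed_point(self):
        # cophenetic distances of a UPGMA tree reproduce an ultrametric input
        dm = DistanceMatrix(["a", "b", "c", "d"],
                            np.array([[0, 2, 6, 6], [2, 0, 6, 6],
                                      [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float))
        p = patristic(upgma(dm))
        for i, j in itertools.combinations(range(4), 2):
            assert p[tuple(sorted((dm.labels[i], dm.labels[j])))] == pytest.approx(
                dm.values[i, j])

    def test_matches_definition_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 6))
            dm = random_dm(n, rng)
            coph = upgma_oracle_cophenetic(dm)
            p = patristic(upgma(dm))
            for (i, j), d in ((tuple(sorted(k)), v) for k, v in coph.items()):
                assert p[(dm.labels[i], dm.labels[j])] == pytest.approx(d), dm.values

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, np.nan], [np.nan, 0]]))


class TestNeighborJoining:
    def test_additive_four_leaf_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); NJ must reproduce the path lengths
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        p = patristic(tree)
        for i, j in itertools.combinations(range(4), 2):
            assert p[(labels[i], labels[j])] == pytest.approx(D[i, j])
        # AB|CD split present
        tree.encode_bipartitions()
        splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                  for e in tree.preorder_edge_iter() if e.head_node.child_nodes()}
        assert frozenset("AB") in splits or frozenset("CD") in splits

    def test_three_leaves_star(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        p = patristic(tree)
        assert p[("a", "b")] == pytest.approx(4.0)
        assert p[("a", "c")] == pytest.approx(6.0)
        assert p[("b", "c")] == pytest.approx(8.0)

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))

    def test_label_order_invariance(self):
        rng = np.random.default_rng(3)
        dm = random_dm(5, rng)
        perm = [3, 1, 4, 0, 2]
        dm2 = DistanceMatrix([dm.labels[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        assert patristic(neighbor_joining(dm)) == pytest.approx(
            patristic(neighbor_joining(dm2)))

    def test_matches_skbio_oracle_random(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(4, 6))
            dm = random_dm(n, rng)
            mine = patristic(neighbor_joining(dm))
            sk_tree = sk_nj(SkDM(dm.values, ids=dm.labels))
            for (a, b), d in mine.items():
                assert sk_tree.find(a).distance(sk_tree.find(b)) == pytest.approx(d, abs=1e-6)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestRobinsonFoulds:
    def test_tree_vs_itself_zero(self):
        t = _tree("((a,b),(c,d));")
        assert robinson_foulds(t, _tree("((a,b),(c,d));")) == (0, 0.0)

    def test_conflicting_four_leaf_trees_maximal(self):
        rf, norm = robinson_foulds(_tree("((a,b),(c,d));"), _tree("((a,c),(b,d));"))
        assert (rf, norm) == (2, 1.0)

    def test_symmetry_and_restriction_to_shared_leaves(self):
        t1 = _tree("(((a,b),(c,d)),e);")
        t2 = _tree("((a,c),(b,d));")  # no leaf e
        assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1) == (2, 1.0)

    def test_too_few_shared_leaves_errors(self):
        with pytest.raises(ValueError):
            robinson_foulds(_tree("((a,b),(c,x));"), _tree("((a,b),(y,z));"))


class TestLabelConcordance:
    def _block_dm(self, n_labels=3, per=6, within=5.0, between=60.0):
        n = n_labels * per
        D = np.full((n, n), between)
        labels = {}
        names = []
        for g in range(n_labels):
            for k in range(per):
                names.append(f"g{g}_{k}")
                labels[f"g{g}_{k}"] = f"L{g}"
            block = slice(g * per, (g + 1) * per)
            D[block, block] = within
        np.fill_diagonal(D, 0)
        return DistanceMatrix(names, D), labels

    def test_separated_blocks_minimal_p(self):
        dm, labels = self._block_dm()
        res = label_concordance(dm, labels, n_perm=199, seed=1)
        assert res.score > 0
        assert res.p_value == pytest.approx(1 / 200)

    def test_random_labels_p_roughly_uniform(self):
        rng = np.random.default_rng(17)
        dm = random_dm(12, rng)
        ps = []
        for rep in range(40):
            labels = {l: f"L{rng.integers(2)}" for l in dm.labels}
            counts = {}
            for v in labels.values():
                counts[v] = counts.get(v, 0) + 1
            if min(counts.values(), default=0) < 2 or len(counts) < 2:
                continue
            ps.append(label_concordance(dm, labels, n_perm=99, seed=rep).p_value)
        assert 0.25 < np.mean(ps) < 0.75

    def test_singleton_labels_excluded_with_warning(self):
        dm, labels = self._block_dm(n_labels=2, per=3)
        labels[dm.labels[0]] = "solo"
        with pytest.warns(UserWarning, match="solo"):
            res = label_concordance(dm, labels, n_perm=99, seed=0)
        assert res.n_items == len(dm) - 1

    def test_all_singletons_error(self):
        dm, _ = self._block_dm(n_labels=2, per=2)
        labels = {l: f"L{i}" for i, l in enumerate(dm.labels)}
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                label_concordance(dm, labels, n_perm=99, seed=0)

    def test_bit_reproducible_given_seed(self):
        dm, labels = self._block_dm()
        a = label_concordance(dm, labels, n_perm=199, seed=42)
        b = label_concordance(dm, labels, n_perm=199, seed=42)
        assert (a.score, a.p_value) == (b.score, b.p_value)
        assert a.p_value >= 1 / 200  # invariant p >= 1/(n_perm+1)


class TestTanglegram:
    def test_identical_trees(self):
        t = "((a,b),(c,d));"
        tbl = tanglegram_table(_tree(t), _tree(t))
        assert len(tbl) == 4
        assert (tbl["genome_tree_position"] == tbl["gene_tree_position"]).all()
        assert tbl.attrs["rf"]["rf"] == 0

    def test_row_count_equals_shared_leaves(self):
        tbl = tanglegram_table(_tree("((a,b),((c,d),e));"), _tree("((a,c),(b,d));"))
        assert len(tbl) == 4

    def test_disjoint_leaves_error(self):
        with pytest.raises(ValueError):
            tanglegram_table(_tree("((a,b),(c,d));"), _tree("((w,x),(y,z));"))
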