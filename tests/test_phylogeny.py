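import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from gvannot.phylogeny import (
    Alignment, bipartitions, bootstrap_support, concat_markers,
    distance_matrix, nj_tree, progressive_align, same_topology, upgma_tree,
)
from gvannot.synthetic_data import simulate_two_clade_proteins
from oracles import sp_score, three_way_sp_oracle

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_tree_distances(rng, n_taxa):
    """Random binary tree -> (ids, additive distance matrix).

    Built by random cluster joins while tracking every leaf's depth
    within its cluster, so leaf-to-leaf path lengths are exact.
    """
    leaf_sets = [{f"t{i}"} for i in range(n_taxa)]
    depth = {f"t{i}": 0.0 for i in range(n_taxa)}
    paths = {}
    while len(leaf_sets) > 1:
        i, j = sorted(rng.choice(len(leaf_sets), size=2, replace=False))
        bi = rng.uniform(0.05, 1.0)
        bj = rng.uniform(0.05, 1.0)
        for a in leaf_sets[i]:
            depth[a] += bi
        for b in leaf_sets[j]:
            depth[b] += bj
        for a in leaf_sets[i]:
            for b in leaf_sets[j]:
                paths[frozenset((a, b))] = depth[a] + depth[b]
        leaf_sets[i] |= leaf_sets[j]
        del leaf_sets[j]
    ids = sorted(depth)
    D = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            D[x, y] = D[y, x] = paths[frozenset((ids[x], ids[y]))]
    return ids, D


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        aln = progressive_align({"a": "MKV" * 10, "b": "MKV" * 10, "c": "MKV" * 10})
        assert all("-" not in s for s in aln.seqs.values())
        assert aln.n_cols == 30

    def test_single_deletion(self):
        aln = progressive_align({"x": "ACD", "y": "AD"})
        assert aln.n_cols == 3
        assert aln.seqs["x"] == "ACD" and aln.seqs["y"] == "A-D"

    def test_fewer_than_two_sequences_errors(self):
        with pytest.raises(ValueError):
            progressive_align({"only": "MKV"})

    @pytest.mark.parametrize("trio", [
        ("MKVLA", "MKVA", "MKVLA"),
        ("ACDEFGHIK", "ACDEGHIK", "ACDFGHIK"),
        ("WWCPN", "WWPN", "WCPN"),
    ])
    def test_sum_of_pairs_at_least_exhaustive_dp(self, trio):
        """On easy <=10-residue trios the heuristic reaches the 3-way DP optimum."""
        from Bio.Align import substitution_matrices
        bl = substitution_matrices.load("BLOSUM62")
        score_pair = lambda a, b: float(bl[a][b])
        gap = 4.0
        aln = progressive_align(dict(zip("abc", trio)))
        ours = sp_score([aln.seqs[t] for t in "abc"], score_pair, gap)
        best = three_way_sp_oracle(*trio, score_pair=score_pair, gap=gap)
        assert ours >= best - 1e-9


class TestConcat:
    def _aln(self, taxa, width, fill="A"):
        return Alignment(taxa=list(taxa), seqs={t: fill * width for t in taxa})

    def test_widths_add(self):
        markers = {"m1": self._aln("ab", 100), "m2": self._aln("ab", 200),
                   "m3": self._aln("ab", 150)}
        cat = concat_markers(markers)
        assert cat.n_cols == 450
        assert [p[1:] for p in cat.partitions] == [(0, 100), (100, 300), (300, 450)]

    def test_missing_marker_gets_all_gap_row(self):
        markers = {"m1": self._aln("abc", 10), "m2": self._aln("ab", 5)}
        with pytest.warns(UserWarning, match="missing marker"):
            cat = concat_markers(markers)
        assert cat.seqs["c"][10:] == "-" * 5

    def test_disjoint_taxa_error(self):
        markers = {"m1": self._aln("ab", 10), "m2": self._aln("cd", 10)}
        with pytest.raises(ValueError, match="share no taxa"):
            concat_markers(markers)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        seqs = {t: "".join(rng.choice(AA, 30)) for t in "abcd"}
        m1 = progressive_align(seqs)
        m2 = progressive_align(dict(reversed(list(seqs.items()))))
        cat1 = concat_markers({"x": m1})
        cat2 = concat_markers({"x": m2})
        assert {t: cat1.seqs[t] for t in "abcd"} == {t: cat2.seqs[t] for t in "abcd"}


class TestDistances:
    def test_closed_form_examples(self):
        aln = Alignment(taxa=["a", "b"], seqs={"a": "AAAAAAAAAA", "b": "AAAAAAAACC"})
        dm_p = distance_matrix(aln, model="p-distance")
        assert dm_p["a", "b"] == pytest.approx(0.2)
        dm_poi = distance_matrix(aln, model="poisson")
        assert dm_poi["a", "b"] == pytest.approx(-math.log(0.8), abs=1e-12)
        ident = Alignment(taxa=["a", "b"], seqs={"a": "MKV", "b": "MKV"})
        assert distance_matrix(ident)["a", "b"] == 0.0

    def test_pairwise_deletion_counting_oracle(self):
        rng = np.random.default_rng(6)
        taxa = list("abcd")
        seqs = {}
        for t in taxa:
            row = rng.choice(AA + ["-"], size=80, p=[0.9 / 20] * 20 + [0.1])
            seqs[t] = "".join(row)
        aln = Alignment(taxa=taxa, seqs=seqs)
        dm = distance_matrix(aln, model="p-distance")
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                comp = [(x, y) for x, y in zip(seqs[a], seqs[b])
                        if x != "-" and y != "-"]
                mism = sum(1 for x, y in comp if x != y)
                assert dm[a, b] == pytest.approx(mism / len(comp))

    def test_no_comparable_sites_errors(self):
        aln = Alignment(taxa=["a", "b"], seqs={"a": "A-", "b": "-A"})
        with pytest.raises(ValueError, match="no comparable sites"):
            distance_matrix(aln)


class TestTreeBuilding:
    def test_nj_three_taxon_closed_form(self):
        D = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]),
                           ids=["a", "b", "c"])
        t = nj_tree(D)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["a"] == pytest.approx((3 + 5 - 6) / 2)
        assert lengths["b"] == pytest.approx((3 + 6 - 5) / 2)
        assert lengths["c"] == pytest.approx((5 + 6 - 3) / 2)

    def test_nj_exact_on_additive_five_taxon_matrix(self):
        rng = np.random.default_rng(17)
        ids, D = _random_tree_distances(rng, 5)
        t = nj_tree(DistanceMatrix(D, ids=ids))
        # recovered tree reproduces all pairwise path lengths exactly
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                tip = t.find(a)
                assert t.find(a).distance(t.find(b)) == pytest.approx(
                    D[ids.index(a), ids.index(b)], abs=1e-9)

    def test_nj_topology_matches_skbio(self):
        rng = np.random.default_rng(23)
        ids, D = _random_tree_distances(rng, 8)
        from skbio.tree import nj as skbio_nj
        dm = DistanceMatrix(D, ids=ids)
        assert same_topology(nj_tree(dm), skbio_nj(dm))

    def test_nj_rejects_asymmetric_input(self):
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(Exception):
            nj_tree(DistanceMatrix(bad, ids=list("abc")))

    def test_upgma_recovers_ultrametric_tree(self):
        D = DistanceMatrix(np.array([
            [0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0.0]]),
            ids=list("abcd"))
        t = upgma_tree(D)
        assert bipartitions(t) == {frozenset({"c", "d"})}
        depths = [t.distance(tip) for tip in t.tips()]
        assert all(d == pytest.approx(3.0, abs=1e-12) for d in depths)  # max d / 2

    def test_upgma_is_ultrametric_on_random_input(self):
        rng = np.random.default_rng(31)
        n = 9
        M = rng.uniform(0.1, 2.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        t = upgma_tree(DistanceMatrix(D, ids=[f"t{i}" for i in range(n)]))
        depths = [t.distance(tip) for tip in t.tips()]
        assert max(depths) - min(depths) <= 1e-9


class TestBootstrap:
    def test_same_seed_reproduces_supports(self):
        seqs = simulate_two_clade_proteins(seed=2)
        aln = progressive_align(seqs)
        _, s1 = bootstrap_support(aln, n_reps=50, seed=9)
        _, s2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert s1 == s2

    def test_identical_sequences_star_tree_convention(self):
        aln = Alignment(taxa=list("abcd"), seqs={t: "MKVLL" * 8 for t in "abcd"})
        tree, supports = bootstrap_support(aln, n_reps=20, seed=1)
        # zero-length internal edges carry whatever support; all distances 0
        for tip in tree.tips():
            assert tree.distance(tip) == pytest.approx(0.0)

    def test_two_clade_split_strongly_supported(self):
        seqs = simulate_two_clade_proteins(n_per_clade=3, length=200,
                                           d_within=0.03, d_between=0.5, seed=5)
        aln = progressive_align(seqs)
        tree, supports = bootstrap_support(aln, n_reps=200, seed=11)
        clade_b = frozenset({"B1", "B2", "B3"})
        assert clade_b in supports
        assert supports[clade_b] >= 0.95

    def test_support_labels_written_to_newick(self):
        seqs = simulate_two_clade_proteins(seed=3)
        aln = progressive_align(seqs)
        tree, supports = bootstrap_support(aln, n_reps=30, seed=2)
        nwk = str(tree)
        assert any(f"{v:.2f}" in nwk for v in supports.values())
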