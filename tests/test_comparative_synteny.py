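import numpy as np
import pytest

from gvannot.comparative_synteny import (
    OrthologPair, OrthologTable, core_gene_audit, load_core_gene_reference,
    name_repeated_genes, pair_orthologs, synteny_blocks,
)
from gvannot.genome_io import GeneAnnotation, OrfRecord
from gvannot.synthetic_data import perturb_gene_order

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_proteins(rng, n, length=120):
    return {i + 1: "".join(rng.choice(AA, size=length)) for i in range(n)}


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AA if a != out[i]])
    return "".join(out)


def _annotation(n, gene_nt=300, spacer=50):
    feats = []
    pos = 1
    for i in range(n):
        feats.append(OrfRecord(start=pos, end=pos + gene_nt - 1, strand="+",
                               serial=i + 1))
        pos += gene_nt + spacer
    return GeneAnnotation(genome_id="x", features=feats)


class TestOrthologPairing:
    def test_genome_vs_itself_is_identity(self):
        rng = np.random.default_rng(0)
        prots = _random_proteins(rng, 12)
        table = pair_orthologs(prots, prots)
        assert [(r.a_serial, r.b_serial) for r in table.rows] == \
               [(i, i) for i in sorted(prots)]
        assert all(r.similarity == pytest.approx(1.0) for r in table.rows)

    def test_mutated_counterparts_all_paired(self):
        rng = np.random.default_rng(1)
        prots_a = _random_proteins(rng, 30, length=100)
        prots_b = {k: _mutate(rng, v, 0.10) for k, v in prots_a.items()}
        table = pair_orthologs(prots_a, prots_b, min_similarity=0.5)
        assert {(r.a_serial, r.b_serial) for r in table.rows} == \
               {(i, i) for i in prots_a}

    def test_disjoint_sets_yield_empty_table(self):
        assert len(pair_orthologs({}, {})) == 0
        rng = np.random.default_rng(2)
        a = _random_proteins(rng, 5, 60)
        b = {k: v for k, v in _random_proteins(rng, 5, 60).items()}
        table = pair_orthologs(a, b, min_similarity=0.6)
        assert len(table) == 0  # unrelated randoms fall below the cutoff


class TestSyntenyBlocks:
    def test_identical_orders_one_same_block(self):
        ann = _annotation(10)
        table = OrthologTable(rows=[OrthologPair(i, i, 1.0) for i in range(1, 11)])
        blocks = synteny_blocks(ann, ann, table)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same" and blocks[0].n_genes == 10
        assert blocks[0].a_span == (1, ann.features[-1].end)

    def test_constructed_middle_inversion_gives_three_blocks(self):
        ann_a = _annotation(10)
        order = [1, 2, 3, 7, 6, 5, 4, 8, 9, 10]
        table = OrthologTable(rows=[
            OrthologPair(s, order.index(s) + 1, 1.0) for s in range(1, 11)])
        ann_b = _annotation(10)
        blocks = synteny_blocks(ann_a, ann_b, table)
        assert [(b.n_genes, b.orientation) for b in blocks] == \
               [(3, "same"), (4, "inverted"), (3, "same")]

    @pytest.mark.parametrize("lo,hi", [(2, 5), (1, 4), (5, 12), (3, 10), (6, 7)])
    def test_single_inversion_recovered_across_endpoints(self, lo, hi):
        """With strict adjacency (max_gap_genes=0) any inversion span,
        including a 2-gene one, yields exactly the truth blocks; the
        default gap allowance may absorb inversions shorter than
        max_gap_genes + 2 as skips."""
        n = 12
        ann_a = _annotation(n)
        ann_b, truth_blocks = perturb_gene_order(ann_a, [(lo, hi)])
        # mapping: original serial s sits at position p in the perturbed order
        perm = list(range(1, lo)) + list(range(hi, lo - 1, -1)) + list(range(hi + 1, n + 1))
        table = OrthologTable(rows=[
            OrthologPair(s, perm.index(s) + 1, 1.0) for s in range(1, n + 1)])
        blocks = synteny_blocks(ann_a, ann_b, table, max_gap_genes=0)
        assert len(blocks) == len(truth_blocks)
        inv = [b for b in blocks if b.orientation == "inverted"]
        assert len(inv) == 1 and inv[0].n_genes == hi - lo + 1

    def test_blocks_partition_the_pairs(self):
        ann_a = _annotation(12)
        ann_b, _ = perturb_gene_order(ann_a, [(3, 6), (9, 11)])
        perm = [1, 2, 6, 5, 4, 3, 7, 8, 11, 10, 9, 12]
        table = OrthologTable(rows=[
            OrthologPair(s, perm.index(s) + 1, 1.0) for s in range(1, 13)])
        blocks = synteny_blocks(ann_a, ann_b, table)
        seen = [p for b in blocks for p in b.pairs]
        assert sorted((p.a_serial, p.b_serial) for p in seen) == \
               sorted((r.a_serial, r.b_serial) for r in table.rows)


class TestCoreGeneAudit:
    def test_reference_list_has_37_names(self):
        assert len(load_core_gene_reference()) == 37

    def test_full_and_partial_presence(self):
        ref = load_core_gene_reference()
        names = sorted(ref)
        full = GeneAnnotation(genome_id="g", features=[
            OrfRecord(start=100 * i + 1, end=100 * i + 90, strand="+",
                      serial=i + 1, label=nm) for i, nm in enumerate(names)])
        audit = core_gene_audit(full)
        assert (audit.n_present, audit.n_absent) == (37, 0)
        partial = GeneAnnotation(genome_id="g", features=full.features[:10])
        audit10 = core_gene_audit(partial)
        assert (audit10.n_present, audit10.n_absent) == (10, 27)
        empty = core_gene_audit(GeneAnnotation(genome_id="g"))
        assert empty.n_present == 0

    def test_alias_matching(self):
        ann = GeneAnnotation(genome_id="g", features=[
            OrfRecord(start=1, end=90, strand="+", serial=1, label="odv-e56")])
        audit = core_gene_audit(ann)
        assert audit.status["pif-5"] == (True, 1)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            core_gene_audit(GeneAnnotation(genome_id="g"), reference={})


class TestRepeatedGeneNaming:
    def test_two_members_by_genome_order(self):
        feats = [OrfRecord(start=1, end=90, strand="+", serial=65, label="bro"),
                 OrfRecord(start=101, end=190, strand="+", serial=94, label="bro")]
        ann = GeneAnnotation(genome_id="g", features=feats)
        named = name_repeated_genes(ann, "bro")
        assert [f.label for f in named.features] == ["bro-a", "bro-b"]

    def test_single_member_gets_suffix_a(self):
        ann = GeneAnnotation(genome_id="g", features=[
            OrfRecord(start=1, end=90, strand="+", serial=3, label="bro")])
        assert name_repeated_genes(ann, "bro").features[0].label == "bro-a"

    def test_shuffled_members_follow_serial_order(self):
        rng = np.random.default_rng(4)
        serials = [40, 7, 93, 21, 64]
        feats = [OrfRecord(start=100 * i + 1, end=100 * i + 90, strand="+",
                           serial=s, label="bro") for i, s in enumerate(serials)]
        rng.shuffle(feats)
        named = name_repeated_genes(GeneAnnotation(genome_id="g", features=feats), "bro")
        by_serial = {f.serial: f.label for f in named.features}
        for suffix, serial in zip("abcde", sorted(serials)):
            assert by_serial[serial] == f"bro-{suffix}"

    def test_absent_family_errors(self):
        with pytest.raises(ValueError):
            name_repeated_genes(GeneAnnotation(genome_id="g"), "bro")
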