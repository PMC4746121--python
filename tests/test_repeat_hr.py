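import numpy as np
import pytest

from gvannot.genome_io import CircularGenome, GeneAnnotation, OrfRecord
from gvannot.repeat_hr import (
    PalindromeCall, classify_repeat_placement, cluster_hrs,
    dedupe_palindromes, find_palindromes, find_palindromes_genome,
    find_tandem_repeats, repeat_genome_fraction,
)
from conftest import random_dna
from oracles import palindrome_oracle, rc


def _genome(seq, circular=False):
    return CircularGenome(id="t", seq=seq, circular=circular)


def _rotations(u):
    return {u[i:] + u[:i] for i in range(len(u))}


class TestTandemRepeats:
    def test_perfect_triplet_array(self):
        calls = find_tandem_repeats(_genome("GGTCAT" + "ACG" * 3 + "GGTCAT"),
                                    min_len=9, min_copies=3)
        assert len(calls) == 1
        c = calls[0]
        assert c.unit_len == 3 and c.copy_number == 3.0
        assert c.consensus_unit in _rotations("ACG")
        assert c.percent_identity == 1.0

    def test_fractional_copy_number(self):
        # (CAGT) x 5 + CA -> 5.5 copies
        seq = "TTGGA" + "CAGT" * 5 + "CA" + "TTGGA"
        calls = find_tandem_repeats(_genome(seq), min_len=20, min_copies=3)
        assert any(c.unit_len == 4 and c.copy_number == 5.5 for c in calls)

    def test_planted_arrays_in_random_sequence_recovered(self):
        rng = np.random.default_rng(20)
        bg = random_dna(rng, 5000, gc=0.4)
        units = ["GATCCTA", "ACGGATTGCAT", "TGCATGGACGTTACA",
                 "GGATACCAGTTACGAATTCCGGATTA", "CCGTAAGGATCACCAGTTGACGTATGACGGTATACCAGGATTACCGGTTAGGCCAATTCG"]
        copies = [4.0, 3.0, 5.0, 3.5, 3.2]
        pos = [300, 1200, 2200, 3200, 4100]
        seq = list(bg)
        truth = []
        for u, cp, p in zip(units, copies, pos):
            span = int(round(len(u) * cp))
            arr = (u * (span // len(u) + 1))[:span]
            seq[p: p + span] = arr
            truth.append((p + 1, span, len(u), cp))
        genome = _genome("".join(seq))
        calls = find_tandem_repeats(genome)
        for start, span, ulen, cp in truth:
            match = [c for c in calls
                     if abs(c.start - start) <= 2 and c.unit_len == ulen]
            assert match, f"array at {start} (unit {ulen}) not recovered"
            assert abs(match[0].copy_number - cp) <= 0.2

    def test_no_calls_on_shuffled_background(self):
        rng = np.random.default_rng(21)
        seq = random_dna(rng, 50_000, gc=0.35)
        calls = find_tandem_repeats(_genome(seq))
        assert len(calls) <= 1  # empirical false-positive bound per 50 kb

    def test_harmonic_suppression_prefers_smallest_unit(self):
        seq = "GGTAC" + "AT" * 20 + "GGTCC"
        calls = find_tandem_repeats(_genome(seq), min_len=12, min_copies=3)
        assert len(calls) == 1
        assert calls[0].unit_len <= 2

    def test_circular_array_spanning_origin_called_once(self):
        arr = "GATCCTA" * 5
        seq = arr[17:] + random_dna(np.random.default_rng(3), 500, 0.4) + arr[:17]
        calls = find_tandem_repeats(_genome(seq, circular=True))
        spanning = [c for c in calls if c.unit_len == 7]
        assert len(spanning) == 1
        assert abs(spanning[0].copy_number - 5.0) <= 0.2

    def test_planted_default_genome_arrays_exact(self, default_sim):
        genome, truth = default_sim
        calls = find_tandem_repeats(genome)
        got = {(c.start, c.end): c for c in calls}
        assert set(got) == {(r.start, r.end) for r in truth.repeats}
        for r in truth.repeats:
            c = got[(r.start, r.end)]
            assert c.unit_len == r.unit_len
            assert abs(c.copy_number - r.copy_number) <= 0.2
            assert c.consensus_unit in _rotations(r.consensus_unit)


class TestPlacement:
    def test_coding_noncoding_both(self):
        ann = GeneAnnotation(genome_id="t", features=[
            OrfRecord(start=101, end=400, strand="+", serial=1)])
        from gvannot.repeat_hr import RepeatCall

        def call(s, e):
            return RepeatCall(start=s, end=e, unit_len=3, copy_number=3.0,
                              consensus_unit="ACG", percent_identity=1.0)

        reps = classify_repeat_placement(
            [call(150, 200), call(500, 550), call(380, 420)], ann, 1000)
        assert [r.placement for r in reps] == ["coding", "noncoding", "both"]

    def test_default_genome_placements_match_truth(self, default_sim):
        genome, truth = default_sim
        calls = classify_repeat_placement(
            find_tandem_repeats(genome), truth.orfs, genome.length)
        got = {(c.start, c.end): c.placement for c in calls}
        for r in truth.repeats:
            assert got[(r.start, r.end)] == r.placement


class TestGenomeFraction:
    def test_trivial_cases(self):
        genome = _genome("A" * 112_000, circular=True)
        assert repeat_genome_fraction([], genome) == 0.0
        from gvannot.repeat_hr import RepeatCall
        one = RepeatCall(start=1, end=1120, unit_len=10, copy_number=112.0,
                         consensus_unit="A" * 10, percent_identity=1.0)
        assert repeat_genome_fraction([one], genome) == pytest.approx(1.0)
        # overlapping calls counted once
        two = RepeatCall(start=561, end=1680, unit_len=10, copy_number=112.0,
                         consensus_unit="A" * 10, percent_identity=1.0)
        assert repeat_genome_fraction([one, two], genome) == pytest.approx(1.5)


class TestPalindromes:
    def test_perfect_restriction_site(self):
        calls = find_palindromes("GAATTC", min_arm=3, max_loop=0, max_mismatch=0)
        assert len(calls) == 1
        c = calls[0]
        assert (c.arm_len, c.loop_len, c.mismatches, c.start, c.end) == (3, 0, 0, 1, 6)

    def test_homopolymer_is_not_a_palindrome(self):
        assert find_palindromes("A" * 8, min_arm=2, max_loop=4, max_mismatch=0) == []

    @pytest.mark.parametrize("seed,params", [
        (0, dict(min_arm=4, max_loop=6, max_mismatch=1)),
        (1, dict(min_arm=8, max_loop=20, max_mismatch=2)),
        (2, dict(min_arm=3, max_loop=3, max_mismatch=0)),
        (3, dict(min_arm=6, max_loop=10, max_mismatch=2)),
    ])
    def test_matches_bruteforce_oracle(self, seed, params):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 300, gc=0.4)
        got = {(c.center, c.loop_len, c.arm_len, c.mismatches)
               for c in find_palindromes(seq, **params)}
        assert got == palindrome_oracle(seq, params["min_arm"],
                                        params["max_loop"], params["max_mismatch"])

    def test_imperfect_palindrome_mismatch_count(self):
        left = "GGGGATCC"
        right = list(rc(left))
        right[3] = "A" if right[3] != "A" else "C"
        seq = "TT" + left + "AAAA" + "".join(right) + "TT"
        calls = find_palindromes(seq, min_arm=8, max_loop=6, max_mismatch=2)
        assert any(c.arm_len >= 8 and c.mismatches == 1 for c in calls)


class TestHrClustering:
    def _pal(self, start, end):
        return PalindromeCall(center=start + 10, arm_len=10, loop_len=4,
                              mismatches=0, start=start, end=end)

    def test_three_planted_cassettes(self):
        genome = _genome("A" * 50_000, circular=True)
        pals = []
        for base in (1000, 20_000, 40_000):
            for k in range(4):
                s = base + 60 * k
                pals.append(self._pal(s, s + 30))
        regions = cluster_hrs(pals, genome, cluster_gap=1000, min_cluster=2)
        assert [r.n_palindromes for r in regions] == [4, 4, 4]
        assert [r.hr_id for r in regions] == ["hr1", "hr2", "hr3"]

    def test_isolated_palindrome_is_not_an_hr(self):
        genome = _genome("A" * 10_000, circular=True)
        regions = cluster_hrs([self._pal(5000, 5030)], genome,
                              cluster_gap=1000, min_cluster=2)
        assert regions == []

    def test_wraparound_cluster_merged(self):
        genome = _genome("A" * 10_000, circular=True)
        pals = [self._pal(9900, 9930), self._pal(50, 80), self._pal(150, 180)]
        regions = cluster_hrs(pals, genome, cluster_gap=500, min_cluster=3)
        assert len(regions) == 1 and regions[0].n_palindromes == 3

    def test_regions_are_disjoint_and_in_bounds(self, default_sim):
        genome, _ = default_sim
        pals = dedupe_palindromes(
            find_palindromes_genome(genome, min_arm=13, max_mismatch=2))
        regions = cluster_hrs(pals, genome, cluster_gap=200, min_cluster=3)
        spans = sorted((r.start, r.end) for r in regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for s, e in spans:
            assert 1 <= s <= genome.length and e <= 2 * genome.length

    def test_default_genome_hrs_match_truth(self, default_sim):
        genome, truth = default_sim
        pals = dedupe_palindromes(
            find_palindromes_genome(genome, min_arm=13, max_mismatch=2))
        regions = cluster_hrs(pals, genome, cluster_gap=200, min_cluster=3)
        assert [(r.start, r.end, r.n_palindromes) for r in regions] == truth.hr_spans
        # the AT-rich character of hr cassettes is preserved
        assert all(r.at_content > 0.6 for r in regions)
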