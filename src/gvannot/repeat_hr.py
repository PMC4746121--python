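"""Tandem repeats, imperfect palindromes and homologous regions (hrs).

Tandem repeats are found by per-period self-match profiling: for every
candidate period p the genome is compared against its own p-shift, and
maximal high-identity stretches (identity-fraction threshold rather
than an alignment score, to keep the algorithm transparent) become
repeat calls with fractional copy numbers.  Circularity is handled by
scanning the doubled sequence and discarding duplicate calls.

Imperfect palindromes are inverted repeats whose arms reverse-
complement each other up to a bounded number of substitutions,
optionally separated by a loop.  For every (position, loop) the single
maximal call is reported: the largest arm whose outermost and
innermost base pairs match and whose total mismatches stay within the
bound.  Homologous regions (hrs) are single-linkage clusters of
palindromes along the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np

from .genome_io import CircularGenome, GeneAnnotation
from .composition import at_content
from .orf_annotation import _merged_union, _segments

__all__ = [
    "RepeatCall",
    "PalindromeCall",
    "HrRegion",
    "find_tandem_repeats",
    "classify_repeat_placement",
    "repeat_genome_fraction",
    "find_palindromes",
    "dedupe_palindromes",
    "cluster_hrs",
]


@dataclass
class RepeatCall:
    start: int            # 1-based inclusive
    end: int              # may exceed L for origin-wrapping calls
    unit_len: int
    copy_number: float    # rounded to 0.1
    consensus_unit: str
    percent_identity: float
    placement: str = ""   # "coding" | "noncoding" | "both"

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PalindromeCall:
    center: int           # 1-based position of the first loop base
    arm_len: int
    loop_len: int
    mismatches: int
    start: int            # 1-based inclusive span of the whole palindrome
    end: int

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class HrRegion:
    hr_id: str
    start: int
    end: int
    n_palindromes: int
    at_content: float
    palindromes: tuple[PalindromeCall, ...]


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def _best_scoring_run(m: np.ndarray, lo: int, hi: int, min_identity: float) -> tuple[int, int] | None:
    """Maximum-score segment of m[lo:hi] under match +1 / mismatch
    -min_identity/(1-min_identity) scoring (Kadane).

    With that penalty every prefix and suffix of the optimum keeps
    identity >= min_identity, so calls cannot creep across array
    boundaries by absorbing terminal mismatches.  Ties prefer the
    longer, then the leftmost segment; the optimum necessarily starts
    and ends on a match.
    """
    w = min_identity / max(1e-9, 1.0 - min_identity)
    best = None  # (score, length, start, end) inclusive local coords
    cur_score, cur_start = 0.0, 0
    for k in range(hi - lo):
        val = 1.0 if m[lo + k] else -w
        if cur_score <= 0:
            cur_score, cur_start = val, k
        else:
            cur_score += val
        if cur_score > 0:
            length = k - cur_start + 1
            if (best is None or cur_score > best[0] + 1e-9
                    or (abs(cur_score - best[0]) <= 1e-9 and length > best[1])):
                best = (cur_score, length, cur_start, k)
    if best is None:
        return None
    _, _, i, j = best
    while i < j and m[lo + i] == 0:
        i += 1
    while j > i and m[lo + j] == 0:
        j -= 1
    if j < i or not m[lo + i]:
        return None
    return lo + i, lo + j  # inclusive


def _consensus_unit(s2: str, i: int, p: int, n_copies: int) -> str:
    out = []
    for k in range(p):
        col = [s2[i + k + c * p] for c in range(n_copies) if i + k + c * p < len(s2)]
        out.append(max(sorted(set(col)), key=col.count))
    return "".join(out)


def find_tandem_repeats(
    genome: CircularGenome,
    min_unit: int = 1,
    max_unit: int = 500,
    min_copies: float = 3.0,
    min_len: int = 24,
    min_identity: float = 0.8,
) -> list[RepeatCall]:
    """Identity-threshold tandem-repeat scan over all periods.

    Copy number = span / unit length, reported to 0.1 (fractional final
    copies allowed).  Harmonic calls (period 2u shadowing period u at
    equal identity) are suppressed in favour of the smaller unit.
    """
    L = genome.length
    s2 = genome.seq + genome.seq if genome.circular else genome.seq
    arr = np.frombuffer(s2.encode(), dtype=np.uint8)
    n = len(arr)
    raw: list[RepeatCall] = []
    for p in range(min_unit, min(max_unit, L - 1 if genome.circular else n - 1) + 1):
        if n <= p:
            break
        m = (arr[:-p] == arr[p:]).astype(np.uint8)
        need = max(min_len, int(ceil(min_copies * p))) - p
        need = max(need, 1)
        if len(m) < need:
            continue
        cs = np.concatenate([[0], np.cumsum(m, dtype=np.int64)])
        winsum = cs[need:] - cs[:-need]
        hot = np.flatnonzero(winsum >= ceil(min_identity * need) - 1e-9)
        if hot.size == 0:
            continue
        # group hot starts into candidate windows
        breaks = np.flatnonzero(np.diff(hot) > need)
        groups = np.split(hot, breaks + 1)
        for g in groups:
            lo = max(0, int(g[0]) - p)
            hi = min(len(m), int(g[-1]) + need + p)
            run = _best_scoring_run(m, lo, hi, min_identity)
            if run is None:
                continue
            i, j = run
            span = j - i + 1 + p
            copies = span / p
            if span < min_len or copies + 1e-9 < min_copies or span > L:
                continue
            ident = float(np.mean(m[i : j + 1]))
            if ident + 1e-9 < min_identity:
                continue
            raw.append(RepeatCall(
                start=i + 1, end=i + span, unit_len=p,
                copy_number=round(copies, 1),
                consensus_unit=_consensus_unit(s2, i, p, int(copies)),
                percent_identity=ident,
            ))
    return _dedupe_repeats(raw, L, circular=genome.circular)


def _span_overlap(a: RepeatCall, b: RepeatCall) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _dedupe_repeats(raw: list[RepeatCall], L: int, circular: bool) -> list[RepeatCall]:
    if circular:
        # collapse duplicate calls from the doubled sequence
        seen: dict[tuple[int, int], RepeatCall] = {}
        for c in raw:
            if c.start > L:
                key = ((c.start - 1 - L) % L + 1, c.unit_len)
                c = replace(c, start=c.start - L, end=c.end - L)
            key = (c.start, c.unit_len)
            prev = seen.get(key)
            if prev is None or c.span_nt > prev.span_nt:
                seen[key] = c
        raw = list(seen.values())
    # prefer smaller units at equal (or better) identity among overlapping calls
    raw.sort(key=lambda c: (-c.span_nt, c.unit_len, c.start))
    kept: list[RepeatCall] = []
    for c in raw:
        redundant = False
        for k in kept:
            ov = _span_overlap(c, k)
            if ov >= 0.5 * c.span_nt:
                if k.unit_len <= c.unit_len and k.percent_identity >= c.percent_identity - 0.05:
                    redundant = True
                    break
                if c.unit_len % k.unit_len == 0 and k.percent_identity >= c.percent_identity - 0.05:
                    redundant = True
                    break
        if not redundant:
            kept.append(c)
    # second pass: drop larger-unit harmonics that survived ordering
    final: list[RepeatCall] = []
    for c in sorted(kept, key=lambda c: (c.unit_len, -c.span_nt, c.start)):
        if any(
            _span_overlap(c, k) >= 0.5 * min(c.span_nt, k.span_nt)
            and c.unit_len % k.unit_len == 0
            and c.unit_len > k.unit_len
            and k.percent_identity >= c.percent_identity - 0.05
            for k in final
        ):
            continue
        final.append(c)
    final.sort(key=lambda c: (c.start, c.unit_len))
    return final


def classify_repeat_placement(
    repeats: list[RepeatCall], annotation: GeneAnnotation, genome_length: int
) -> list[RepeatCall]:
    """Set placement: coding (inside an ORF), noncoding (outside all), both."""
    merged = _merged_union(annotation, genome_length)

    def _cov(seg: tuple[int, int]) -> int:
        s, e = seg
        return sum(max(0, min(e, me) - max(s, ms)) for ms, me in merged)

    out = []
    for r in repeats:
        segs = []
        s0, e0 = r.start - 1, r.end
        if e0 <= genome_length:
            segs = [(s0, e0)]
        else:
            segs = [(s0, genome_length), (0, e0 - genome_length)]
        cov = sum(_cov(seg) for seg in segs)
        if cov == r.span_nt:
            placement = "coding"
        elif cov == 0:
            placement = "noncoding"
        else:
            placement = "both"
        out.append(replace(r, placement=placement))
    return out


def repeat_genome_fraction(repeats: list[RepeatCall], genome: CircularGenome) -> float:
    """Percentage of the genome covered by the union of repeat spans."""
    L = genome.length
    segs: list[tuple[int, int]] = []
    for r in repeats:
        s0, e0 = r.start - 1, r.end
        if e0 <= L:
            segs.append((s0, e0))
        else:
            segs.extend([(s0, L), (0, e0 - L)])
    if not segs:
        return 0.0
    segs.sort()
    covered, cur_s, cur_e = 0, *segs[0]
    for s, e in segs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return 100.0 * covered / L


# ---------------------------------------------------------------------------
# imperfect palindromes
# ---------------------------------------------------------------------------

_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def find_palindromes(
    seq: str,
    min_arm: int = 8,
    max_loop: int = 20,
    max_mismatch: int = 2,
    max_arm: int | None = None,
) -> list[PalindromeCall]:
    """All maximal imperfect palindromes of a linear sequence.

    For each (center, loop) the call is the largest arm a such that the
    left arm reverse-complements the right arm with at most
    ``max_mismatch`` substitutions and both the outermost and innermost
    base pairs match; only arms >= ``min_arm`` are reported.
    """
    n = len(seq)
    if n == 0 or min_arm < 1:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = _COMP_LUT[arr]
    cap = (n // 2) if max_arm is None else max_arm
    calls: list[PalindromeCall] = []
    for loop in range(0, max_loop + 1):
        # center i = index of first loop base (left arm ends at i-1,
        # right arm starts at i+loop); pair k: seq[i-k] vs comp(seq[i+loop+k-1])
        idx = np.arange(n)
        cum = np.zeros(n, dtype=np.int32)
        inner_ok = np.zeros(n, dtype=bool)
        best_arm = np.zeros(n, dtype=np.int32)
        best_mm = np.zeros(n, dtype=np.int32)
        alive = np.ones(n, dtype=bool)
        for k in range(1, cap + 1):
            li = idx - k
            ri = idx + loop + k - 1
            valid = (li >= 0) & (ri < n)
            match = np.zeros(n, dtype=bool)
            vv = np.flatnonzero(valid)
            match[vv] = arr[li[vv]] == comp[ri[vv]]
            cum = cum + (valid & ~match)  # out-of-range pairs kill via alive
            alive &= valid
            if k == 1:
                inner_ok = match.copy()
            ok = alive & inner_ok & match & (cum <= max_mismatch)
            sel = ok
            best_arm[sel] = k
            best_mm[sel] = cum[sel]
            alive &= cum <= max_mismatch
            if not alive.any():
                break
        hits = np.flatnonzero(best_arm >= min_arm)
        for i in hits:
            a = int(best_arm[i])
            calls.append(PalindromeCall(
                center=int(i) + 1, arm_len=a, loop_len=loop,
                mismatches=int(best_mm[i]),
                start=int(i) - a + 1, end=int(i) + loop + a,
            ))
    calls.sort(key=lambda c: (c.start, c.end, c.loop_len))
    return calls


def find_palindromes_genome(
    genome: CircularGenome,
    min_arm: int = 8,
    max_loop: int = 20,
    max_mismatch: int = 2,
    max_arm: int | None = 60,
) -> list[PalindromeCall]:
    """Palindrome scan of a genome; circular genomes are scanned doubled
    and duplicate calls (center beyond L) discarded."""
    if not genome.circular:
        return find_palindromes(genome.seq, min_arm, max_loop, max_mismatch, max_arm)
    L = genome.length
    ext = genome.seq + genome.seq[: min(L, 2 * (max_arm or 60) + max_loop + 2)]
    calls = find_palindromes(ext, min_arm, max_loop, max_mismatch, max_arm)
    return [c for c in calls if 1 <= c.center <= L]


def dedupe_palindromes(calls: list[PalindromeCall]) -> list[PalindromeCall]:
    """Collapse overlapping calls of one locus: keep longest arm, then
    fewest mismatches, then smallest loop, earliest start; drop any call
    overlapping a kept one."""
    order = sorted(calls, key=lambda c: (-c.arm_len, c.mismatches, c.loop_len, c.start))
    kept: list[PalindromeCall] = []
    for c in order:
        if all(min(c.end, k.end) - max(c.start, k.start) < 0 for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


# ---------------------------------------------------------------------------
# homologous regions
# ---------------------------------------------------------------------------

def cluster_hrs(
    palindromes: list[PalindromeCall],
    genome: CircularGenome,
    cluster_gap: int = 1000,
    min_cluster: int = 2,
) -> list[HrRegion]:
    """Single-linkage clustering of palindromes into hr regions.

    Palindromes whose spans are within ``cluster_gap`` nt of each other
    (along the circle) join one region; regions with at least
    ``min_cluster`` palindromes are numbered hr1, hr2, ... clockwise
    from position 1.
    """
    if not palindromes:
        return []
    pals = sorted(palindromes, key=lambda c: (c.start, c.end))
    clusters: list[list[PalindromeCall]] = [[pals[0]]]
    for c in pals[1:]:
        prev_end = max(p.end for p in clusters[-1])
        if c.start - prev_end - 1 <= cluster_gap:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    if genome.circular and len(clusters) > 1:
        # wrap-around link between last and first cluster
        L = genome.length
        last_end = max(p.end for p in clusters[-1])
        first_start = clusters[0][0].start
        if (first_start + L) - last_end - 1 <= cluster_gap:
            merged = clusters.pop() + clusters[0]
            clusters[0] = merged
    regions = []
    for cl in clusters:
        if len(cl) < min_cluster:
            continue
        start = min(p.start for p in cl)
        end = max(p.end for p in cl)
        seq = genome.fetch(start, end) if end - start + 1 <= genome.length else genome.seq
        regions.append((start, end, cl, at_content(seq)))
    regions.sort(key=lambda r: r[0])
    return [
        HrRegion(hr_id=f"hr{i}", start=s, end=e, n_palindromes=len(cl),
                 at_content=at, palindromes=tuple(sorted(cl, key=lambda c: c.start)))
        for i, (s, e, cl, at) in enumerate(regions, start=1)
    ]
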