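"""De-novo ORF calling on circular genomes and derived genome statistics.

An ORF is an ATG-initiated reading frame ending at the nearest in-frame
stop codon, on either strand, in any of the six frames, with circular
wrap-around (a frame continues across the origin; an ORF may wrap at
most once).  For each stop codon only the 5'-most (longest) candidate
is kept.  Conflicts among candidates are resolved greedily
longest-first with a configurable overlap allowance, mirroring the
"minimal overlap" convention of baculovirus genome annotation.

ORF spans include the stop codon; the minimum-length filter is applied
to the coding span (ATG..last sense codon) by default, so a 50-codon
protein (153 nt with its stop) passes a 150 nt threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import CircularGenome, GeneAnnotation, OrfRecord, revcomp
from .composition import at_content

__all__ = [
    "OrfCallConfig",
    "IntergenicRegion",
    "enumerate_candidate_orfs",
    "select_orfs",
    "call_orfs",
    "orientation_split",
    "coding_density",
    "intergenic_regions",
    "largest_intergenic_region",
    "extremal_orfs",
    "orf_sequence",
]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfCallConfig:
    min_len_nt: int = 150
    start_codon: str = "ATG"
    stop_codons: tuple[str, ...] = STOP_CODONS
    overlap_policy: str = "longest-first"
    max_allowed_overlap_nt: int = 30
    #: if True the >=min_len test is applied to the span including the stop
    include_stop_in_min: bool = False

    def __post_init__(self) -> None:
        if self.min_len_nt < 3:
            raise ValueError("min_len_nt must be >= 3")
        if self.max_allowed_overlap_nt < 0:
            raise ValueError("max_allowed_overlap_nt must be >= 0")
        if self.overlap_policy not in ("longest-first", "max-coverage"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")


@dataclass
class IntergenicRegion:
    start: int            # 1-based inclusive; end may exceed L (wraps)
    end: int
    at_content: float
    flanking_serials: tuple[int | None, int | None]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def _minus_to_plus_start0(a: int, span: int, L: int) -> int:
    """Genome 0-based start of a minus-strand block at minus-coords [a, a+span)."""
    return (L - a - span) % L


def enumerate_candidate_orfs(
    genome: CircularGenome, config: OrfCallConfig = OrfCallConfig()
) -> list[OrfRecord]:
    """All maximal ATG..stop candidates on both strands (six frames).

    Returns unserialised OrfRecords (serial 0) with spans including the
    stop codon; for each distinct stop position only the longest
    candidate survives.
    """
    L = genome.length
    out: list[OrfRecord] = []
    for strand in "+-":
        s = genome.seq if strand == "+" else revcomp(genome.seq)
        work = s + s if genome.circular else s
        n = len(work)
        stops = set(config.stop_codons)
        # next in-frame stop (codon start index) at or after i, same residue mod 3
        next_stop: list[int] = [-1] * n
        for i in range(n - 3, -1, -1):
            if work[i : i + 3] in stops:
                next_stop[i] = i
            elif i + 3 <= n - 3:
                next_stop[i] = next_stop[i + 3]
        best_for_stop: dict[int, tuple[int, int]] = {}  # stop key -> (a, span)
        start = config.start_codon
        limit = L if genome.circular else n - 2
        for a in range(limit):
            if work[a : a + 3] != start:
                continue
            if a + 3 > n - 3:
                continue
            j = next_stop[a + 3]
            if j < 0:
                continue
            span = j - a + 3
            if genome.circular and span > L:
                continue  # would wrap more than once / overlap itself
            coding = span - 3
            min_test = span if config.include_stop_in_min else coding
            if min_test < config.min_len_nt:
                continue
            key = j % L if genome.circular else j
            prev = best_for_stop.get(key)
            if prev is None or span > prev[1]:
                best_for_stop[key] = (a, span)
        for a, span in best_for_stop.values():
            if strand == "+":
                start0 = a % L
            else:
                start0 = _minus_to_plus_start0(a % L, span, L) if genome.circular \
                    else L - a - span
            end = start0 + span
            out.append(
                OrfRecord(start=start0 + 1, end=end, strand=strand, serial=0,
                          wraps_origin=genome.circular and end > L)
            )
    out.sort(key=lambda f: (f.start, f.end, f.strand))
    return out


# ---------------------------------------------------------------------------
# greedy selection under the overlap allowance
# ---------------------------------------------------------------------------

def _segments(f: OrfRecord, L: int) -> list[tuple[int, int]]:
    """0-based half-open linear segments of a (possibly wrapped) feature."""
    s0, e0 = f.start - 1, f.end  # half-open
    if e0 <= L:
        return [(s0, e0)]
    return [(s0, L), (0, e0 - L)]


def _overlap_nt(a: OrfRecord, b: OrfRecord, L: int) -> int:
    tot = 0
    for s1, e1 in _segments(a, L):
        for s2, e2 in _segments(b, L):
            tot += max(0, min(e1, e2) - max(s1, s2))
    return tot


def select_orfs(
    candidates: list[OrfRecord],
    genome: CircularGenome,
    config: OrfCallConfig = OrfCallConfig(),
) -> GeneAnnotation:
    """Resolve overlapping candidates and assign clockwise serials.

    Longest-first greedy: a candidate is accepted iff its overlap with
    every already-accepted ORF is at most ``max_allowed_overlap_nt``.
    Ties break on earlier start, then plus strand.
    """
    L = genome.length
    order = sorted(
        candidates, key=lambda f: (-f.span_nt, f.start, 0 if f.strand == "+" else 1)
    )
    accepted: list[OrfRecord] = []
    for cand in order:
        if all(_overlap_nt(cand, acc, L) <= config.max_allowed_overlap_nt
               for acc in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda f: (f.start, f.end, f.strand))
    feats = []
    for i, f in enumerate(accepted, start=1):
        feats.append(OrfRecord(start=f.start, end=f.end, strand=f.strand,
                               serial=i, label=f.label,
                               wraps_origin=f.wraps_origin))
    return GeneAnnotation(genome_id=genome.id, features=feats)


def call_orfs(
    genome: CircularGenome, config: OrfCallConfig = OrfCallConfig()
) -> GeneAnnotation:
    """enumerate + select in one step."""
    return select_orfs(enumerate_candidate_orfs(genome, config), genome, config)


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def orientation_split(annotation: GeneAnnotation, anchor_serial: int = 1) -> tuple[int, int]:
    """(n_same, n_opposite) strand counts relative to the anchor ORF."""
    if not annotation.features:
        raise ValueError("empty annotation")
    anchor = annotation.by_serial(anchor_serial)  # KeyError if absent
    same = sum(1 for f in annotation.features if f.strand == anchor.strand)
    return same, len(annotation.features) - same


def _merged_union(annotation: GeneAnnotation, L: int) -> list[tuple[int, int]]:
    """Union of all feature spans as sorted, merged 0-based half-open segments."""
    segs: list[tuple[int, int]] = []
    for f in annotation.features:
        segs.extend(_segments(f, L))
    if not segs:
        return []
    segs.sort()
    merged = [list(segs[0])]
    for s, e in segs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coding_density(genome: CircularGenome, annotation: GeneAnnotation) -> float:
    """Fraction of the genome covered by at least one ORF (overlaps once)."""
    merged = _merged_union(annotation, genome.length)
    return sum(e - s for s, e in merged) / genome.length


def intergenic_regions(
    genome: CircularGenome, annotation: GeneAnnotation
) -> list[IntergenicRegion]:
    """Gaps between consecutive ORF spans around the circle.

    Zero-length gaps (abutting ORFs) are excluded.  Flanking serials
    are the ORF ending at the gap's left edge and the ORF starting at
    its right edge.
    """
    L = genome.length
    merged = _merged_union(annotation, L)
    if not merged:
        return []
    # map segment boundaries back to flanking features
    def _left_flank(pos_half_open: int) -> int | None:
        best = None
        for f in annotation.features:
            for s, e in _segments(f, L):
                if e == pos_half_open:
                    best = f.serial
        return best

    def _right_flank(pos0: int) -> int | None:
        best = None
        for f in annotation.features:
            for s, e in _segments(f, L):
                if s == pos0:
                    best = f.serial
        return best

    gaps: list[IntergenicRegion] = []
    n = len(merged)
    for i in range(n):
        e_cur = merged[i][1]
        if genome.circular:
            s_next = merged[(i + 1) % n][0] + (L if i == n - 1 else 0)
        else:
            if i == n - 1:
                break
            s_next = merged[i + 1][0]
        gap_len = s_next - e_cur
        if gap_len <= 0:
            continue
        start, end = e_cur + 1, s_next  # 1-based inclusive, end may exceed L
        seq = genome.fetch(start, end)
        gaps.append(
            IntergenicRegion(
                start=start, end=end, at_content=at_content(seq),
                flanking_serials=(_left_flank(e_cur), _right_flank(s_next % L)),
            )
        )
    return gaps


def largest_intergenic_region(
    genome: CircularGenome, annotation: GeneAnnotation
) -> IntergenicRegion | None:
    gaps = intergenic_regions(genome, annotation)
    if not gaps:
        return None
    return max(gaps, key=lambda g: (g.length, -g.start))


def extremal_orfs(annotation: GeneAnnotation) -> tuple[tuple[OrfRecord, int], tuple[OrfRecord, int]]:
    """((longest ORF, aa length), (shortest ORF, aa length)).

    aa length excludes the stop codon: (span - 3) / 3.
    """
    if not annotation.features:
        raise ValueError("empty annotation")
    longest = max(annotation.features, key=lambda f: (f.span_nt, -f.serial))
    shortest = min(annotation.features, key=lambda f: (f.span_nt, f.serial))
    return (longest, (longest.span_nt - 3) // 3), (shortest, (shortest.span_nt - 3) // 3)


def orf_sequence(genome: CircularGenome, orf: OrfRecord) -> str:
    """Coding-strand nucleotide sequence of an ORF (stop codon included)."""
    nt = genome.fetch(orf.start, orf.end)
    return revcomp(nt) if orf.strand == "-" else nt
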