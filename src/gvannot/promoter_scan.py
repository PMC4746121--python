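"""IUPAC promoter-motif scanning in ORF upstream windows.

The default motif inventory is the baculovirus set: the consensus late
motif TTAAG and the (reported) late motif GATA, plus the early motifs
CAKT and TATAWAW (K = G/T, W = A/T).

Offset convention: ``offset_nt`` is the number of bases strictly
between the motif's 3' end and the A of the ATG on the coding strand
(a motif immediately adjacent to the start codon has offset 0).  For a
template-strand hit the offset is measured the same way after
reverse-complementing the window, so a template hit at offset d is the
coding-strand hit of the reverse-complemented pattern at offset d.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import CircularGenome, GeneAnnotation, OrfRecord, revcomp

__all__ = [
    "PromoterMotif",
    "MotifHit",
    "DEFAULT_MOTIFS",
    "iupac_match",
    "scan_upstream",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PromoterMotif:
    name: str
    pattern: str
    motif_class: str  # "early" | "late"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC symbols {sorted(bad)}")


DEFAULT_MOTIFS = (
    PromoterMotif("TTAAG", "TTAAG", "late"),
    PromoterMotif("GATA", "GATA", "late"),
    PromoterMotif("CAKT", "CAKT", "early"),
    PromoterMotif("TATAWAW", "TATAWAW", "early"),
)


@dataclass(frozen=True)
class MotifHit:
    orf_serial: int
    motif_name: str
    motif_class: str
    matched_literal: str     # as it reads on the genome plus strand
    offset_nt: int
    strand_of_match: str     # "coding" | "template"
    genome_start: int        # 1-based inclusive span on the plus strand
    genome_end: int
    truncated_window: bool = False


def iupac_match(pattern: str, seq: str) -> list[int]:
    """All 0-based positions where the IUPAC pattern matches ``seq``."""
    pattern = pattern.upper()
    seq = seq.upper()
    sets = []
    for sym in pattern:
        try:
            sets.append(IUPAC[sym])
        except KeyError:
            raise ValueError(f"non-IUPAC symbol {sym!r} in pattern {pattern!r}")
    m = len(sets)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(seq[i + k] in sets[k] for k in range(m))
    ]


def _upstream_window(
    genome: CircularGenome, orf: OrfRecord, window_nt: int
) -> tuple[str, list[int], bool]:
    """Coding-strand upstream window of an ORF.

    Returns (window 5'->3' ending just before the ATG, the 1-based plus
    strand genome position of each window base, truncated flag).
    """
    L = genome.length
    truncated = False
    if orf.strand == "+":
        lo = orf.start - window_nt
        if not genome.circular and lo < 1:
            lo, truncated = 1, True
        positions = [((p - 1) % L) + 1 for p in range(lo, orf.start)]
    else:
        end0 = orf.end  # ATG's A sits at orf.end on the plus strand
        hi = end0 + window_nt
        if not genome.circular and hi > L:
            hi, truncated = L, True
        positions = [((p - 1) % L) + 1 for p in range(end0 + 1, hi + 1)]
        positions.reverse()  # 5'->3' on the coding (minus) strand
    bases = [genome.seq[p - 1] for p in positions]
    window = "".join(bases)
    if orf.strand == "-":
        window = window.translate(str.maketrans("ACGTN", "TGCAN"))
    return window, positions, truncated


def scan_upstream(
    genome: CircularGenome,
    annotation: GeneAnnotation,
    motifs: tuple[PromoterMotif, ...] = DEFAULT_MOTIFS,
    window_nt: int = 120,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan the upstream window of every ORF for the motif set.

    Windows wrap around the origin on circular genomes and are
    truncated (with a flag) at the ends of linear ones.
    """
    if window_nt < max(len(m.pattern) for m in motifs):
        raise ValueError("window_nt shorter than the longest motif pattern")
    hits: list[MotifHit] = []
    for orf in annotation.features:
        window, positions, truncated = _upstream_window(genome, orf, window_nt)
        w = len(window)
        rc = revcomp(window)
        for motif in motifs:
            m = len(motif.pattern)
            def _literal_plus(x: int) -> str:
                sub = window[x : x + m]
                return revcomp(sub) if orf.strand == "-" else sub

            for pos in iupac_match(motif.pattern, window):
                span_pos = positions[pos : pos + m]
                hits.append(MotifHit(
                    orf_serial=orf.serial, motif_name=motif.name,
                    motif_class=motif.motif_class,
                    matched_literal=_literal_plus(pos),
                    offset_nt=w - (pos + m), strand_of_match="coding",
                    genome_start=min(span_pos), genome_end=max(span_pos),
                    truncated_window=truncated,
                ))
            if not both_strands:
                continue
            for pos in iupac_match(motif.pattern, rc):
                # template-strand hit: window coords of the match are
                # [w-pos-m, w-pos); its offset equals pos by symmetry
                wpos = w - pos - m
                span_pos = positions[wpos : wpos + m]
                hits.append(MotifHit(
                    orf_serial=orf.serial, motif_name=motif.name,
                    motif_class=motif.motif_class,
                    matched_literal=_literal_plus(wpos),
                    offset_nt=pos, strand_of_match="template",
                    genome_start=min(span_pos), genome_end=max(span_pos),
                    truncated_window=truncated,
                ))
    hits.sort(key=lambda h: (h.orf_serial, h.motif_name, h.offset_nt, h.strand_of_match))
    return hits
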