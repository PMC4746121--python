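"""Protein-level features: translation, molecular weight, the
six-cysteine chitin-binding (peritrophin-A / CBM_14) motif, and
homopolymer runs.

The chitin-binding motif is the spacer-constrained pattern
C-x(13,20)-C-x(5,6)-C-x(9,19)-C-x(10,14)-C-x(4,14)-C; all spacer
combinations are enumerated and overlapping hits are kept, because
tandem CBM_14 domains can share a cysteine neighbourhood.

Molecular weights use average (not monoisotopic) residue masses plus
one water, as standard protein-MW calculators report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight

from .genome_io import CircularGenome
from .orf_annotation import orf_sequence
from .genome_io import OrfRecord

__all__ = [
    "ProteinRecord",
    "CysMotifHit",
    "CYS_SPACERS",
    "translate_orf",
    "translate_cds",
    "protein_mw",
    "find_cys_motif",
    "find_homopolymer_runs",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: allowed spacer (min, max) lengths between the six cysteines
CYS_SPACERS = ((13, 20), (5, 6), (9, 19), (10, 14), (4, 14))


@dataclass
class ProteinRecord:
    orf_serial: int
    aa_seq: str
    mw_da: float

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class CysMotifHit:
    start_aa: int                  # 1-based inclusive, first cysteine
    end_aa: int                    # last cysteine
    spacer_lengths: tuple[int, int, int, int, int]


class TranslationError(ValueError):
    pass


def translate_cds(nt: str) -> str:
    """Standard-code translation of an ATG..stop CDS; stop removed.

    An internal stop is an error naming its codon position.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise TranslationError(f"CDS length {len(nt)} not divisible by 3")
    if len(nt) < 6:
        raise TranslationError("CDS shorter than start + stop")
    aa = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        res = _CODON_TABLE.get(codon)
        if res is None:
            raise TranslationError(f"unknown codon {codon!r} at codon {i + 1}")
        if res == "*":
            if i != n_codons - 1:
                raise TranslationError(f"internal stop codon at codon {i + 1}")
            return "".join(aa)
        aa.append(res)
    return "".join(aa)  # no terminal stop present


def translate_orf(genome: CircularGenome, orf: OrfRecord) -> ProteinRecord:
    aa = translate_cds(orf_sequence(genome, orf))
    return ProteinRecord(orf_serial=orf.serial, aa_seq=aa, mw_da=protein_mw(aa))


def protein_mw(aa_seq: str, allow_x: bool = False) -> float:
    """Average-mass molecular weight in daltons (residues + one water)."""
    if not aa_seq:
        raise ValueError("empty protein sequence")
    seq = aa_seq.upper()
    if allow_x:
        seq = seq.replace("X", "")
        if not seq:
            raise ValueError("sequence contains only X residues")
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} (set allow_x for X)")
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


def find_cys_motif(
    aa_seq: str, spacers: tuple[tuple[int, int], ...] = CYS_SPACERS
) -> list[CysMotifHit]:
    """All placements of the six-cysteine spacer-constrained motif.

    Enumerates every increasing 6-tuple of cysteine positions whose
    consecutive gaps fall in the spacer windows; overlapping hits are
    all reported.
    """
    cys = [i for i, r in enumerate(aa_seq.upper()) if r == "C"]
    hits: list[CysMotifHit] = []

    def extend(chain: list[int], slot: int) -> None:
        if slot == len(spacers):
            gaps = tuple(chain[i + 1] - chain[i] - 1 for i in range(5))
            hits.append(CysMotifHit(start_aa=chain[0] + 1, end_aa=chain[-1] + 1,
                                    spacer_lengths=gaps))
            return
        lo, hi = spacers[slot]
        last = chain[-1]
        for c in cys:
            gap = c - last - 1
            if gap < lo:
                continue
            if gap > hi:
                break
            extend(chain + [c], slot + 1)

    for c0 in cys:
        extend([c0], 0)
    hits.sort(key=lambda h: (h.start_aa, h.end_aa))
    return hits


def find_homopolymer_runs(seq: str, residue: str, min_len: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of ``residue`` with length >= min_len, 1-based inclusive."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if len(residue) != 1:
        raise ValueError("residue must be a single letter")
    pat = re.compile(f"{re.escape(residue.upper())}{{{min_len},}}")
    return [(m.start() + 1, m.end()) for m in pat.finditer(seq.upper())]
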