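"""Genome and annotation I/O for circular viral genomes.

Coordinate conventions used throughout the package:

* All coordinates are 1-based inclusive (GenBank style).
* A feature on a circular genome that spans the origin is stored with
  *unwrapped* coordinates: ``start <= length < end`` and
  ``wraps_origin=True``.  This keeps interval arithmetic linear; helpers
  below convert to/from the wrapped two-segment representation used by
  GFF3.
* "Clockwise" means ascending plus-strand coordinate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

__all__ = [
    "CircularGenome",
    "OrfRecord",
    "GeneAnnotation",
    "GenomeIOError",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "write_protein_fasta",
    "write_gff3",
    "read_gff3",
    "rotate_to_anchor",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Raised for malformed genome or annotation input."""


@dataclass(frozen=True)
class CircularGenome:
    """A (usually circular) DNA genome.

    ``seq`` is uppercase over {A, C, G, T, N}.  Position 1 is the first
    character of ``seq``; on a circular genome position ``length + k``
    aliases position ``k``.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise GenomeIOError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise GenomeIOError(
                f"genome {self.id!r}: non-ACGTN characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Plus-strand subsequence for 1-based inclusive [start, end].

        ``end`` may exceed ``length`` on a circular genome (wrap once).
        """
        if start < 1 or end < start:
            raise GenomeIOError(f"bad interval {start}..{end}")
        if end <= self.length:
            return self.seq[start - 1 : end]
        if not self.circular:
            raise GenomeIOError(
                f"interval {start}..{end} beyond linear genome of {self.length} nt"
            )
        if end - start + 1 > self.length:
            raise GenomeIOError(f"interval {start}..{end} wraps more than once")
        return self.seq[start - 1 :] + self.seq[: end - self.length]


@dataclass
class OrfRecord:
    """One ORF/CDS: 1-based inclusive span, unwrapped (end may exceed L)."""

    start: int
    end: int
    strand: str
    serial: int
    label: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise GenomeIOError(f"bad feature span {self.start}..{self.end}")

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    genome_id: str
    features: list[OrfRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def by_serial(self, serial: int) -> OrfRecord:
        for f in self.features:
            if f.serial == serial:
                return f
        raise KeyError(f"no feature with serial {serial}")

    def sorted_by_start(self) -> list[OrfRecord]:
        return sorted(self.features, key=lambda f: (f.start, f.end))


# ---------------------------------------------------------------------------
# GenBank / FASTA reading
# ---------------------------------------------------------------------------

def _feature_label(feat) -> str:
    for key in ("gene", "product", "label", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return ""


def read_genbank(path) -> tuple[CircularGenome, GeneAnnotation]:
    """Read a GenBank flat file into (genome, annotation).

    CDS (or, lacking CDS, gene) features are converted to 1-based
    inclusive coordinates; compound ``join()`` locations that span the
    origin of a circular record are unwrapped and flagged.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises plain ValueError with context
        raise GenomeIOError(f"malformed GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise GenomeIOError(f"GenBank file {path}: empty ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    genome = CircularGenome(id=record.id or record.name, seq=seq, circular=circular)
    L = genome.length

    kinds = [f for f in record.features if f.type == "CDS"]
    if not kinds:
        kinds = [f for f in record.features if f.type == "gene"]
    feats: list[OrfRecord] = []
    serial = 0
    for feat in kinds:
        strand = "-" if feat.location.strand == -1 else "+"
        loc = feat.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            first, last = parts[0], parts[-1]
            # origin-spanning join: one part ends at L, the other starts at 1
            if int(first.start) == 0 and int(last.end) == L and len(parts) == 2:
                start, end, wraps = int(last.start) + 1, L + int(first.end), True
            else:
                start, end, wraps = int(first.start) + 1, int(last.end), False
        else:
            start, end, wraps = int(loc.start) + 1, int(loc.end), False
        serial += 1
        feats.append(
            OrfRecord(start=start, end=end, strand=strand, serial=serial,
                      label=_feature_label(feat), wraps_origin=wraps)
        )
    return genome, GeneAnnotation(genome_id=genome.id, features=feats)


def read_fasta(path, circular: bool = True) -> CircularGenome:
    record = SeqIO.read(str(path), "fasta")
    return CircularGenome(id=record.id, seq=str(record.seq).upper(), circular=circular)


def write_fasta(genome: CircularGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.seq[i : i + width] + "\n")


def write_protein_fasta(proteins: dict[str, str], path, width: int = 70) -> None:
    """Write a name -> amino-acid-sequence mapping as FASTA."""
    with open(path, "w") as fh:
        for name, aa in proteins.items():
            fh.write(f">{name}\n")
            for i in range(0, len(aa), width):
                fh.write(aa[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(annotation: GeneAnnotation, path, genome: CircularGenome | None = None) -> None:
    """Write annotation as GFF3 (1-based inclusive).

    Origin-wrapping features are emitted as two CDS segments sharing one
    ``ID`` (is_circular region attribute set when the genome is known).
    """
    lines = ["##gff-version 3"]
    if genome is not None:
        circ = ";Is_circular=true" if genome.circular else ""
        lines.append(
            f"{annotation.genome_id}\tgvannot\tregion\t1\t{genome.length}\t.\t+\t."
            f"\tID=region0{circ}"
        )
    L = genome.length if genome is not None else None
    for f in sorted(annotation.features, key=lambda f: f.serial):
        attrs = f"ID=orf{f.serial};serial={f.serial}"
        if f.label:
            attrs += f";Name={f.label}"
        if f.wraps_origin:
            if L is None:
                raise GenomeIOError("writing a wrapped feature requires the genome")
            segs = [(f.start, L), (1, f.end - L)]
        else:
            segs = [(f.start, f.end)]
        for s, e in segs:
            lines.append(
                f"{annotation.genome_id}\tgvannot\tCDS\t{s}\t{e}\t.\t{f.strand}\t0\t{attrs}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path, genome_length: int | None = None) -> GeneAnnotation:
    """Read back a GFF3 written by :func:`write_gff3`.

    Two CDS segments sharing an ID are re-assembled into one unwrapped
    origin-spanning feature (requires ``genome_length``).
    """
    by_id: dict[str, list] = {}
    genome_id = ""
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            if cols[2] != "CDS":
                continue
            genome_id = cols[0]
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"line{ln}")
            by_id.setdefault(fid, []).append((int(cols[3]), int(cols[4]), cols[6], attrs))
    feats = []
    for fid, segs in by_id.items():
        attrs = segs[0][3]
        serial = int(attrs.get("serial", len(feats) + 1))
        label = attrs.get("Name", "")
        strand = segs[0][2]
        if len(segs) == 1:
            s, e = segs[0][0], segs[0][1]
            wraps = False
        elif len(segs) == 2:
            if genome_length is None:
                raise GenomeIOError(
                    f"feature {fid}: two segments but genome length unknown"
                )
            segs_sorted = sorted(segs, key=lambda t: t[0])
            head, tail = segs_sorted[1], segs_sorted[0]
            if head[1] != genome_length or tail[0] != 1:
                raise GenomeIOError(f"feature {fid}: segments do not abut the origin")
            s, e, wraps = head[0], genome_length + tail[1], True
        else:
            raise GenomeIOError(f"feature {fid}: more than two segments")
        feats.append(OrfRecord(start=s, end=e, strand=strand, serial=serial,
                               label=label, wraps_origin=wraps))
    feats.sort(key=lambda f: f.serial)
    return GeneAnnotation(genome_id=genome_id, features=feats)


# ---------------------------------------------------------------------------
# Rotation to the anchor gene (granulin convention)
# ---------------------------------------------------------------------------

def _remap_feature(f: OrfRecord, L: int, shift0: int) -> OrfRecord:
    """Rotate a feature: new 0-based start = (old0 - shift0) mod L."""
    start0 = (f.start - 1 - shift0) % L
    end = start0 + f.span_nt  # 1-based inclusive end == start0 + span
    return replace(f, start=start0 + 1, end=end, wraps_origin=end > L)


def _revcomp_feature(f: OrfRecord, L: int) -> OrfRecord:
    start0 = (L - (f.start - 1) - f.span_nt) % L
    end = start0 + f.span_nt
    return replace(
        f,
        start=start0 + 1,
        end=end,
        strand="-" if f.strand == "+" else "+",
        wraps_origin=end > L,
    )


def rotate_to_anchor(
    genome: CircularGenome, annotation: GeneAnnotation, anchor_label: str
) -> tuple[CircularGenome, GeneAnnotation]:
    """Rotate (and orient) a circular genome so the anchor ORF starts at 1.

    The returned sequence begins at the anchor's ATG on the plus strand;
    the anchor becomes serial 1 and the remaining serials are assigned
    clockwise by start coordinate.
    """
    if not genome.circular:
        raise GenomeIOError("rotate_to_anchor requires a circular genome")
    wanted = anchor_label.strip().lower()
    hits = [f for f in annotation.features if f.label.strip().lower() == wanted]
    if len(hits) != 1:
        cand = sorted({f.label for f in annotation.features if f.label})
        raise GenomeIOError(
            f"anchor {anchor_label!r}: {len(hits)} matching features; "
            f"available labels: {cand}"
        )
    anchor = hits[0]
    L = genome.length
    seq = genome.seq
    feats = list(annotation.features)
    if anchor.strand == "-":
        seq = revcomp(seq)
        feats = [_revcomp_feature(f, L) for f in feats]
        anchor = feats[[f.serial for f in annotation.features].index(anchor.serial)]
    shift0 = anchor.start - 1
    seq = seq[shift0:] + seq[:shift0]
    feats = [_remap_feature(f, L, shift0) for f in feats]
    feats.sort(key=lambda f: (f.start, f.end))
    for i, f in enumerate(feats, start=1):
        f.serial = i
    out_genome = CircularGenome(id=genome.id, seq=seq, circular=True)
    return out_genome, GeneAnnotation(genome_id=genome.id, features=feats)


def genbank_string(genome: CircularGenome, annotation: GeneAnnotation | None = None) -> str:
    """Render a minimal GenBank record (round-trippable by read_genbank)."""
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqFeature import SeqFeature, SimpleLocation

    rec = SeqRecord(Seq(genome.seq), id=genome.id, name=genome.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    L = genome.length
    if annotation is not None:
        for f in annotation.features:
            strand = 1 if f.strand == "+" else -1
            if f.wraps_origin:
                loc = CompoundLocation(
                    [SimpleLocation(f.start - 1, L, strand),
                     SimpleLocation(0, f.end - L, strand)]
                )
            else:
                loc = SimpleLocation(f.start - 1, f.end, strand)
            rec.features.append(
                SeqFeature(loc, type="CDS", qualifiers={"gene": [f.label or f"orf{f.serial}"]})
            )
    buf = io.StringIO()
    SeqIO.write(rec, buf, "genbank")
    return buf.getvalue()


def write_genbank(genome: CircularGenome, annotation: GeneAnnotation | None, path) -> None:
    with open(path, "w") as fh:
        fh.write(genbank_string(genome, annotation))
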