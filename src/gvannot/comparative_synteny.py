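"""Pairwise gene-order comparison between annotated genomes.

Orthologs are paired by reciprocal-best local protein alignment
(Smith-Waterman, BLOSUM62, gap open 11 / extend 1); synteny blocks are
maximal runs of ortholog pairs consecutive (up to a small gene-gap
allowance) and monotone in both genomes, descending runs being
inversions.  Also: the 37-core-gene presence audit and serial naming
of repeated gene families (bro-a, bro-b, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GeneAnnotation

__all__ = [
    "OrthologTable",
    "SyntenyBlock",
    "CoreGeneAudit",
    "pair_orthologs",
    "synteny_blocks",
    "core_gene_audit",
    "load_core_gene_reference",
    "name_repeated_genes",
]


@dataclass(frozen=True)
class OrthologPair:
    a_serial: int
    b_serial: int
    similarity: float  # identities / alignment length


@dataclass
class OrthologTable:
    rows: list[OrthologPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def as_mapping(self) -> dict[int, int]:
        return {r.a_serial: r.b_serial for r in self.rows}


@dataclass
class SyntenyBlock:
    a_span: tuple[int, int]     # nt hull in genome A
    b_span: tuple[int, int]
    orientation: str            # "same" | "inverted"
    n_genes: int
    pairs: list[OrthologPair] = field(default_factory=list)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _identity_fraction(alignment) -> float:
    a, b = alignment[0], alignment[1]
    n = len(a)
    if n == 0:
        return 0.0
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return ident / n


def pair_orthologs(
    proteins_a: dict[int, str],
    proteins_b: dict[int, str],
    min_similarity: float = 0.25,
) -> OrthologTable:
    """Reciprocal-best-hit ortholog pairing on protein sequences.

    ``proteins_*`` map ORF serials to amino-acid sequences.  All-vs-all
    Smith-Waterman scores pick each gene's best partner; reciprocal
    best pairs with identity fraction >= ``min_similarity`` are kept.
    """
    if not proteins_a or not proteins_b:
        return OrthologTable()
    al = _aligner()
    a_keys = sorted(proteins_a)
    b_keys = sorted(proteins_b)
    scores: dict[tuple[int, int], float] = {}
    for i in a_keys:
        for j in b_keys:
            scores[(i, j)] = al.score(proteins_a[i], proteins_b[j])
    best_a = {i: max(b_keys, key=lambda j: (scores[(i, j)], -j)) for i in a_keys}
    best_b = {j: max(a_keys, key=lambda i: (scores[(i, j)], -i)) for j in b_keys}
    rows = []
    for i in a_keys:
        j = best_a[i]
        if best_b[j] != i or scores[(i, j)] <= 0:
            continue
        aln = al.align(proteins_a[i], proteins_b[j])[0]
        sim = _identity_fraction(aln)
        if sim >= min_similarity:
            rows.append(OrthologPair(a_serial=i, b_serial=j, similarity=sim))
    rows.sort(key=lambda r: r.a_serial)
    return OrthologTable(rows=rows)


def _gene_hull(annotation: GeneAnnotation, serials: list[int]) -> tuple[int, int]:
    feats = [annotation.by_serial(s) for s in serials]
    return min(f.start for f in feats), max(f.end for f in feats)


def synteny_blocks(
    annot_a: GeneAnnotation,
    annot_b: GeneAnnotation,
    orthologs: OrthologTable,
    max_gap_genes: int = 2,
) -> list[SyntenyBlock]:
    """Chain ortholog pairs into monotone syntenic blocks.

    Consecutive pairs may skip up to ``max_gap_genes`` genes in either
    genome; a descending b-serial run is an inversion.  Every ortholog
    pair belongs to exactly one block.
    """
    pairs = sorted(orthologs.rows, key=lambda r: r.a_serial)
    if not pairs:
        return []
    step = max_gap_genes + 1
    blocks: list[list[OrthologPair]] = [[pairs[0]]]
    direction = 0  # 0 unknown, +1 ascending, -1 descending
    for p in pairs[1:]:
        prev = blocks[-1][-1]
        da = p.a_serial - prev.a_serial
        db = p.b_serial - prev.b_serial
        ok = 0 < da <= step and 0 < abs(db) <= step
        if ok:
            d = 1 if db > 0 else -1
            if direction == 0 or d == direction:
                blocks[-1].append(p)
                direction = d
                continue
        blocks.append([p])
        direction = 0
    out = []
    for chain in blocks:
        if len(chain) >= 2:
            orientation = "inverted" if chain[1].b_serial < chain[0].b_serial else "same"
        else:
            orientation = "same"
        out.append(SyntenyBlock(
            a_span=_gene_hull(annot_a, [p.a_serial for p in chain]),
            b_span=_gene_hull(annot_b, [p.b_serial for p in chain]),
            orientation=orientation, n_genes=len(chain), pairs=chain,
        ))
    return out


# ---------------------------------------------------------------------------
# core-gene audit
# ---------------------------------------------------------------------------

@dataclass
class CoreGeneAudit:
    status: dict[str, tuple[bool, int | None]]  # name -> (present, serial)

    @property
    def n_present(self) -> int:
        return sum(1 for present, _ in self.status.values() if present)

    @property
    def n_absent(self) -> int:
        return len(self.status) - self.n_present


def load_core_gene_reference() -> dict[str, set[str]]:
    """The bundled 37-name core-gene list: canonical name -> alias set."""
    ref: dict[str, set[str]] = {}
    text = resources.files("gvannot.data").joinpath("core_genes.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        name = parts[0].strip().lower()
        aliases = {a.strip().lower() for a in parts[1].split(",") if a.strip()} \
            if len(parts) > 1 else set()
        ref[name] = aliases | {name}
    return ref


def core_gene_audit(
    annotation: GeneAnnotation, reference: dict[str, set[str]] | None = None
) -> CoreGeneAudit:
    """Label-based presence/absence of the reference core genes."""
    if reference is None:
        reference = load_core_gene_reference()
    if not reference:
        raise ValueError("empty core-gene reference list")
    labels = {f.label.strip().lower(): f.serial for f in annotation.features if f.label}
    status: dict[str, tuple[bool, int | None]] = {}
    for name, aliases in reference.items():
        serial = next((labels[a] for a in sorted(aliases) if a in labels), None)
        status[name] = (serial is not None, serial)
    return CoreGeneAudit(status=status)


def name_repeated_genes(annotation: GeneAnnotation, family_label: str) -> GeneAnnotation:
    """Suffix repeated family members -a, -b, ... by ascending serial."""
    members = sorted(
        (f for f in annotation.features if f.label.strip().lower() == family_label.lower()),
        key=lambda f: f.serial,
    )
    if not members:
        raise ValueError(f"no feature labelled {family_label!r}")
    suffix = {f.serial: chr(ord("a") + i) for i, f in enumerate(members)}
    feats = [
        replace(f, label=f"{family_label}-{suffix[f.serial]}") if f.serial in suffix else f
        for f in annotation.features
    ]
    return GeneAnnotation(genome_id=annotation.genome_id, features=feats)
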