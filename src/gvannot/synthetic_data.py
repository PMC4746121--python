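"""Synthetic circular genomes with fully known planted features.

The generator emulates the summary statistics of a granulovirus-like
genome (~112 kb circle at ~35% GC, ~130 non-overlapping ATG-initiated
ORFs on both strands, AT-rich intergenic space) and plants, at
recorded coordinates: promoter motifs at chosen upstream offsets,
tandem-repeat arrays with fractional copy numbers (coding, noncoding
and boundary-straddling), clustered imperfect-palindrome cassettes
forming hr regions, and a chitin-binding-like protein carrying two
six-cysteine domains and a poly-Q tract.

Spurious-ORF suppression: intergenic spacers are interleaved with the
self-reverse-complementary stop cassette TTAATTAATTAA (TTAA contains a
stop in every plus frame and, being its own reverse complement, in
every minus frame), spaced closely enough that no candidate ORF of the
minimum length can cross intergenic space.  Planted ORFs are therefore
recoverable with sensitivity and precision 1.0 by the default caller.

Determinism: one ``numpy`` Generator seeded from the config drives all
randomness; the same config yields byte-identical genomes.

GC calibration: gene codons are sampled from a base distribution
solved (bisection on the 61 sense codons) so coding sequence meets the
target GC in expectation, and the free intergenic bases are sampled at
a probability solved from the realised GC of everything else, so the
whole-genome GC hits the configured target to within binomial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .genome_io import CircularGenome, GeneAnnotation, OrfRecord, revcomp
from .repeat_hr import RepeatCall, PalindromeCall

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulationError",
    "simulate_genome",
    "perturb_gene_order",
    "simulate_two_clade_proteins",
]

# Stops in all six reading-frame phases, no ATG on either strand, not
# internally periodic, and (key for palindrome specificity) its longest
# common substring with its own reverse complement is 2 nt, so cassette
# pairs cannot seed inverted repeats.  Ends in TAG: a cassette abutting a
# gene start puts an in-frame stop right before the ATG.
STOP_CASSETTE = "GTTAGAGTTTAGTTAG"
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PromoterPlant:
    orf_index: int        # 0-based gene index (serial = index + 1)
    motif_name: str
    literal: str          # stamped on the coding strand of the window
    offset_nt: int


@dataclass(frozen=True)
class TrPlant:
    unit: str
    span_nt: int          # total array length; copies = span / |unit|
    placement: str        # "coding" | "noncoding" | "both"

    @property
    def copies(self) -> float:
        return round(self.span_nt / len(self.unit), 1)


@dataclass(frozen=True)
class HrPlant:
    n_palindromes: int
    arm: int
    loop: int
    mismatches: int
    at_content: float = 0.73


@dataclass
class SimulationConfig:
    seed: int = 1
    genome_len: int = 112_000
    gc: float = 0.352
    n_orfs: int = 130
    orf_aa_range: tuple[int, int] = (50, 1162)
    strand_fraction_same: float = 0.53
    coding_fraction: float = 0.851
    promoter_plants: tuple[PromoterPlant, ...] | None = None
    tr_plants: tuple[TrPlant, ...] | None = None
    hr_plants: tuple[HrPlant, ...] | None = None
    plant_proteins: bool = True
    polyq_len: int = 13

    def __post_init__(self) -> None:
        if self.promoter_plants is None and self.n_orfs >= 60:
            self.promoter_plants = (
                PromoterPlant(20, "TTAAG", "TTAAG", 8),
                PromoterPlant(13, "TATAWAW", "TATAAAT", 30),
                PromoterPlant(54, "TATAWAW", "ATTTATA", 57),
                PromoterPlant(14, "GATA", "GATA", 20),
                PromoterPlant(32, "CAKT", "CAGT", 15),
            )
        elif self.promoter_plants is None:
            self.promoter_plants = ()
        if self.tr_plants is None and self.n_orfs >= 60:
            self.tr_plants = (
                TrPlant("CAG", 37, "coding"),          # 12.3 copies, in-frame
                TrPlant("CACTT", 25, "noncoding"),
                TrPlant("AAGAGGC", 32, "noncoding"),
                TrPlant("AAGAGGTAAGG", 323, "noncoding"),
                TrPlant("TAA", 39, "both"),            # gene stop starts the array
            )
        elif self.tr_plants is None:
            self.tr_plants = ()
        if self.hr_plants is None and self.n_orfs >= 60:
            self.hr_plants = (
                HrPlant(3, 13, 6, 1),
                HrPlant(11, 13, 6, 1),
                HrPlant(3, 13, 8, 2),
                HrPlant(4, 13, 5, 0),
                HrPlant(3, 14, 6, 1),
                HrPlant(3, 13, 7, 2),
            )
        elif self.hr_plants is None:
            self.hr_plants = ()


@dataclass
class TruthTable:
    orfs: GeneAnnotation
    motif_hits: list[tuple[int, str, int]] = field(default_factory=list)   # serial, motif, offset
    repeats: list[RepeatCall] = field(default_factory=list)
    palindromes: list[PalindromeCall] = field(default_factory=list)
    hr_spans: list[tuple[int, int, int]] = field(default_factory=list)     # start, end, n_pal
    proteins: dict[int, str] = field(default_factory=dict)                 # serial -> designed aa
    cys_hits: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    polyq: dict[int, tuple[int, int]] = field(default_factory=dict)        # serial -> aa span
    inversions: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# composition helpers
# ---------------------------------------------------------------------------

def _codon_base_prob(gc_target: float) -> np.ndarray:
    """Base probabilities (A,C,G,T) whose sense-codon GC equals the target."""

    def codon_gc(q_gc: float) -> float:
        p = {"A": (1 - q_gc) / 2, "T": (1 - q_gc) / 2, "C": q_gc / 2, "G": q_gc / 2}
        tot = gc = 0.0
        for codon in _SENSE_CODONS:
            w = p[codon[0]] * p[codon[1]] * p[codon[2]]
            tot += w
            gc += w * sum(1 for b in codon if b in "GC") / 3
        return gc / tot

    lo, hi = 0.01, 0.99
    q = brentq(lambda x: codon_gc(x) - gc_target, lo, hi)
    return np.array([(1 - q) / 2, q / 2, q / 2, (1 - q) / 2])


def _sample_codons(rng: np.random.Generator, n: int, base_p: np.ndarray) -> str:
    """n sense codons sampled i.i.d. (stop codons rejected)."""
    out: list[str] = []
    while len(out) < n:
        draw = _BASES[rng.choice(4, size=3 * (n - len(out) + 8), p=base_p)]
        for i in range(0, len(draw) - 2, 3):
            codon = "".join(draw[i : i + 3])
            if codon not in ("TAA", "TAG", "TGA"):
                out.append(codon)
                if len(out) == n:
                    break
    return "".join(out)


def _random_bases(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _at_rich(rng: np.random.Generator, n: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return _random_bases(rng, n, p)


# ---------------------------------------------------------------------------
# designed chitin-binding-like protein
# ---------------------------------------------------------------------------

_SPACER_AA = "ASTNVLIDEKFG"  # no C, no Q


def _design_special_protein(rng: np.random.Generator, polyq_len: int):
    """190-aa protein with two six-cysteine domains and one poly-Q run.

    Cys positions 40,55,61,72,85,92 and 113,128,134,145,158,165 admit
    exactly the two in-domain spacer chains and no cross-domain chain
    (all mixed chains violate a spacer window); poly-Q at 170..182.
    """
    cys1 = [40, 55, 61, 72, 85, 92]
    cys2 = [113, 128, 134, 145, 158, 165]
    q_start = 170
    length = 190
    aa = [str(rng.choice(list(_SPACER_AA))) for _ in range(length)]
    aa[0] = "M"
    for pos in cys1 + cys2:
        aa[pos - 1] = "C"
    for k in range(polyq_len):
        aa[q_start - 1 + k] = "Q"
    aa[q_start - 2] = "F"                      # run boundaries cannot extend
    aa[q_start - 1 + polyq_len] = "F"
    truth = {
        "cys_hits": [(cys1[0], cys1[-1]), (cys2[0], cys2[-1])],
        "polyq": (q_start, q_start + polyq_len - 1),
    }
    return "".join(aa), truth


_CODON_CHOICES = {}
for _c in _SENSE_CODONS:
    from Bio.Seq import Seq as _Seq
    _aa = str(_Seq(_c).translate())
    _CODON_CHOICES.setdefault(_aa, []).append(_c)


def _backtranslate(rng: np.random.Generator, aa: str, polyq_span: tuple[int, int] | None) -> str:
    codons = []
    for i, res in enumerate(aa, start=1):
        if polyq_span and polyq_span[0] <= i <= polyq_span[1]:
            codons.append("CAA")               # pure-CAA poly-Q: a planted TR
        else:
            codons.append(str(rng.choice(_CODON_CHOICES[res])))
    return "".join(codons)


# ---------------------------------------------------------------------------
# spacer construction
# ---------------------------------------------------------------------------

_CHUNK_SENTINEL = "n"  # placeholder for to-be-calibrated intergenic bases


def _spacer_template(rng: np.random.Generator, length: int) -> str:
    """Spacer skeleton: stop cassettes at both ends (the trailing one puts
    an in-frame TAA right before the next gene's ATG, and the leading one a
    minus-strand stop right after a reverse gene, pinning candidate ORFs to
    their planted spans) with sentinel chunks and further cassettes between.
    """
    cas = STOP_CASSETTE
    lead = "TTA" + cas  # TTA: minus-strand stop right after a reverse gene
    if length < len(cas):
        return _CHUNK_SENTINEL * length
    if length < len(lead) + len(cas) + 5:
        pad = length - len(cas)
        return _CHUNK_SENTINEL * (pad // 2) + cas + _CHUNK_SENTINEL * (pad - pad // 2)
    parts: list[str] = [lead]
    remaining = length - len(lead) - len(cas)
    while remaining > 0:
        chunk = min(int(rng.integers(10, 25)), remaining)
        parts.append(_CHUNK_SENTINEL * chunk)
        remaining -= chunk
        if remaining >= len(cas) + 5:
            parts.append(cas)
            remaining -= len(cas)
    parts.append(cas)
    return "".join(parts)


def _build_hr_cassette(rng: np.random.Generator, plant: HrPlant):
    """Cassette string + palindrome calls at cassette-local coordinates."""
    pieces: list[str] = []
    pals: list[dict] = []
    pos = 0

    def linker(n: int) -> str:
        if n >= len(STOP_CASSETTE) + 8:
            k = (n - len(STOP_CASSETTE)) // 2
            return (_at_rich(rng, k, plant.at_content) + STOP_CASSETTE
                    + _at_rich(rng, n - k - len(STOP_CASSETTE), plant.at_content))
        return _at_rich(rng, n, plant.at_content)

    lead = linker(int(rng.integers(24, 33)))
    pieces.append(lead)
    pos += len(lead)
    for _ in range(plant.n_palindromes):
        left = _at_rich(rng, plant.arm, plant.at_content)
        loop = _at_rich(rng, plant.loop, plant.at_content)
        right = list(revcomp(left))
        if plant.mismatches:
            # interior substitutions only: outer & inner pairs stay matched
            sites = rng.choice(np.arange(1, plant.arm - 1), size=plant.mismatches,
                               replace=False)
            for s in sites:
                cur = right[s]
                right[s] = str(rng.choice([b for b in "ACGT" if b != cur]))
        right = "".join(right)
        pal = left + loop + right
        # 3 forced boundary mismatch pairs: bases after the right arm copy
        # the bases before the left arm (x never pairs with comp(x))
        pre3 = pieces[-1][-3:]
        post3 = pre3[-1] + pre3[-2] + pre3[-3]
        pals.append({
            "start": pos + 1, "end": pos + len(pal), "arm": plant.arm,
            "loop": plant.loop, "mism": plant.mismatches,
            "center": pos + plant.arm + 1,
        })
        gap = int(rng.integers(24, 33))
        link = post3 + linker(gap - 3)
        pieces.append(pal + link)
        pos += len(pal) + len(link)
    cassette = "".join(pieces)
    return cassette, pals


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _gene_lengths(rng: np.random.Generator, config: SimulationConfig) -> list[int]:
    lo, hi = config.orf_aa_range
    aa = np.clip(rng.gamma(2.2, 110.0, size=config.n_orfs) + lo, lo, hi).astype(int)
    target = config.coding_fraction * config.genome_len
    nt = 3 * aa + 3
    scale = target / nt.sum()
    aa = np.clip((aa * scale).astype(int), lo, hi)
    return list(aa)


def simulate_genome(config: SimulationConfig) -> tuple[CircularGenome, TruthTable]:
    """Generate a circular genome plus its full planted-feature truth."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_len
    n = config.n_orfs

    if n == 0:
        spacer = _spacer_template(rng, L)
        body = _fill_chunks(rng, spacer, config.gc)
        genome = CircularGenome(id=f"synth-seed{config.seed}", seq=body)
        return genome, TruthTable(orfs=GeneAnnotation(genome_id=genome.id))

    aa_lens = _gene_lengths(rng, config)

    special_protein = None
    special_idx = 20 if (config.plant_proteins and n > 21) else None
    if special_idx is not None:
        special_protein, special_truth = _design_special_protein(rng, config.polyq_len)
        aa_lens[special_idx] = len(special_protein)

    cag_idx = 5 if n > 6 else None            # host of the in-frame CAG array
    both_idx = 40 if n > 41 else None         # host of the boundary array
    plus_forced = {0, special_idx, cag_idx, both_idx} - {None}

    strands = ["+" if (i in plus_forced or rng.random() < config.strand_fraction_same)
               else "-" for i in range(n)]

    # --- gene sequences (coding strand) -----------------------------------
    base_p = _codon_base_prob(config.gc)
    stops = ["TAA", "TAG", "TGA"]
    gene_seqs: list[str] = []
    tr_truth: list[dict] = []
    for i in range(n):
        aa_len = aa_lens[i]
        if i == special_idx:
            # poly-Q span shifted into the post-Met slice (1-based)
            q0, q1 = special_truth["polyq"]
            cds = "ATG" + _backtranslate(
                rng, special_protein[1:], (q0 - 1, q1 - 1)) + "TAA"
            gene_seqs.append(cds)
            continue
        if i == cag_idx:
            # [ATG][pre][TTT][CAG x12 + CCC][TTT][post][stop]
            pre = max(8, aa_len // 4)
            post = aa_len - 1 - pre - 1 - 13 - 1
            if post < 4:
                raise SimulationError("CAG host gene too short")
            cds = ("ATG" + _sample_codons(rng, pre, base_p) + "TTT"
                   + "CAG" * 12 + "CCC" + "TTT"
                   + _sample_codons(rng, post, base_p) + str(rng.choice(stops)))
            tr_truth.append({"gene": i, "codon_offset": 1 + pre + 1,
                             "unit": "CAG", "span": 37, "placement": "coding"})
            gene_seqs.append(cds)
            continue
        if i == both_idx:
            body_codons = aa_len - 2
            if body_codons < 4:
                raise SimulationError("boundary-array host gene too short")
            # TTT before the TAA stop: the poly-TAA array starting at the
            # stop codon cannot extend leftward into the gene
            cds = ("ATG" + _sample_codons(rng, body_codons, base_p)
                   + "TTT" + "TAA")
            gene_seqs.append(cds)
            continue
        cds = "ATG" + _sample_codons(rng, aa_len - 1, base_p) + str(rng.choice(stops))
        gene_seqs.append(cds)

    gene_nt = [len(s) for s in gene_seqs]

    # --- spacer sizing -----------------------------------------------------
    # spacer i precedes gene i; gene 0 starts at position 1, spacer 0 wraps
    # to the genome end.
    min_spacer = 40  # room for the stop scaffolding at both spacer ends
    spacer_len = [min_spacer] * n
    promoter_plants = [p for p in config.promoter_plants if p.orf_index < n]
    promoter_spacer_idx: set[int] = set()
    for p in promoter_plants:
        need = p.offset_nt + len(p.literal) + 6
        idx = p.orf_index if strands[p.orf_index] == "+" else (p.orf_index + 1) % n
        promoter_spacer_idx.add(idx)
        spacer_len[idx] = max(spacer_len[idx], need + 8)
    both_plant = next((t for t in config.tr_plants if t.placement == "both"), None)
    both_spacer_idx = (both_idx + 1) % n if (both_plant and both_idx is not None) else None
    reserved = {0} | promoter_spacer_idx | ({both_spacer_idx} - {None})
    hr_plants = list(config.hr_plants)
    hr_cassettes = []
    hr_spacer_idx: list[int] = []
    for k, plant in enumerate(hr_plants):
        cassette, pals = _build_hr_cassette(rng, plant)
        idx = (2 + k * max(1, n // max(1, len(hr_plants)))) % n
        while idx in hr_spacer_idx or idx in reserved:
            idx = (idx + 1) % n
        hr_spacer_idx.append(idx)
        hr_cassettes.append((idx, cassette, pals))
        spacer_len[idx] = max(spacer_len[idx], len(cassette) + 2 * min_spacer)
    nc_plants = [t for t in config.tr_plants if t.placement == "noncoding"]
    nc_spacer_idx: list[int] = []
    for t in nc_plants:
        idx = int(rng.integers(1, n))
        while idx in hr_spacer_idx or idx in nc_spacer_idx or idx in reserved:
            idx = (idx + 1) % n
        nc_spacer_idx.append(idx)
        spacer_len[idx] = max(spacer_len[idx], t.span_nt + 2 * min_spacer)
    if both_spacer_idx is not None:
        spacer_len[both_spacer_idx] = max(
            spacer_len[both_spacer_idx], both_plant.span_nt + min_spacer)

    remainder = L - sum(gene_nt) - sum(spacer_len)
    if remainder < 0:
        raise SimulationError(
            f"infeasible packing: genes + spacers exceed genome_len by {-remainder} nt"
        )
    free_idx = [i for i in range(n)
                if i not in hr_spacer_idx and i not in nc_spacer_idx]
    extra = rng.multinomial(remainder, np.ones(len(free_idx)) / len(free_idx))
    for k, i in enumerate(free_idx):
        spacer_len[i] += int(extra[k])

    # --- assembly ----------------------------------------------------------
    parts: list[str] = []
    pos = 0  # 0-based
    gene_start0: list[int] = []
    truth = TruthTable(orfs=GeneAnnotation(genome_id=f"synth-seed{config.seed}"))
    pal_truth: list[PalindromeCall] = []
    hr_span_truth: list[tuple[int, int, int]] = []

    for i in range(n):
        gene_start0.append(pos)
        coding = gene_seqs[i]
        parts.append(coding if strands[i] == "+" else revcomp(coding))
        pos += len(coding)
        # spacer i+1 follows gene i (spacer 0 comes last, wrapping to gene 0)
        sp_idx = (i + 1) % n
        template = _spacer_template(rng, spacer_len[sp_idx])
        # plant hr cassette / noncoding arrays centrally inside the spacer
        if sp_idx in hr_spacer_idx:
            k = hr_spacer_idx.index(sp_idx)
            _, cassette, pals = hr_cassettes[k]
            off = (len(template) - len(cassette)) // 2
            template = template[:off] + cassette + template[off + len(cassette):]
            for p in pals:
                pal_truth.append(PalindromeCall(
                    center=pos + off + p["center"],
                    arm_len=p["arm"], loop_len=p["loop"], mismatches=p["mism"],
                    start=pos + off + p["start"], end=pos + off + p["end"],
                ))
            hr_span_truth.append(
                (pos + off + pals[0]["start"], pos + off + pals[-1]["end"],
                 len(pals))
            )
        if sp_idx in nc_spacer_idx:
            t = nc_plants[nc_spacer_idx.index(sp_idx)]
            p_len = len(t.unit)
            arr = (t.unit * (t.span_nt // p_len + 1))[: t.span_nt]
            off = (len(template) - len(arr)) // 2
            # breaker bases chosen so no period-p match crosses the array edge
            pre = "".join(
                "G" if t.unit[(-k) % p_len] != "G" else "A" for k in (2, 1)
            )
            tail_phase = t.span_nt % p_len
            post = "".join(
                "G" if t.unit[(tail_phase + k) % p_len] != "G" else "A"
                for k in (0, 1)
            )
            template = (template[: off - 2] + pre + arr + post
                        + template[off + len(arr) + 2:])
            tr_truth.append({"abs_start": pos + off + 1, "unit": t.unit,
                             "span": t.span_nt, "placement": "noncoding"})
        if both_plant is not None and both_idx is not None and sp_idx == (both_idx + 1) % n:
            # continue the poly-TAA array right after the stop of gene both_idx
            arr_tail = both_plant.span_nt - 3  # the stop codon is copy one
            arr = ("TAA" * (arr_tail // 3 + 1))[:arr_tail]
            template = arr + "CC" + template[arr_tail + 2:]
            tr_truth.append({"abs_start": pos - 2, "unit": "TAA",
                             "span": both_plant.span_nt, "placement": "both"})
        parts.append(template)
        pos += len(template)

    body = "".join(parts)
    assert len(body) == L, (len(body), L)

    # --- promoter stamping (after layout, before chunk filling) ------------
    body_list = list(body)
    motif_truth: list[tuple[int, str, int]] = []
    for p in promoter_plants:
        i = p.orf_index
        if strands[i] == "+":
            atg0 = gene_start0[i]
            lo = atg0 - p.offset_nt - len(p.literal)
            stamp = p.literal
            span = [(lo + k) % L for k in range(len(p.literal))]
        else:
            end0 = gene_start0[i] + gene_nt[i] - 1
            lo = end0 + 1 + p.offset_nt
            stamp = revcomp(p.literal)
            span = [(lo + k) % L for k in range(len(stamp))]
        for k, gpos in enumerate(span):
            body_list[gpos] = stamp[k]
        motif_truth.append((i + 1, p.motif_name, p.offset_nt))
    body = "".join(body_list)

    body = _fill_chunks(rng, body, config.gc)

    genome = CircularGenome(id=f"synth-seed{config.seed}", seq=body)

    # --- truth table -------------------------------------------------------
    feats = []
    labels = _make_labels(n, special_idx)
    for i in range(n):
        start = gene_start0[i] + 1
        end = gene_start0[i] + gene_nt[i]
        feats.append(OrfRecord(start=start, end=end, strand=strands[i],
                               serial=i + 1, label=labels[i]))
    truth.orfs = GeneAnnotation(genome_id=genome.id, features=feats)
    truth.motif_hits = motif_truth
    truth.palindromes = sorted(pal_truth, key=lambda c: c.start)
    truth.hr_spans = sorted(hr_span_truth)

    repeats: list[RepeatCall] = []
    for t in tr_truth:
        if "gene" in t:
            g = t["gene"]
            start = gene_start0[g] + 3 * t["codon_offset"] + 1
            span = t["span"]
        else:
            start = t["abs_start"]
            span = t["span"]
        repeats.append(RepeatCall(
            start=start, end=start + span - 1, unit_len=len(t["unit"]),
            copy_number=round(span / len(t["unit"]), 1),
            consensus_unit=t["unit"], percent_identity=1.0,
            placement=t["placement"],
        ))
    if special_idx is not None:
        g = special_idx
        q0, _ = special_truth["polyq"]
        start = gene_start0[g] + 3 * (q0 - 1) + 1
        span = 3 * config.polyq_len
        repeats.append(RepeatCall(
            start=start, end=start + span - 1, unit_len=3,
            copy_number=float(config.polyq_len), consensus_unit="CAA",
            percent_identity=1.0, placement="coding",
        ))
        truth.proteins[g + 1] = special_protein
        truth.cys_hits[g + 1] = special_truth["cys_hits"]
        truth.polyq[g + 1] = special_truth["polyq"]
    truth.repeats = sorted(repeats, key=lambda r: r.start)
    return genome, truth


def _make_labels(n: int, special_idx: int | None) -> list[str]:
    from .comparative_synteny import load_core_gene_reference

    labels = [""] * n
    labels[0] = "granulin"
    if special_idx is not None:
        labels[special_idx] = "chit-1"
    if n > 94:
        labels[64] = "bro"
        labels[93] = "bro"
    core = sorted(load_core_gene_reference())
    free = [i for i in range(1, n) if not labels[i]]
    stride = max(1, len(free) // max(1, len(core)))
    k = 0
    for name in core:
        while k < len(free) and labels[free[k]]:
            k += 1
        if k >= len(free):
            break
        labels[free[k]] = name
        k += stride
    return labels


def _fill_chunks(rng: np.random.Generator, body: str, gc_target: float) -> str:
    """Replace sentinel bases so the whole genome meets the target GC."""
    arr = np.array(list(body))
    mask = arr == _CHUNK_SENTINEL
    n_free = int(mask.sum())
    if n_free == 0:
        return body
    fixed = arr[~mask]
    fixed_gc = int(np.isin(fixed, ["G", "C"]).sum())
    want_gc = gc_target * len(arr) - fixed_gc
    p_gc = min(max(want_gc / n_free, 0.02), 0.98)
    p = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    arr[mask] = _BASES[rng.choice(4, size=n_free, p=p)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# gene-order perturbation (synteny truth)
# ---------------------------------------------------------------------------

def perturb_gene_order(
    annotation: GeneAnnotation,
    inversions: list[tuple[int, int]],
    spacer_nt: int = 50,
) -> tuple[GeneAnnotation, list[tuple[int, int]]]:
    """Apply serial-span inversions to a gene order.

    ``inversions`` are inclusive (lo_serial, hi_serial) spans; within
    each, gene order and strands are reversed.  Returns the perturbed
    annotation (serials renumbered along the new order, coordinates
    laid out with fixed spacers) and the truth block boundaries in the
    original serial space.
    """
    spans = sorted(inversions)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise SimulationError(f"overlapping inversion spans {(a1, b1)} / {(a2, b2)}")
    order = sorted(annotation.features, key=lambda f: f.serial)
    n = len(order)
    for lo, hi in spans:
        if lo < 1 or hi > n or lo > hi:
            raise SimulationError(f"inversion span {(lo, hi)} outside 1..{n}")
    new_order = list(order)
    for lo, hi in spans:
        seg = new_order[lo - 1 : hi]
        seg = [OrfRecord(start=f.start, end=f.end,
                         strand="-" if f.strand == "+" else "+",
                         serial=f.serial, label=f.label) for f in reversed(seg)]
        new_order[lo - 1 : hi] = seg
    feats = []
    pos = 1
    for i, f in enumerate(new_order, start=1):
        span = f.span_nt
        feats.append(OrfRecord(start=pos, end=pos + span - 1, strand=f.strand,
                               serial=i, label=f.label))
        pos += span + spacer_nt
    blocks: list[tuple[int, int]] = []
    cut = sorted({1, n + 1} | {lo for lo, _ in spans} | {hi + 1 for _, hi in spans})
    for a, b in zip(cut, cut[1:]):
        blocks.append((a, b - 1))
    return GeneAnnotation(genome_id=annotation.genome_id + "-perturbed",
                          features=feats), blocks


# ---------------------------------------------------------------------------
# marker-alignment simulation (bootstrap acceptance)
# ---------------------------------------------------------------------------

def simulate_two_clade_proteins(
    n_per_clade: int = 3,
    length: int = 200,
    d_within: float = 0.03,
    d_between: float = 0.5,
    seed: int = 0,
) -> dict[str, str]:
    """Two well-separated clades of protein sequences.

    Clade ancestors diverge by ~``d_between`` substitutions/site from a
    common root; leaves diverge ~``d_within`` from their ancestor.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def mutate(seq: np.ndarray, d: float) -> np.ndarray:
        out = seq.copy()
        k = rng.binomial(len(seq), d)
        sites = rng.choice(len(seq), size=k, replace=False)
        for s in sites:
            out[s] = rng.choice(aa[aa != out[s]])
        return out

    root = rng.choice(aa, size=length)
    anc = {c: mutate(root, d_between / 2) for c in "AB"}
    seqs = {}
    for c in "AB":
        for i in range(n_per_clade):
            seqs[f"{c}{i + 1}"] = "".join(mutate(anc[c], d_within))
    return seqs
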