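# Methods

This note documents the models and procedures implemented in
`gvannot`, the defaults they ship with, and what the synthetic-genome
tests do and do not demonstrate.

## Coordinates and circularity

All coordinates are 1-based inclusive. A feature spanning the origin
of a circular genome is stored *unwrapped* (`start ≤ L < end`,
`wraps_origin=True`), which keeps interval arithmetic linear; the GFF3
writer emits such features as two CDS segments sharing one `ID`.
`rotate_to_anchor` re-origins the circle at an anchor gene's ATG
(reverse-complementing first if the anchor is on the minus strand); it
is a bijection on positions, so every downstream statistic that should
be rotation-invariant (coding density, k-mer content, skew profile up
to cyclic shift) is tested to be so. N bases are allowed and excluded
from every GC/AT denominator.

## ORF calling

An ORF candidate is a maximal ATG…stop span in any of the six frames,
with frames continuing across the origin (an ORF may wrap at most
once); for each stop only the 5′-most ATG survives. The length filter
is ≥ 150 nt applied to the coding span ATG…last sense codon (a
50-codon protein passes with its stop at 153 nt); a config flag
switches to counting the stop, since the two readings differ by one
codon and published ORF tables rarely say which was used. Only ATG
starts are accepted.

"Minimal overlap" between ORFs is operationalised as longest-first
greedy selection: candidates are sorted by span (ties: earlier start,
then plus strand) and accepted iff they overlap every already-accepted
ORF by at most `max_allowed_overlap_nt` (default 30 nt — baculovirus
ORFs frequently overlap by a few codons). The allowance is a config
knob because published counts depend on an unstated overlap rule;
reproducing a deposited table to ±3 ORFs is the realistic expectation.

## Composition

Windowed GC and GC skew (G−C)/(G+C) with circular wrap (defaults
window 1000 nt, step 100 nt; no published values exist for these, so
they follow common practice for ~100 kb genomes). The cumulative sum
of per-window (G−C) is reported with its extrema as candidate
replication origin/terminus; no formal origin prediction is attempted.

## Promoter motifs

Default inventory: late TTAAG and GATA, early CAKT and TATAWAW
(IUPAC K=G/T, W=A/T); the table is user-editable, since the GATA
entry is reported as a late motif in the source annotation but is not
part of the classical DTAAG late consensus. Windows are 120 nt of the
coding strand 5′ of each ATG (the reported offsets of 8 and 57 nt sit
comfortably inside; configurable), wrapping the origin on circles and
truncating with a flag on linear sequences. Matching runs on the
window and its reverse complement; `offset_nt` counts the bases
strictly between the motif's 3′ end and the A of ATG, so a motif
abutting the start codon has offset 0. A template-strand hit at offset
d is identical to a coding-strand hit of the reverse-complemented
pattern at offset d, and hit literals are always reported as they read
on the genome plus strand.

## Tandem repeats

For every candidate period p (1–500) the genome (doubled, for
circularity) is compared against its own p-shift, giving a
match/mismatch profile. Dense regions are pre-screened with a moving
sum, then refined to the maximum-scoring segment under match +1 /
mismatch −t/(1−t) scoring, where t is the identity threshold (default
0.8, giving penalty 4). This Kadane-style scoring is what makes calls
honest at their boundaries: any prefix or suffix of an optimal segment
keeps identity ≥ t, so a call cannot creep over an array edge by
absorbing terminal mismatches (an earlier longest-run-above-mean rule
did exactly that and systematically inflated copy numbers).

A call's copy number is span/period to 0.1 (fractional final copies
are expected); the consensus unit is a per-offset majority vote.
Overlapping calls and period harmonics (2u shadowing u at comparable
identity) are suppressed in favour of the smaller unit. Defaults
`min_len 24` (the shortest repeat worth reporting in this genome
class is ~25 nt), `min_copies 3`, `min_identity 0.8`. This is an
identity-fraction reimplementation, not a clone of alignment-scored
repeat finders, so counts on real genomes are comparable only with
tolerance.

## Palindromes and homologous regions

An imperfect palindrome is two arms separated by a loop (≤ 20 nt)
whose left arm reverse-complements the right up to `max_mismatch`
substitutions; for each (position, loop) the single maximal call is
the largest arm whose innermost and outermost base pairs match within
the mismatch budget. The implementation is vectorised over arm length
and is exactly equal to a brute-force enumeration (property-tested).

hr regions are single-linkage clusters of palindromes along the
circle. The bare operation defaults (min_arm 8, max_mismatch 2,
cluster_gap 1000, min_cluster 2) follow the loosest published
descriptions, but they have no specificity on an AT-rich genome: with
complementary-pair probability ≈ 0.27 per base, an 8 bp arm with ≤ 2
mismatches occurs by chance every few hundred positions, which is why
the *pipeline's* hr stage uses a calibrated stricter setting —
min_arm 13, max_mismatch 2, overlap dedup (best arm per locus), and
clusters of ≥ 3 palindromes within 200 nt gaps (real hr palindromes
sit tens of bases apart inside their repeat units). Under these
settings the expected chance background is ~20 isolated palindromes
per 112 kb and usually zero spurious clusters; roughly one seed in
five still produces a single chance triple inside an AT-rich coding
stretch, so an hr count from one genome should be read with a ±1
understanding. The deposited-genome checks carry tolerances for the
same reason.

## Protein features

Translation uses the standard genetic code with internal stops as
hard errors naming the offending codon. Molecular weights are
average (not monoisotopic) residue masses plus one water, matching
the convention of protein-MW calculators used in genome reports; the
initiator Met is included. The six-cysteine chitin-binding motif
C-x(13,20)-C-x(5,6)-C-x(9,19)-C-x(10,14)-C-x(4,14)-C is searched by
enumerating every spacer combination over the protein's cysteines;
overlapping hits are kept because tandem CBM_14 domains can share a
cysteine neighbourhood. Homopolymer runs are maximal single-residue
runs above a length threshold.

## Orthologs, synteny, core genes

Ortholog pairing is reciprocal-best local alignment
(Smith–Waterman, BLOSUM62, gap open 11 / extend 1) with similarity =
identities/alignment-length — a deliberate, dependency-free stand-in
for translated-BLAST searches, adequate for gene-order work between
related genomes. Synteny blocks are maximal runs of ortholog pairs
monotone in both serial orders, allowing up to `max_gap_genes`
(default 2) skips in either genome to absorb lineage-specific
insertions; descending runs are inversions, block spans are the hull
of member gene coordinates. A consequence of the gap allowance is
that inversions of fewer than `max_gap_genes + 2` genes can be
absorbed as skips; set `max_gap_genes=0` for strict adjacency when
short inversions matter. The 37-name core-gene reference shipped in
`gvannot/data/core_genes.tsv` is a curated list with aliases; the
audit is label/alias-based (it audits an annotation, it does not do
homology searching).

## Phylogenetics

Progressive alignment: k-mer (k=3) distances → average-linkage guide
order → profile–profile global alignment (Gotoh affine, BLOSUM62,
open 10 / extend 0.5, column scores averaged over residue pairs with
gaps contributing 0). Distances: p-distance or Poisson-corrected
−ln(1−p) (default), with per-pair deletion of gap columns; a
saturated pair (p ≥ 1) is an error rather than a silent clamp.
Neighbor-joining uses the canonical Q-criterion with the standard
branch-length and distance updates (negative branch lengths clamped
to 0); UPGMA is size-weighted average linkage with ultrametric
heights. All agglomeration ties break on the lexicographically
smallest pair of cluster representatives, so trees are reproducible
to the byte. The bootstrap resamples alignment columns with an
explicit seed; support is the fraction of replicate trees containing
each internal bipartition of the full-data tree, written as internal
node labels in Newick output. For an alignment of identical
sequences all branch lengths are 0 and supports are reported for
whatever zero-length resolution the tie-break produces — a star tree
in everything but data structure.

## Synthetic genomes

The generator emulates the headline statistics of a granulovirus
genome — defaults: 112,000 nt circle, GC 0.352, 130 ORFs at ~85 %
coding density with ~53 % of genes on the anchor strand, gene lengths
gamma-distributed between 50 and 1162 aa — and plants, at recorded
coordinates: five promoter motifs at offsets including the reported
8 nt (TTAAG) and 57 nt (template-strand TATAWAW) cases; six tandem
arrays covering coding (CAG ×12.3, poly-CAA ×13), noncoding
(units of 5/7/11 nt, spans 25–323 nt) and boundary-straddling
(poly-TAA continuing the gene's own stop codon) placements; six hr
cassettes of 3–11 imperfect palindromes (arm 13–14, loop 5–8, 0–2
mismatches, AT ≈ 0.73); and one designed 190-aa protein carrying two
six-cysteine domains (whose cysteine spacings admit exactly the two
in-domain chains and no cross-domain chain) plus a 13-residue poly-Q.

Two constructions make exact recovery provable rather than hopeful:

* **Stop scaffolding.** Intergenic spacers are interleaved with the
  cassette `GTTAGAGTTTAGTTAG`, which contains stop codons in all six
  frame phases, no start codon on either strand, and — crucial for
  palindrome specificity — shares no common substring longer than
  2 nt with its own reverse complement, so cassette pairs cannot seed
  inverted repeats (an earlier TTAA-based cassette, being its own
  reverse complement, littered the genome with perfect arm-12
  palindromes). Spacers begin with TTA (a minus-strand stop abutting
  reverse genes) and end with the cassette's TAG abutting the next
  ATG, which pins every candidate ORF to its planted span; the
  cassette spacing bounds any stop-free intergenic stretch well below
  the 150 nt ORF threshold, so the caller's planted-ORF recovery is
  exactly sensitivity = precision = 1.
* **Boundary breakers.** Every planted array and palindrome is
  flanked by bases chosen to mismatch the continuing period (or, for
  palindromes, three forced non-complementary pairs), so detected
  spans equal planted spans and copy numbers are exact.

Whole-genome GC is met by construction: gene codons are sampled from
a base distribution solved (bisection over the 61 sense codons) for
the target GC, and the free intergenic bases are sampled at a
probability solved from the realised GC of everything else, leaving
only binomial noise (≪ 0.01).

What passing these tests shows: the detectors find exactly what the
definitions say, at the signal strengths and noise levels typical of
this genome class. What it does not show: performance on real genomes
with diverged repeat copies, nested gene arrangements, sequencing
errors, or hr palindromes weaker than the calibrated thresholds —
those are exactly the cases the tolerance bands on the
deposited-genome checks exist for. The generator also does not model
codon usage or substitution-process evolution; ortholog tests mutate
proteins i.i.d.

`perturb_gene_order` applies serial-span inversions to an annotation
(order and strands reversed, coordinates re-laid with fixed spacers)
and returns the implied truth blocks, supporting the synteny tests
end to end.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full 112 kb
default genome through every stage (a few seconds per stage), 50
random 2 kb circles against the exhaustive ORF oracle, 20 random
300 nt sequences against the brute-force palindrome oracle, 100
random additive trees of up to 12 taxa for NJ, and 200 bootstrap
replicates on a 6-taxon, 200-residue two-clade simulation — sizes at
which the oracles stay exact and the whole suite completes in well
under a coffee break on one core.
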