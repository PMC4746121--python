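"""Concatenated-marker distance phylogenies.

Workflow: per-marker progressive protein alignment -> column-wise
concatenation -> pairwise distances (p-distance or Poisson-corrected)
-> neighbor-joining (Saitou-Nei, canonical update) or UPGMA ->
nonparametric bootstrap over alignment columns.

Determinism: every agglomeration tie breaks on the lexicographically
smallest pair of cluster representatives (each cluster represented by
its smallest leaf name), and all resampling uses an explicit seed, so
identical inputs give identical trees and supports.

Trees are scikit-bio ``TreeNode`` objects; internal-node ``name``
carries the bootstrap support when supports have been computed, so the
Newick output follows the usual support-label convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from Bio.Align import substitution_matrices

__all__ = [
    "Alignment",
    "progressive_align",
    "concat_markers",
    "distance_matrix",
    "nj_tree",
    "upgma_tree",
    "bipartitions",
    "bootstrap_support",
    "same_topology",
]

GAP = "-"
_AA = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM = substitution_matrices.load("BLOSUM62")
_BL = np.array([[float(_BLOSUM[a][b]) for b in _AA] for a in _AA])


@dataclass
class Alignment:
    taxa: list[str]
    seqs: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)  # name, start, end (0-based half-open)

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        lengths = {len(self.seqs[t]) for t in self.taxa}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.seqs[self.taxa[0]])

    def subsample_columns(self, cols: np.ndarray) -> "Alignment":
        seqs = {t: "".join(self.seqs[t][c] for c in cols) for t in self.taxa}
        return Alignment(taxa=list(self.taxa), seqs=seqs)


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    k = min(k, len(a), len(b))
    if k == 0:
        return 1.0
    from collections import Counter
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    denom = min(sum(ca.values()), sum(cb.values()))
    return 1.0 - shared / denom if denom else 1.0


def _profile_counts(rows: list[str]) -> np.ndarray:
    idx = {a: i for i, a in enumerate(_AA)}
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(_AA)))
    for r in rows:
        for j, ch in enumerate(r):
            i = idx.get(ch)
            if i is not None:
                counts[j, i] += 1
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh affine gaps)."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = ca.shape[0], cb.shape[0]
    denom = max(1, len(rows_a)) * max(1, len(rows_b))
    S = (ca @ _BL @ cb.T) / denom
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in B (consume A)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, nb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, na + 1):
        Si = S[i - 1]
        for j in range(1, nb + 1):
            best = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best + Si[j - 1]
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    # traceback
    i, j = na, nb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            out_a.append("col")
            out_b.append("col")
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            cands = [M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                     Y[i - 1, j] - gap_open]
            prev = int(np.argmax(cands))
            out_a.append("col")
            out_b.append("gap")
            i, state = i - 1, prev
        else:
            cands = [M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                     X[i, j - 1] - gap_open]
            prev = int(np.argmax(cands))
            prev = [0, 2, 1][prev]
            out_a.append("gap")
            out_b.append("col")
            j, state = j - 1, prev
    out_a.reverse()
    out_b.reverse()
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    pa = pb = 0
    for ta, tb in zip(out_a, out_b):
        if ta == "col":
            for r, row in enumerate(rows_a):
                new_a[r] += row[pa]
            pa += 1
        else:
            for r in range(len(rows_a)):
                new_a[r] += GAP
        if tb == "col":
            for r, row in enumerate(rows_b):
                new_b[r] += row[pb]
            pb += 1
        else:
            for r in range(len(rows_b)):
                new_b[r] += GAP
    return new_a, new_b


def progressive_align(
    seqs: dict[str, str], gap_open: float = 10.0, gap_extend: float = 0.5
) -> Alignment:
    """Progressive multiple alignment: k-mer guide tree + profile merging.

    BLOSUM62 column scores, affine gaps (open 10 / extend 0.5).
    """
    names = sorted(seqs)
    if len(names) < 2:
        raise ValueError("progressive_align needs at least 2 sequences")
    # guide order: repeated merge of closest clusters (average linkage on
    # k-mer distances), lexicographic tie-break
    d = {(a, b): _kmer_distance(seqs[a], seqs[b]) for a in names for b in names if a < b}
    clusters: dict[str, list[str]] = {n: [n] for n in names}  # rep -> members
    profiles: dict[str, list[str]] = {n: [seqs[n]] for n in names}
    order: dict[str, list[str]] = {n: [n] for n in names}

    def cdist(r1: str, r2: str) -> float:
        tot = 0.0
        for x in clusters[r1]:
            for y in clusters[r2]:
                tot += d[(min(x, y), max(x, y))]
        return tot / (len(clusters[r1]) * len(clusters[r2]))

    while len(clusters) > 1:
        reps = sorted(clusters)
        best = None
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                dd = cdist(r1, r2)
                if best is None or dd < best[0] - 1e-12:
                    best = (dd, r1, r2)
        _, r1, r2 = best
        rows_a, rows_b = profiles[r1], profiles[r2]
        new_a, new_b = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        rep = min(r1, r2)
        other = max(r1, r2)
        profiles[rep] = new_a + new_b if rep == r1 else new_b + new_a
        order[rep] = (order[r1] + order[r2]) if rep == r1 else (order[r2] + order[r1])
        clusters[rep] = clusters[r1] + clusters[r2]
        del clusters[other], profiles[other], order[other]
    rep = next(iter(clusters))
    rows = profiles[rep]
    member_order = order[rep]
    aligned = {t: rows[k] for k, t in enumerate(member_order)}
    return Alignment(taxa=names, seqs=aligned)


def concat_markers(alignments: dict[str, Alignment]) -> Alignment:
    """Column-wise concatenation of per-marker alignments.

    Taxa are joined by name; a taxon missing a marker gets an all-gap
    partition (with a warning).  Markers sharing no taxon at all are an
    error.
    """
    if not alignments:
        raise ValueError("no marker alignments given")
    marker_names = sorted(alignments)
    all_taxa: list[str] = []
    for m in marker_names:
        for t in alignments[m].taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    common = set(all_taxa)
    for m in marker_names:
        common &= set(alignments[m].taxa)
    if not common:
        raise ValueError("marker alignments share no taxa")
    seqs = {t: "" for t in all_taxa}
    partitions = []
    offset = 0
    for m in marker_names:
        aln = alignments[m]
        width = aln.n_cols
        for t in all_taxa:
            if t in aln.seqs:
                seqs[t] += aln.seqs[t]
            else:
                warnings.warn(f"taxon {t!r} missing marker {m!r}: all-gap row")
                seqs[t] += GAP * width
        partitions.append((m, offset, offset + width))
        offset += width
    return Alignment(taxa=all_taxa, seqs=seqs, partitions=partitions)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(alignment: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with per-pair deletion of gap columns.

    p-distance = mismatches / compared sites; Poisson d = -ln(1 - p).
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    taxa = list(alignment.taxa)
    n = len(taxa)
    D = np.zeros((n, n))
    rows = [alignment.seqs[t] for t in taxa]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            compared = mism = 0
            for x, y in zip(a, b):
                if x == GAP or y == GAP:
                    continue
                compared += 1
                if x != y:
                    mism += 1
            if compared == 0:
                raise ValueError(f"taxa {taxa[i]!r}/{taxa[j]!r}: no comparable sites")
            p = mism / compared
            if model == "p-distance":
                dd = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"taxa {taxa[i]!r}/{taxa[j]!r}: p={p} saturates the Poisson correction"
                    )
                dd = -np.log(1.0 - p)
            D[i, j] = D[j, i] = dd
    return DistanceMatrix(D, ids=taxa)


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def _check_dm(dm: DistanceMatrix) -> None:
    # skbio already enforces symmetry/hollow; keep an explicit guard for
    # raw arrays routed here
    if not np.allclose(dm.data, dm.data.T):
        raise ValueError("distance matrix is not symmetric")


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the canonical Q criterion.

    Deterministic: Q ties break on the lexicographically smallest pair
    of cluster representatives.  Negative branch lengths are clamped to
    zero.  The returned tree is unrooted (trifurcating root).
    """
    _check_dm(dm)
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                D[(a, b)] = float(dm[a, b])

    def get(a: str, b: str) -> float:
        return D[(a, b)] if (a, b) in D else D[(b, a)]

    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in ids}
    active = sorted(ids)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * get(a, b) - r[a] - r[b]
                key = (q, min(a, b), max(a, b))
                if best is None or q < best[0][0] - 1e-12 or (
                    abs(q - best[0][0]) <= 1e-12 and key[1:] < best[0][1:]
                ):
                    best = (key, a, b)
        _, a, b = best
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        child_a, child_b = nodes[a], nodes[b]
        child_a.length, child_b.length = la, lb
        rep = min(a, b)
        new = TreeNode(children=[child_a, child_b])
        for c in active:
            if c in (a, b):
                continue
            D[(rep + "\0u", c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        # rename: internal cluster key carries its smallest leaf
        newkey = rep + "\0u"
        nodes[newkey] = new
        active = sorted([c for c in active if c not in (a, b)] + [newkey])
        # normalise stored distances for the new key
        D = {
            (x, y): v
            for (x, y), v in D.items()
            if (x in active or y in active) or (x not in (a, b) and y not in (a, b))
        }
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    for key, ln in ((a, la), (b, lb), (c, lc)):
        nodes[key].length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """UPGMA (average linkage, ultrametric heights), deterministic ties."""
    _check_dm(dm)
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                dist[(min(a, b), max(a, b))] = float(dm[a, b])
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in ids}
    heights: dict[str, float] = {t: 0.0 for t in ids}
    sizes: dict[str, int] = {t: 1 for t in ids}
    active = sorted(ids)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                dd = dist[(min(a, b), max(a, b))]
                if best is None or dd < best[0] - 1e-12 or (
                    abs(dd - best[0]) <= 1e-12 and (a, b) < (best[1], best[2])
                ):
                    best = (dd, a, b)
        dd, a, b = best
        h = dd / 2.0
        ca, cb = nodes[a], nodes[b]
        ca.length = h - heights[a]
        cb.length = h - heights[b]
        rep = min(a, b)
        new = TreeNode(children=[ca, cb])
        newkey = rep + "\0u"
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dnew = (sizes[a] * dac + sizes[b] * dbc) / (sizes[a] + sizes[b])
            dist[(min(newkey, c), max(newkey, c))] = dnew
        nodes[newkey] = new
        heights[newkey] = h
        sizes[newkey] = sizes[a] + sizes[b]
        active = sorted([c for c in active if c not in (a, b)] + [newkey])
    root = nodes[active[0]]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised to the side that
    excludes the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    full = set(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    return bipartitions(t1) == bipartitions(t2)


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    method: str = "nj",
    model: str = "poisson",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Column bootstrap: support = fraction of replicate trees
    containing each internal bipartition of the full-data tree.

    Internal-node names of the returned tree carry the support values
    (2 decimal fractions) so Newick output is self-describing.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    build = nj_tree if method == "nj" else upgma_tree
    full = build(distance_matrix(alignment, model=model))
    target = bipartitions(full)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = alignment.n_cols
    done = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = alignment.subsample_columns(cols)
        try:
            rep_tree = build(distance_matrix(rep_aln, model=model))
        except ValueError:
            continue  # saturated or incomparable replicate: skipped
        done += 1
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    denom = max(done, 1)
    support = {bp: counts[bp] / denom for bp in target}
    ref = sorted(t.name for t in full.tips())[0]
    full_leaves = {t.name for t in full.tips()}
    for node in full.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        canon = frozenset(full_leaves - side) if ref in side else frozenset(side)
        if canon in support:
            node.name = f"{support[canon]:.2f}"
    return full, support
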