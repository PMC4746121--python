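"""Independent brute-force oracles used by the tests.

These deliberately use the most naive formulation of each definition
(position-by-position walking/enumeration) and share no code with the
package implementations they check.
"""

from __future__ import annotations

import re

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# ORF enumeration: walk every position x strand
# ---------------------------------------------------------------------------

def orf_oracle(seq: str, circular: bool = True, min_len: int = 150,
               include_stop_in_min: bool = False) -> set[tuple[int, int, str]]:
    """All maximal ATG..stop candidates as (start, end, strand), 1-based,
    end possibly unwrapped beyond the sequence length.

    For each stop position only the longest candidate per strand is kept.
    """
    L = len(seq)
    stops = {"TAA", "TAG", "TGA"}
    out: dict[tuple[str, int], tuple[int, int]] = {}
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        work = s + s if circular else s
        limit = L if circular else L - 2
        for a in range(limit):
            if work[a:a + 3] != "ATG":
                continue
            # walk forward codon by codon
            j = a + 3
            span = None
            while j + 3 <= len(work):
                if circular and j + 3 - a > L:
                    break  # would wrap more than once
                if work[j:j + 3] in stops:
                    span = j + 3 - a
                    break
                j += 3
            if span is None:
                continue
            coding = span - 3
            if (span if include_stop_in_min else coding) < min_len:
                continue
            key = (strand, j % L if circular else j)
            prev = out.get(key)
            if prev is None or span > prev[1]:
                out[key] = (a, span)
    result = set()
    for (strand, _), (a, span) in out.items():
        if strand == "+":
            start0 = a % L
        else:
            start0 = (L - (a % L) - span) % L if circular else L - a - span
        result.add((start0 + 1, start0 + span, strand))
    return result


# ---------------------------------------------------------------------------
# palindromes: enumerate every (center, loop, arm)
# ---------------------------------------------------------------------------

def palindrome_oracle(seq: str, min_arm: int, max_loop: int,
                      max_mismatch: int) -> set[tuple[int, int, int, int]]:
    """All maximal imperfect palindromes as (center, loop, arm, mismatches).

    center is the 1-based index of the first loop base; per (center,
    loop) only the largest arm whose innermost and outermost base pairs
    match and whose mismatches stay within the bound is kept.
    """
    n = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "#"}
    out = set()
    for i in range(n):          # first loop base (0-based)
        for loop in range(max_loop + 1):
            best = None
            a = 1
            mism = 0
            while i - a >= 0 and i + loop + a - 1 < n:
                pair_ok = seq[i - a] == comp.get(seq[i + loop + a - 1], "#")
                if not pair_ok:
                    mism += 1
                    if mism > max_mismatch:
                        break
                else:
                    inner_ok = seq[i - 1] == comp.get(seq[i + loop], "#")
                    if inner_ok and a >= min_arm:
                        best = (a, mism)
                a += 1
            if best is not None:
                out.add((i + 1, loop, best[0], best[1]))
    return out


# ---------------------------------------------------------------------------
# IUPAC matching via regex expansion
# ---------------------------------------------------------------------------

_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]",
    "M": "[AC]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


def iupac_regex_oracle(pattern: str, seq: str) -> list[int]:
    regex = "".join(_IUPAC_RE[c] for c in pattern.upper())
    return [m.start() for m in re.finditer(f"(?={regex})", seq.upper())]


# ---------------------------------------------------------------------------
# six-cysteine motif: six nested loops
# ---------------------------------------------------------------------------

def cys_motif_oracle(aa: str, spacers) -> set[tuple[int, int]]:
    cys = [i for i, r in enumerate(aa) if r == "C"]
    hits = set()
    for a in cys:
        for b in cys:
            if not spacers[0][0] <= b - a - 1 <= spacers[0][1]:
                continue
            for c in cys:
                if not spacers[1][0] <= c - b - 1 <= spacers[1][1]:
                    continue
                for d in cys:
                    if not spacers[2][0] <= d - c - 1 <= spacers[2][1]:
                        continue
                    for e in cys:
                        if not spacers[3][0] <= e - d - 1 <= spacers[3][1]:
                            continue
                        for f in cys:
                            if spacers[4][0] <= f - e - 1 <= spacers[4][1]:
                                hits.add((a + 1, f + 1))
    return hits


# ---------------------------------------------------------------------------
# exhaustive 3-way alignment (sum-of-pairs, linear gaps)
# ---------------------------------------------------------------------------

def three_way_sp_oracle(s1: str, s2: str, s3: str, score_pair, gap: float) -> float:
    """Optimal sum-of-pairs score of a 3-way alignment by cubic DP.

    score_pair(a, b) scores two residues; a residue against a gap costs
    ``gap``; gap-gap pairs cost 0.
    """
    n1, n2, n3 = len(s1), len(s2), len(s3)
    NEG = float("-inf")
    dp = [[[NEG] * (n3 + 1) for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    dp[0][0][0] = 0.0
    moves = [(1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                cur = dp[i][j][k]
                if cur == NEG:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > n1 or nj > n2 or nk > n3:
                        continue
                    a = s1[i] if di else None
                    b = s2[j] if dj else None
                    c = s3[k] if dk else None
                    sc = 0.0
                    for x, y in ((a, b), (a, c), (b, c)):
                        if x is not None and y is not None:
                            sc += score_pair(x, y)
                        elif (x is None) != (y is None):
                            sc -= gap
                    val = cur + sc
                    if val > dp[ni][nj][nk]:
                        dp[ni][nj][nk] = val
    return dp[n1][n2][n3]


def sp_score(rows: list[str], score_pair, gap: float) -> float:
    """Sum-of-pairs score of an existing alignment under the same scheme."""
    total = 0.0
    n = len(rows[0])
    for c in range(n):
        col = [r[c] for r in rows]
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                x, y = col[i], col[j]
                if x != "-" and y != "-":
                    total += score_pair(x, y)
                elif (x == "-") != (y == "-"):
                    total -= gap
    return total
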