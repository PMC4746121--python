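"""Base-composition statistics: GC content, windowed GC skew, cumulative skew.

Skew convention: per-window skew is (G - C) / (G + C); the cumulative
profile is the running sum of per-window (G - C) counts, whose extrema
are reported as candidate replication origin/terminus.  N bases are
excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CircularGenome

__all__ = ["gc_content", "at_content", "SkewProfile", "gc_skew_profile"]


def _counts(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in "ACGTN"}


def gc_content(seq: str | CircularGenome) -> float:
    """(G+C)/(A+C+G+T); N excluded.  Error on an empty/all-N sequence."""
    if isinstance(seq, CircularGenome):
        seq = seq.seq
    c = _counts(seq.upper())
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (c["G"] + c["C"]) / denom


def at_content(seq: str | CircularGenome) -> float:
    return 1.0 - gc_content(seq)


@dataclass
class SkewProfile:
    window_nt: int
    step_nt: int
    centers: np.ndarray          # 1-based window-center positions
    gc: np.ndarray               # per-window GC content
    skew: np.ndarray             # per-window (G-C)/(G+C), 0 (flagged) if G+C==0
    skew_undefined: np.ndarray   # True where G+C==0 in the window
    cumulative: np.ndarray       # running sum of per-window (G-C) counts
    sign_convention: str = field(default="(G-C)/(G+C)")

    @property
    def origin_candidate(self) -> int:
        """Window center at the cumulative-skew minimum."""
        return int(self.centers[int(np.argmin(self.cumulative))])

    @property
    def terminus_candidate(self) -> int:
        return int(self.centers[int(np.argmax(self.cumulative))])


def gc_skew_profile(genome: CircularGenome, window_nt: int = 1000, step_nt: int = 100) -> SkewProfile:
    """Windowed GC content/skew of a genome; circular windows wrap.

    Windows start at 1, 1+step, ... ; for a circular genome there are
    ceil(L/step) of them, each of ``window_nt`` bases.
    """
    L = genome.length
    if window_nt > L:
        raise ValueError(f"window {window_nt} exceeds genome length {L}")
    if window_nt < 1 or step_nt < 1:
        raise ValueError("window and step must be positive")
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    if genome.circular:
        n_win = -(-L // step_nt)  # ceil
        arr2 = np.concatenate([arr, arr[: window_nt]])
    else:
        n_win = max(1, (L - window_nt) // step_nt + 1)
        arr2 = arr
    is_g = (arr2 == ord("G")).astype(np.int64)
    is_c = (arr2 == ord("C")).astype(np.int64)
    is_acgt = np.isin(arr2, [ord(b) for b in "ACGT"]).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    cn = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = np.arange(n_win) * step_nt
    ends = starts + window_nt
    g = cg[ends] - cg[starts]
    c = cc[ends] - cc[starts]
    tot = cn[ends] - cn[starts]
    gc_frac = np.where(tot > 0, (g + c) / np.maximum(tot, 1), np.nan)
    undef = (g + c) == 0
    skew = np.where(undef, 0.0, (g - c) / np.maximum(g + c, 1))
    centers = (starts + window_nt // 2) % L + 1
    cumulative = np.cumsum(g - c)
    return SkewProfile(
        window_nt=window_nt, step_nt=step_nt, centers=centers,
        gc=gc_frac, skew=skew, skew_undefined=undef, cumulative=cumulative,
    )
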