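"""Glocal alignment of tagged reads to their target windows.

Alignment is *global in the read* (every read base is consumed) and *local in
the reference* (free end positioning inside the target window) -- the right
contract for primer-anchored amplicon reads that always lie fully inside a
known window.  Affine gap costs: a gap of length k costs
``gap_open + (k - 1) * gap_extend``.

The optimal-score contract is the full affine dynamic programme
(:func:`align_dp`); :meth:`TargetAligner.align` reaches the same optimum
through two exact fast paths (exact substring match; ungapped sliding-window
scan accepted only when the mismatch count is small enough that no gapped
alignment can pay for itself) plus a per-sequence cache, which matters
because UMI families contain many identical reads.

Column projection turns an alignment into a map from reference positions
(and insertion slots keyed by ``(preceding reference position, offset)``) to
read bases, the coordinate system consensus building operates in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Scoring",
    "Alignment",
    "AlignedColumns",
    "align_dp",
    "glocal_align",
    "project",
    "reconstruct",
    "TargetAligner",
    "GAP",
]

GAP = "-"
_NEG = -(10 ** 7)
_MISSING = object()


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4   # cost of the first gap base
    gap_extend: int = -1  # cost of each additional gap base


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Alignment:
    """A read placed in window coordinates.

    ``cigar`` uses M (match/mismatch, consumes both), I (insertion, consumes
    read only) and D (deletion, consumes window only).
    """

    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    score: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def read_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")


class AlignedColumns(NamedTuple):
    """Reference-projected read: per-column bases plus insertion slots."""

    start: int
    end: int
    bases: bytes  # one byte per reference column, '-' marks deletions
    insertions: tuple[tuple[tuple[int, int], str], ...]


def _merge_ops(ops: list[str]) -> tuple[tuple[str, int], ...]:
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return tuple(cigar)


def align_dp(insert: str, window: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """Full affine glocal dynamic programme (the optimality contract).

    Ties are broken by preferring diagonal (M) over deletion over insertion
    during traceback and the smallest window end position, which yields a
    total, deterministic rule.
    """
    n, m = len(insert), len(window)
    if n == 0:
        raise ValueError("empty insert")
    go, ge = scoring.gap_open, scoring.gap_extend
    warr = np.frombuffer(window.encode(), dtype=np.uint8)
    sarr = np.frombuffer(insert.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    I = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in window (consumes read)
    D = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in read (consumes window)
    M[0, :] = 0  # free leading window gap: start anywhere
    kidx = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(warr == sarr[i - 1], scoring.match, scoring.mismatch).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], I[i - 1]), D[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        M[i, 0] = _NEG
        I[i] = np.maximum(M[i - 1] + go, I[i - 1] + ge)
        # D[i, j] = max_{k < j} M[i, k] + go + (j - 1 - k) * ge, via prefix max
        c = M[i] - kidx * ge
        run = np.maximum.accumulate(c)
        D[i, 1:] = run[:-1] + go + (kidx[1:] - 1) * ge
        D[i, 0] = _NEG

    final = np.maximum(M[n], I[n])
    j = int(np.argmax(final))  # first occurrence: smallest end position
    score = int(final[j])
    state = "M" if M[n, j] >= I[n, j] else "I"

    ops: list[str] = []
    i = n
    while i > 0:
        if state == "M":
            ops.append("M")
            prev = (M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            target = M[i, j] - (scoring.match if insert[i - 1] == window[j - 1] else scoring.mismatch)
            if prev[0] == target:
                state = "M"
            elif prev[1] == target:
                state = "D"
            else:
                state = "I"
            i -= 1
            j -= 1
        elif state == "D":
            ops.append("D")
            if M[i, j - 1] + go == D[i, j]:
                state = "M"
            else:
                state = "D"
            j -= 1
        else:  # I
            ops.append("I")
            if M[i - 1, j] + go == I[i, j]:
                state = "M"
            else:
                state = "I"
            i -= 1
    ops.reverse()
    return Alignment(ref_start=j, cigar=_merge_ops(ops), score=score)


class TargetAligner:
    """Aligner for one target window with exact fast paths and a cache.

    ``region_start`` records where the window slice begins on its contig so
    alignment coordinates can be translated back to contig coordinates.
    """

    def __init__(
        self,
        window: str,
        scoring: Scoring = DEFAULT_SCORING,
        score_floor_frac: float = 0.4,
        region_start: int = 0,
        min_insert_len: int = 20,
    ):
        self.window = window
        self.scoring = scoring
        self.score_floor_frac = score_floor_frac
        self.region_start = region_start
        self.min_insert_len = min_insert_len
        self._warr = np.frombuffer(window.encode(), dtype=np.uint8)
        self._views: dict[int, np.ndarray] = {}
        self._cache: dict[str, Alignment | None] = {}
        self.n_unaligned = 0
        # any alignment containing a gap scores at most n*match + gap_open,
        # so an ungapped placement with q mismatches is provably optimal
        # whenever q * (match - mismatch) < -gap_open
        s = scoring
        self._max_ungapped_mm = max(
            0, (-s.gap_open - 1) // (s.match - s.mismatch)
        )

    def _sliding(self, k: int) -> np.ndarray:
        v = self._views.get(k)
        if v is None:
            v = np.lib.stride_tricks.sliding_window_view(self._warr, k)
            self._views[k] = v
        return v

    def align(self, insert: str) -> Alignment | None:
        """Optimal glocal alignment, or None when the score falls below the
        floor (``score_floor_frac * len(insert)``) -- counted in
        ``n_unaligned`` and excluded downstream."""
        if len(insert) < self.min_insert_len:
            raise ValueError(f"insert shorter than {self.min_insert_len} nt")
        hit = self._cache.get(insert, _MISSING)
        if hit is not _MISSING:
            if hit is None:
                self.n_unaligned += 1
            return hit
        aln = self._align_uncached(insert)
        if aln is not None and aln.score < self.score_floor_frac * len(insert):
            aln = None
        self._cache[insert] = aln
        if aln is None:
            self.n_unaligned += 1
        return aln

    #: extra reference columns on each side of the best ungapped diagonal
    #: when running the banded dynamic programme (covers InDels far longer
    #: than any expected edit; boundary hits trigger the unbanded fallback)
    BAND_MARGIN = 60

    def _align_uncached(self, insert: str) -> Alignment | None:
        n, m = len(insert), len(self.window)
        s = self.scoring
        if n > m:
            return align_dp(insert, self.window, s)
        j = self.window.find(insert)
        if j >= 0:
            return Alignment(j, (("M", n),), n * s.match)
        view = self._sliding(n)
        sarr = np.frombuffer(insert.encode(), dtype=np.uint8)
        mm = (view != sarr).sum(axis=1)
        best = int(np.argmin(mm))
        q = int(mm[best])
        if q <= self._max_ungapped_mm:
            return Alignment(best, (("M", n),), (n - q) * s.match + q * s.mismatch)
        # banded acceleration: run the DP on a slice around the best ungapped
        # diagonal; the unbanded result is the contract, so fall back whenever
        # the banded alignment touches the slice edge or misses the floor
        lo = max(0, best - self.BAND_MARGIN)
        hi = min(m, best + n + self.BAND_MARGIN)
        if lo > 0 or hi < m:
            sub = align_dp(insert, self.window[lo:hi], s)
            edge = (lo > 0 and sub.ref_start <= 1) or (hi < m and sub.ref_end >= hi - lo - 1)
            if not edge and sub.score >= self.score_floor_frac * n:
                return Alignment(sub.ref_start + lo, sub.cigar, sub.score)
        return align_dp(insert, self.window, s)


def glocal_align(
    insert: str,
    window: str,
    scoring: Scoring = DEFAULT_SCORING,
    score_floor_frac: float = 0.4,
) -> Alignment | None:
    """One-shot glocal alignment of ``insert`` against ``window``."""
    return TargetAligner(window, scoring, score_floor_frac).align(insert)


def project(alignment: Alignment, insert: str) -> AlignedColumns:
    """Project a read into reference columns.

    Deletion columns map to the gap symbol; inserted bases go to slots keyed
    by ``(preceding reference position, offset >= 1)``.  The projection is
    reversible via :func:`reconstruct`.
    """
    bases = bytearray()
    ins: list[tuple[tuple[int, int], str]] = []
    rp = alignment.ref_start
    qp = 0
    for op, k in alignment.cigar:
        if op == "M":
            bases.extend(insert[qp:qp + k].encode())
            rp += k
            qp += k
        elif op == "D":
            bases.extend(GAP.encode() * k)
            rp += k
        else:  # I
            for off in range(1, k + 1):
                ins.append(((rp - 1, off), insert[qp + off - 1]))
            qp += k
    if qp != len(insert):
        raise ValueError("alignment does not consume the whole read")
    return AlignedColumns(alignment.ref_start, rp, bytes(bases), tuple(ins))


def reconstruct(cols: AlignedColumns) -> str:
    """Rebuild the read sequence from its reference projection."""
    by_pos: dict[int, list[tuple[int, str]]] = {}
    for (pos, off), base in cols.insertions:
        by_pos.setdefault(pos, []).append((off, base))
    out: list[str] = []
    for off, base in sorted(by_pos.get(cols.start - 1, [])):
        out.append(base)
    seq = cols.bases.decode()
    for i, p in enumerate(range(cols.start, cols.end)):
        if seq[i] != GAP:
            out.append(seq[i])
        for off, base in sorted(by_pos.get(p, [])):
            out.append(base)
    return "".join(out)
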