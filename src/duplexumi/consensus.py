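"""UMI-family grouping, single-strand and duplex consensus building.

Reads sharing ``(locus, UMI, strand tag)`` derive from one strand of one
original molecule; their per-column plurality call is the single-strand
consensus (SSC), which removes sequencing errors.  The two opposite-strand
SSCs of one molecule merge into a duplex consensus sequence (DCS): any
column where the strands disagree (including one being N) is masked with N,
which removes PCR errors present on one strand only.  Insertion slots are
treated exactly like substitution columns, with the "no insertion" state
competing as a base.

A directional UMI merge absorbs families whose UMI lies within Hamming
distance 1 of a family at least 3x larger at the same (locus, strand tag);
without it, UMI sequencing errors inflate family counts by roughly
UMI length x error rate.

The per-strand read minimum for a duplex defaults to 1: a duplex needs both
strands, but each strand may be represented by a single read -- duplex
masking, not per-strand depth, is the error control.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tagio import TaggedRead
from .targetalign import GAP, AlignedColumns

__all__ = [
    "UmiFamily",
    "SingleStrandConsensus",
    "DuplexConsensus",
    "group_families",
    "build_ssc",
    "build_dcs",
    "pair_duplexes",
    "dcs_sequence",
    "write_dcs_outputs",
    "consensus_report",
]

_N = ord("N")
_GAP = ord(GAP)
_BASE_BYTES = np.frombuffer(b"ACGT-", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate(_BASE_BYTES):
    _CODE[_b] = _i

MatePair = tuple[AlignedColumns, AlignedColumns]


@dataclass(slots=True)
class UmiFamily:
    locus_id: str
    umi: str
    strand_tag: str
    members: list[MatePair]

    @property
    def read_count(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class SingleStrandConsensus:
    """Per-column plurality consensus of one UMI family.

    ``bases`` holds one byte per reference column over ``[start, end)``:
    ACGT, ``-`` for a consensus deletion, N where no base reaches the
    plurality fraction, and 0 where no read covers the column.
    """

    locus_id: str
    umi: str
    strand_tag: str
    start: int
    end: int
    bases: np.ndarray
    depth: np.ndarray
    insertions: dict[tuple[int, int], str]
    read_count: int


@dataclass(slots=True)
class DuplexConsensus:
    """Strand-merged molecule sequence with N-masked discordance."""

    locus_id: str
    umi: str
    start: int
    end: int
    bases: np.ndarray  # 0 where either strand lacks coverage
    insertions: dict[tuple[int, int], str]
    top_reads: int
    bottom_reads: int

    @property
    def covered(self) -> np.ndarray:
        return self.bases != 0


def _hamming1_neighbours(umi: str) -> Iterable[str]:
    for i, c in enumerate(umi):
        for n in "ACGT":
            if n != c:
                yield umi[:i] + n + umi[i + 1:]


def group_families(
    records: Iterable[tuple[TaggedRead, AlignedColumns, AlignedColumns]],
    merge_size_ratio: int = 3,
) -> list[UmiFamily]:
    """Group aligned read pairs into UMI families and merge UMI errors.

    Exact grouping by ``(locus, umi, strand_tag)`` first; then a family is
    absorbed into a family at the same (locus, strand_tag) whose UMI differs
    at one position and whose size is at least ``merge_size_ratio`` times
    larger (directional merge, smallest families first).
    """
    groups: dict[tuple[str, str, str], list[MatePair]] = {}
    for tagged, c1, c2 in records:
        groups.setdefault((tagged.locus_id, tagged.umi, tagged.strand_tag), []).append((c1, c2))

    if merge_size_ratio > 0:
        order = sorted(groups, key=lambda k: (len(groups[k]), k))
        for key in order:
            members = groups.get(key)
            if members is None:
                continue
            locus, umi, tag = key
            size = len(members)
            best_key = None
            best_size = 0
            for nb in _hamming1_neighbours(umi):
                cand = groups.get((locus, nb, tag))
                if cand is not None and len(cand) >= merge_size_ratio * size:
                    if len(cand) > best_size or (len(cand) == best_size and (best_key is None or nb < best_key[1])):
                        best_key = (locus, nb, tag)
                        best_size = len(cand)
            if best_key is not None:
                groups[best_key].extend(members)
                del groups[key]

    return [
        UmiFamily(locus, umi, tag, members)
        for (locus, umi, tag), members in groups.items()
    ]


def build_ssc(
    family: UmiFamily,
    min_reads: int = 1,
    plurality: float = 0.6,
) -> SingleStrandConsensus | None:
    """Single-strand consensus by per-column plurality.

    A column keeps the plurality base when its fraction of covering reads is
    at least ``plurality`` (boundary inclusive), else N.  Single-read
    families adopt the read's bases.  Both mates of a pair contribute as
    independent coverage.  Insertion slots are called the same way with the
    "absent" state competing as a base.
    """
    if family.read_count < min_reads:
        return None
    pattern_counts = Counter(family.members)
    if len(pattern_counts) == 1:
        ssc = _unanimous_ssc(family, pattern_counts)
        if ssc is not None:
            return ssc
    mates: list[tuple[AlignedColumns, int]] = []
    for (c1, c2), w in pattern_counts.items():
        mates.append((c1, w))
        mates.append((c2, w))
    start = min(c.start for c, _ in mates)
    end = max(c.end for c, _ in mates)
    length = end - start
    counts = np.zeros((length, 5), dtype=np.int32)
    ins_support: dict[tuple[int, int], Counter] = {}
    for c, w in mates:
        idx = _CODE[np.frombuffer(c.bases, dtype=np.uint8)]
        sub = counts[c.start - start: c.end - start]
        sub[np.arange(c.end - c.start), idx] += w
        for slot, base in c.insertions:
            ins_support.setdefault(slot, Counter())[base] += w

    total = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    best_ct = counts[np.arange(length), best]
    bases = np.where(
        best_ct + 1e-9 >= plurality * total, _BASE_BYTES[best], _N
    ).astype(np.uint8)
    bases[total == 0] = 0

    insertions: dict[tuple[int, int], str] = {}
    for slot in sorted(ins_support):
        p = slot[0]
        support = ins_support[slot]
        covering = sum(w for c, w in mates if c.start <= p and p + 1 < c.end)
        n_support = sum(support.values())
        covering = max(covering, n_support)
        absent = covering - n_support
        base, base_ct = max(support.items(), key=lambda kv: (kv[1], kv[0]))
        if absent > base_ct or (absent == base_ct):
            winner, w_ct = None, absent  # ties go to "no insertion"
        else:
            winner, w_ct = base, base_ct
        if w_ct + 1e-9 >= plurality * covering:
            if winner is not None:
                insertions[slot] = winner
        else:
            insertions[slot] = "N"

    return SingleStrandConsensus(
        family.locus_id, family.umi, family.strand_tag,
        start, end, bases, total.astype(np.int32), insertions, family.read_count,
    )


def _unanimous_ssc(
    family: UmiFamily,
    pattern_counts: Counter,
) -> SingleStrandConsensus | None:
    """Fast path: every member read pair is identical, so the consensus is
    the pattern itself wherever the two mates do not contradict each other.
    Returns None (punting to the general path) when the mates disagree in
    their overlap or report insertions."""
    (c1, c2), w = next(iter(pattern_counts.items()))
    if c1.insertions or c2.insertions:
        return None
    start = min(c1.start, c2.start)
    end = max(c1.end, c2.end)
    bases = np.zeros(end - start, dtype=np.uint8)
    depth = np.zeros(end - start, dtype=np.int32)
    for c in (c1, c2):
        arr = np.frombuffer(c.bases, dtype=np.uint8)
        sl = slice(c.start - start, c.end - start)
        prev = bases[sl]
        conflict = (prev != 0) & (prev != arr)
        if conflict.any():
            return None
        bases[sl] = arr
        depth[sl] += w
    return SingleStrandConsensus(
        family.locus_id, family.umi, family.strand_tag,
        start, end, bases, depth, {}, family.read_count,
    )


def build_dcs(
    ssc_a: SingleStrandConsensus,
    ssc_b: SingleStrandConsensus,
    min_reads_per_strand: int = 1,
) -> DuplexConsensus | None:
    """Merge two opposite-strand SSCs of one molecule.

    Both SSCs are in reference (top-strand) orientation -- the pipeline
    aligns bottom-family reads after rotating them back to reference
    orientation.  Agreeing columns keep the base; disagreeing columns
    (including one side N) become N; the covered span is the intersection.
    Insertion slots survive only when both strands call the same inserted
    base; one-strand slots are discordant and are masked (no insertion).
    The result is symmetric in argument order.
    """
    if (ssc_a.locus_id, ssc_a.umi) != (ssc_b.locus_id, ssc_b.umi):
        raise ValueError("SSCs do not belong to the same (locus, UMI)")
    if ssc_a.strand_tag == ssc_b.strand_tag:
        raise ValueError("duplex requires opposite strand tags")
    if min(ssc_a.read_count, ssc_b.read_count) < min_reads_per_strand:
        return None
    start = max(ssc_a.start, ssc_b.start)
    end = min(ssc_a.end, ssc_b.end)
    if end <= start:
        return None
    ba = ssc_a.bases[start - ssc_a.start: end - ssc_a.start]
    bb = ssc_b.bases[start - ssc_b.start: end - ssc_b.start]
    covered = (ba != 0) & (bb != 0)
    bases = np.where(covered, np.where(ba == bb, ba, _N), 0).astype(np.uint8)

    insertions: dict[tuple[int, int], str] = {}
    for slot in set(ssc_a.insertions) | set(ssc_b.insertions):
        p = slot[0]
        if not (start <= p and p + 1 < end):
            continue
        va = ssc_a.insertions.get(slot)
        vb = ssc_b.insertions.get(slot)
        if va is not None and va == vb and va != "N":
            insertions[slot] = va

    top, bottom = (ssc_a, ssc_b) if ssc_a.strand_tag == "TT" else (ssc_b, ssc_a)
    return DuplexConsensus(
        ssc_a.locus_id, ssc_a.umi, start, end, bases, insertions,
        top.read_count, bottom.read_count,
    )


def pair_duplexes(
    sscs: Sequence[SingleStrandConsensus],
    min_reads_per_strand: int = 1,
) -> tuple[list[DuplexConsensus], dict]:
    """Pair SSCs by (locus, UMI) with opposite tags and build all duplexes.

    Molecules sequenced on one strand only contribute to SSC statistics but
    never to duplexes.  Returns (duplexes, stats).
    """
    by_mol: dict[tuple[str, str], list[SingleStrandConsensus]] = {}
    for s in sscs:
        by_mol.setdefault((s.locus_id, s.umi), []).append(s)
    duplexes: list[DuplexConsensus] = []
    n_single = 0
    for key in by_mol:
        group = by_mol[key]
        tags = {s.strand_tag for s in group}
        if len(tags) < 2:
            n_single += len(group)
            continue
        top = max((s for s in group if s.strand_tag == "TT"), key=lambda s: s.read_count)
        bot = max((s for s in group if s.strand_tag == "GG"), key=lambda s: s.read_count)
        d = build_dcs(top, bot, min_reads_per_strand)
        if d is not None:
            duplexes.append(d)
    stats = {"n_ssc": len(sscs), "n_dcs": len(duplexes), "n_single_strand_only": n_single}
    return duplexes, stats


def dcs_sequence(dcs: DuplexConsensus) -> str:
    """Called molecule sequence over the duplex span: masked or uncovered
    columns as N, consensus deletions dropped, insertions interleaved."""
    by_pos: dict[int, list[tuple[int, str]]] = {}
    for (p, off), base in dcs.insertions.items():
        by_pos.setdefault(p, []).append((off, base))
    out: list[str] = []
    for i, p in enumerate(range(dcs.start, dcs.end)):
        b = dcs.bases[i]
        if b == 0:
            out.append("N")
        elif b != ord(GAP):
            out.append(chr(b))
        for _, base in sorted(by_pos.get(p, [])):
            out.append(base)
    return "".join(out)


def write_dcs_outputs(duplexes: Sequence[DuplexConsensus], fasta_path, table_path) -> None:
    """Unaligned FASTA of duplex consensus sequences (N-containing) plus a
    TSV of (locus, umi, top reads, bottom reads, span)."""
    import pandas as pd

    with open(fasta_path, "w") as fh:
        for d in duplexes:
            fh.write(f">{d.locus_id}:{d.umi}\n{dcs_sequence(d)}\n")
    pd.DataFrame(
        [
            {"locus_id": d.locus_id, "umi": d.umi, "top_reads": d.top_reads,
             "bottom_reads": d.bottom_reads, "span_start": d.start,
             "span_end": d.end}
            for d in duplexes
        ]
    ).to_csv(table_path, sep="\t", index=False)


def consensus_report(
    families: Sequence[UmiFamily],
    sscs: Sequence[SingleStrandConsensus],
    duplexes: Sequence[DuplexConsensus],
) -> dict:
    """Stage metrics: family/SSC/DCS counts, mean reads per UMI and per-locus
    duplex counts."""
    per_locus: dict[str, int] = {}
    for d in duplexes:
        per_locus[d.locus_id] = per_locus.get(d.locus_id, 0) + 1
    n_reads = sum(f.read_count for f in families)
    return {
        "n_families": len(families),
        "n_ssc": len(sscs),
        "n_dcs": len(duplexes),
        "mean_reads_per_umi": (n_reads / len(families)) if families else 0.0,
        "duplex_count_per_locus": dict(sorted(per_locus.items())),
    }
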