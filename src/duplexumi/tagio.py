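"""Read-pair parsing: UMI / strand-tag extraction, SPE locus assignment, QC.

Read 1 of a duplex-adapter library starts with a 12-nt UMI followed by a
2-nt strand tag (TT = top-strand family, GG = bottom).  Read 2 starts at the
locus-specific (SPE) primer.  This module turns raw read pairs into
:class:`TaggedRead` records and keeps exact per-reason rejection counters so
every input pair is accounted for exactly once.

Design notes: the strand tag must match TT or GG *exactly* -- a 1-mismatch
rescue on a 2-nt tag would merge opposite strands, the single most damaging
error for duplex logic.  UMIs containing N (or any non-ACGT symbol) are
rejected rather than repaired, because a wrong UMI silently merges molecules.
Primer matching tolerates one mismatch but must anchor at position 0 of
read 2, since SPE amplicons are primer-anchored by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = [
    "TaggedRead",
    "TagConfig",
    "StageReport",
    "extract_tags",
    "assign_locus",
    "qc_filter",
    "process_read_pairs",
    "read_fastq_pairs",
]

STRAND_TAGS = ("TT", "GG")
_ACGT = frozenset("ACGT")


@dataclass(slots=True)
class TaggedRead:
    read_id: str
    umi: str
    strand_tag: str
    locus_id: str | None
    insert_r1: str
    insert_r2: str
    qual_r1: str
    qual_r2: str


@dataclass(frozen=True)
class TagConfig:
    umi_len: int = 12
    max_primer_mismatch: int = 1
    min_mean_quality: float = 20.0
    min_insert_len: int = 30


@dataclass
class StageReport:
    """Per-stage accounting; ``n_pass + sum(rejections) == n_total``."""

    n_total: int = 0
    n_pass: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1

    def as_dict(self) -> dict:
        return {"total": self.n_total, "passed": self.n_pass,
                "rejected": dict(sorted(self.rejections.items()))}


def extract_tags(
    name: str,
    seq1: str,
    qual1: str,
    seq2: str,
    qual2: str,
    umi_len: int = 12,
) -> tuple[TaggedRead | None, str | None]:
    """Split read 1 into UMI, strand tag and genomic insert.

    Returns ``(tagged, None)`` on success or ``(None, reason)`` with reason
    ``short_read1``, ``ambiguous_umi`` or ``invalid_tag``.
    """
    k = umi_len + 2
    if len(seq1) <= k:
        return None, "short_read1"
    umi = seq1[:umi_len]
    if not _ACGT.issuperset(umi):
        return None, "ambiguous_umi"
    tag = seq1[umi_len:k]
    if tag not in STRAND_TAGS:
        return None, "invalid_tag"
    return (
        TaggedRead(name, umi, tag, None, seq1[k:], seq2, qual1[k:], qual2),
        None,
    )


def _exact_primer_index(primers: Sequence[tuple[str, str]]) -> dict[str, tuple[str, int]]:
    index: dict[str, tuple[str, int]] = {}
    for locus, pseq in primers:
        if pseq in index:
            raise ValueError(f"duplicate primer sequence for {locus}")
        index[pseq] = (locus, len(pseq))
    return index


def assign_locus(
    tagged: TaggedRead,
    primers: Sequence[tuple[str, str]],
    max_mismatch: int = 1,
    _exact: dict[str, tuple[str, int]] | None = None,
) -> str | None:
    """Assign the locus whose SPE primer matches the start of read 2.

    ``primers`` is a sequence of ``(locus_id, primer_sequence)``.  The best
    primer must anchor at position 0 of read 2 with at most ``max_mismatch``
    mismatches and beat every other primer; on success the primer bases are
    trimmed from ``insert_r2``.  Returns the rejection reason (``off_target``
    or ``ambiguous_primer``) when no unique assignment exists.
    """
    if not primers:
        raise ValueError("primer set must be non-empty")
    r2 = tagged.insert_r2
    if _exact is not None:
        plen = next(iter(_exact.values()))[1]
        hit = _exact.get(r2[:plen])
        if hit is not None:
            tagged.locus_id = hit[0]
            tagged.insert_r2 = r2[hit[1]:]
            tagged.qual_r2 = tagged.qual_r2[hit[1]:]
            return None
    best: tuple[int, str, int] | None = None  # (mismatches, locus, primer_len)
    n_best = 0
    for locus, pseq in primers:
        if len(r2) < len(pseq):
            continue
        if r2.startswith(pseq):
            mm = 0
        else:
            mm = 0
            for a, b in zip(r2, pseq):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            if mm > max_mismatch:
                continue
        if best is None or mm < best[0]:
            best = (mm, locus, len(pseq))
            n_best = 1
        elif mm == best[0]:
            n_best += 1
    if best is None:
        return "off_target"
    if n_best > 1:
        return "ambiguous_primer"
    _, locus, plen = best
    tagged.locus_id = locus
    tagged.insert_r2 = r2[plen:]
    tagged.qual_r2 = tagged.qual_r2[plen:]
    return None


_qual_sum_cache: dict[str, int] = {}


def _mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    s = _qual_sum_cache.get(qual)
    if s is None:
        if len(_qual_sum_cache) > 65536:
            _qual_sum_cache.clear()
        s = sum(map(ord, qual))
        _qual_sum_cache[qual] = s
    return s / len(qual) - 33.0


def qc_filter(
    tagged: TaggedRead,
    min_mean_quality: float = 20.0,
    min_insert_len: int = 30,
) -> str | None:
    """Post-assignment quality control; returns a failure reason or None.

    Both genomic inserts must reach ``min_insert_len`` and the mean Phred
    quality over both inserts must reach ``min_mean_quality``.
    """
    if min(len(tagged.insert_r1), len(tagged.insert_r2)) < min_insert_len:
        return "short_insert"
    q = tagged.qual_r1 + tagged.qual_r2
    if _mean_quality(q) < min_mean_quality:
        return "low_quality"
    return None


def process_read_pairs(
    pairs: Iterable[tuple[str, str, str, str, str]],
    primers: Sequence[tuple[str, str]],
    config: TagConfig = TagConfig(),
) -> tuple[list[TaggedRead], StageReport]:
    """Run extract -> locus assignment -> QC over a stream of read pairs."""
    report = StageReport()
    out: list[TaggedRead] = []
    # exact-prefix shortcut, valid only for a uniform-length primer panel
    exact = None
    if len({len(p) for _, p in primers}) == 1:
        exact = _exact_primer_index(primers)
    for name, s1, q1, s2, q2 in pairs:
        report.n_total += 1
        tagged, reason = extract_tags(name, s1, q1, s2, q2, config.umi_len)
        if tagged is None:
            report.reject(reason)
            continue
        reason = assign_locus(tagged, primers, config.max_primer_mismatch, exact)
        if reason is not None:
            report.reject(reason)
            continue
        reason = qc_filter(tagged, config.min_mean_quality, config.min_insert_len)
        if reason is not None:
            report.reject(reason)
            continue
        report.n_pass += 1
        out.append(tagged)
    return out, report


def read_fastq_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
) -> Iterator[tuple[str, str, str, str, str]]:
    """Stream synchronised (name, seq1, qual1, seq2, qual2) tuples from a
    FASTQ pair (plain or gzipped); raises on desynchronised or truncated
    files with the failing record index."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        idx = 0
        it2 = iter(f2)
        for rec1 in f1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError(f"read 2 file truncated at record {idx}") from None
            n1 = rec1.name.removesuffix("/1")
            n2 = rec2.name.removesuffix("/2")
            if n1 != n2:
                raise ValueError(f"record {idx}: mismatched ids {n1!r} vs {n2!r}")
            if rec1.quality is None or rec2.quality is None:
                raise ValueError(f"record {idx}: missing quality string")
            yield (n1, rec1.sequence, rec1.quality, rec2.sequence, rec2.quality)
            idx += 1
        try:
            next(it2)
        except StopIteration:
            return
        raise ValueError(f"read 1 file truncated at record {idx}")
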