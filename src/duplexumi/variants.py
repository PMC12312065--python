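"""Variant calling from duplex consensus sequences.

Every non-N duplex column that differs from the reference yields an
observation; adjacent deletion columns merge into one deletion, insertion
slots yield insertions, and InDels are left-normalized against the
reference so "the same exact mutation" is well defined as identity of the
normalized (contig, pos, ref, alt) tuple.  The mutation frequency is the
ratio of mutant duplex consensus count to the total number of duplex
consensus sequences making a non-N call at the position.

Observations near a duplex coverage edge are discarded (edge-anchoring
guard): an InDel that sits within a few bases of an alignment end is
routinely misrepresented as substitutions, because the optimal alignment
of a short trailing stub prefers mismatches over opening a gap.  The guard
default (8 columns) therefore exceeds the longest expected edit length by a
comfortable margin.  Reported variants are restricted to the declared
target windows.

The replicate-aware filter encodes the duplex-count x replicate heuristics:
a variant is accepted when supported by at least 2 duplex molecules in all
3 replicates, or by 5 or more duplex molecules in at least 2 replicates;
the boundary case (4, 4, 0) is rejected.  A PAM-proximity annotation flags
variants with an NGG (or CCN on the reverse orientation) motif within three
nucleotides, the signature of a plausible Cas9 editing site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .consensus import DuplexConsensus
from .simlib import EditSpec, ReferenceSet, TargetWindow

__all__ = [
    "Observation",
    "left_normalize",
    "call_dcs_variants",
    "duplex_depth",
    "aggregate_counts",
    "replicate_filter",
    "detection_contingency",
    "pam_proximity",
    "edit_to_variant",
    "write_vcf",
    "read_vcf",
    "write_variant_table",
]

_N = ord("N")
_GAP = ord("-")

#: columns next to a coverage edge where observations are never called;
#: must exceed the longest expected InDel so end-anchored gap/substitution
#: ambiguities cannot leak through
DEFAULT_EDGE_GUARD = 8

DEFAULT_RULES: tuple[tuple[int, int], ...] = ((2, 3), (5, 2))
_RULE_NAMES = {(2, 3): "three_rep_min2", (5, 2): "two_rep_min5"}


class Observation(NamedTuple):
    """One mutant call on one duplex consensus (contig coordinates,
    left-normalized; empty ref = insertion, empty alt = deletion)."""

    contig: str
    pos: int
    ref: str
    alt: str
    kind: str
    dist_to_frag_end: int  # distance from the adapter-proximal fragment end


def left_normalize(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize a variant against its contig: trim shared bases, shift pure
    InDels left while the preceding reference base equals the allele's last
    base (the standard VCF-style left alignment)."""
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    while (not ref) != (not alt) and pos > 0:
        longer = ref or alt
        if seq[pos - 1] != longer[-1]:
            break
        pos -= 1
        if ref:
            ref = seq[pos] + ref[:-1]
        else:
            alt = seq[pos] + alt[:-1]
    return pos, ref, alt


def call_dcs_variants(
    dcs: DuplexConsensus,
    contig: str,
    contig_seq: str,
    region_start: int,
    window: TargetWindow | None = None,
    edge_guard: int = DEFAULT_EDGE_GUARD,
) -> list[Observation]:
    """Mutant observations on one duplex consensus.

    ``region_start`` translates the DCS's alignment-region coordinates to
    contig coordinates.  N columns never call; observations within
    ``edge_guard`` columns of a coverage-run edge are discarded; when
    ``window`` is given only variants inside it are reported.
    """
    bases = dcs.bases
    cov = bases != 0
    if not cov.any():
        return []
    n = bases.shape[0]
    # contiguous coverage runs and their interiors
    interior = np.zeros(n, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], cov, [False])).astype(np.int8)))
    runs = edges.reshape(-1, 2)  # [start, end) pairs
    for a, b in runs:
        if b - a > 2 * edge_guard:
            interior[a + edge_guard: b - edge_guard] = True

    ref_arr = np.frombuffer(
        contig_seq.encode(), dtype=np.uint8
    )[region_start + dcs.start: region_start + dcs.start + n]
    callable_ = cov & interior & (bases != _N)
    gap_full = cov & (bases == _GAP)
    snv = callable_ & ~gap_full & (bases != ref_arr)

    obs: list[Observation] = []

    def emit(pos0: int, ref: str, alt: str, kind: str) -> None:
        cpos = region_start + dcs.start + pos0
        npos, nref, nalt = left_normalize(contig_seq, cpos, ref, alt)
        if window is not None and not (window.start <= npos < window.end):
            return
        obs.append(Observation(contig, npos, nref, nalt, kind,
                               dcs.end - (dcs.start + pos0)))

    for p in np.flatnonzero(snv):
        emit(int(p), chr(ref_arr[p]), chr(bases[p]), "SNV")

    if gap_full.any():
        gedges = np.flatnonzero(np.diff(np.concatenate(([False], gap_full, [False])).astype(np.int8)))
        for a, b in gedges.reshape(-1, 2):
            if not interior[a:b].all():  # deletion truncated by an edge
                continue
            # a gap run flanked by a masked column is a truncated version of
            # a longer discordant event -- ambiguous evidence, never called
            if a == 0 or b == n or bases[a - 1] == _N or bases[b] == _N:
                continue
            emit(int(a), contig_seq[region_start + dcs.start + a: region_start + dcs.start + b], "", "deletion")

    by_anchor: dict[int, dict[int, str]] = {}
    for (p, off), base in dcs.insertions.items():
        by_anchor.setdefault(p, {})[off] = base
    for p, offs in by_anchor.items():
        k = len(offs)
        if sorted(offs) != list(range(1, k + 1)) or "N" in offs.values():
            continue
        if not (interior[p - dcs.start] and interior[p + 1 - dcs.start]):
            continue
        seq = "".join(offs[i] for i in range(1, k + 1))
        emit(p + 1 - dcs.start, "", seq, "insertion")
    return obs


def duplex_depth(duplexes: Sequence[DuplexConsensus], region_len: int) -> np.ndarray:
    """Per-position count of duplexes making a non-N call (region coords).

    An N cannot support either allele, so N columns do not count toward the
    frequency denominator; consensus deletion columns do.
    """
    delta = np.zeros(region_len + 1, dtype=np.int64)
    extra = np.zeros(region_len, dtype=np.int64)
    for d in duplexes:
        cov = d.bases != 0
        edges = np.flatnonzero(np.diff(np.concatenate(([False], cov, [False])).astype(np.int8)))
        for a, b in edges.reshape(-1, 2):
            delta[d.start + a] += 1
            delta[d.start + b] -= 1
        for p in np.flatnonzero(d.bases == _N):
            extra[d.start + p] -= 1
    return np.cumsum(delta[:-1]) + extra


def aggregate_counts(
    observations: Iterable[Observation],
    duplexes: Sequence[DuplexConsensus],
    region_start: int,
    region_len: int,
    locus_id: str,
) -> pd.DataFrame:
    """Group observations by exact normalized variant and attach the duplex
    depth denominator at each variant position."""
    depth = duplex_depth(duplexes, region_len)

    def depth_at(o: Observation) -> int:
        p = o.pos - region_start
        if o.kind == "insertion":
            p = p - 1  # depth at the base preceding the insertion point
        return int(depth[p]) if 0 <= p < region_len else 0

    rows: dict[tuple, dict] = {}
    for o in observations:
        key = (o.contig, o.pos, o.ref, o.alt)
        r = rows.get(key)
        if r is None:
            rows[key] = r = {
                "locus_id": locus_id, "contig": o.contig, "pos": o.pos,
                "ref": o.ref, "alt": o.alt, "kind": o.kind,
                "mutant_duplex_count": 0, "total_duplex_depth": depth_at(o),
            }
        r["mutant_duplex_count"] += 1
    df = pd.DataFrame(
        rows.values(),
        columns=["locus_id", "contig", "pos", "ref", "alt", "kind",
                 "mutant_duplex_count", "total_duplex_depth"],
    )
    if len(df):
        df["frequency"] = df["mutant_duplex_count"] / df["total_duplex_depth"].clip(lower=1)
        df = df.sort_values(["contig", "pos", "ref", "alt"]).reset_index(drop=True)
    else:
        df["frequency"] = pd.Series(dtype=float)
    return df


KEY_COLS = ["contig", "pos", "ref", "alt"]


def replicate_filter(
    tables: Sequence[pd.DataFrame],
    rules: tuple[tuple[int, int], ...] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Replicate-aware duplex-count filter.

    ``rules`` is a tuple of ``(min_count, min_replicates)`` alternatives; a
    variant passes when any rule is satisfied.  The defaults accept a
    variant seen with >= 2 duplex counts in all 3 replicates or >= 5 duplex
    counts in at least 2; counts (4, 4, 0) are rejected.  Rejected variants
    are retained with their status.
    """
    n_reps = len(tables)
    if n_reps < 2:
        raise ValueError("replicate filter needs at least two replicate tables")
    if rules == DEFAULT_RULES and n_reps not in (2, 3):
        raise ValueError(
            f"default rules are calibrated for 2-3 replicates, got {n_reps}; "
            "pass explicit rules"
        )
    keys: dict[tuple, dict] = {}
    for i, tbl in enumerate(tables):
        for row in tbl.itertuples(index=False):
            key = (row.contig, row.pos, row.ref, row.alt)
            rec = keys.get(key)
            if rec is None:
                keys[key] = rec = {
                    "contig": row.contig, "pos": row.pos, "ref": row.ref,
                    "alt": row.alt, "kind": row.kind,
                    "counts": [0] * n_reps, "freqs": [0.0] * n_reps,
                }
            rec["counts"][i] = int(row.mutant_duplex_count)
            rec["freqs"][i] = float(row.frequency)
    out = []
    for rec in keys.values():
        counts = rec["counts"]
        rule_fired = "rejected"
        for mc, mr in rules:
            if sum(c >= mc for c in counts) >= mr:
                rule_fired = _RULE_NAMES.get((mc, mr), f"min{mc}_in_{mr}reps")
                break
        out.append({
            **{k: rec[k] for k in ("contig", "pos", "ref", "alt", "kind")},
            **{f"count_rep{i + 1}": c for i, c in enumerate(counts)},
            "counts": tuple(counts),
            "n_replicates_detected": sum(c > 0 for c in counts),
            "mean_frequency": float(np.mean(rec["freqs"])),
            "rule": rule_fired,
            "status": "pass" if rule_fired != "rejected" else "rejected",
        })
    df = pd.DataFrame(out)
    if len(df):
        df = df.sort_values(["contig", "pos", "ref", "alt"]).reset_index(drop=True)
    return df


def detection_contingency(
    decisions: pd.DataFrame,
    truth_keys: set[tuple] | None = None,
) -> pd.DataFrame:
    """Duplex-count x replicate-count contingency (heat-map data).

    Each variant contributes one cell at (its smallest positive per-replicate
    duplex count, number of replicates detected); when truth is available,
    cells are split into expected/unexpected.
    """
    rows: dict[tuple, int] = {}
    for row in decisions.itertuples(index=False):
        pos_counts = [c for c in row.counts if c > 0]
        if not pos_counts:
            continue
        label = ""
        if truth_keys is not None:
            key = (row.contig, row.pos, row.ref, row.alt)
            label = "expected" if key in truth_keys else "unexpected"
        cell = (min(pos_counts), len(pos_counts), label)
        rows[cell] = rows.get(cell, 0) + 1
    return pd.DataFrame(
        [
            {"min_duplex_count": c, "n_replicates": r, "label": lab, "n_variants": n}
            for (c, r, lab), n in sorted(rows.items())
        ]
    )


def pam_proximity(contig_seq: str, pos: int, window: int = 3) -> bool:
    """True iff an NGG motif (or CCN, its reverse-strand image) has any base
    within ``window`` nucleotides of ``pos``."""
    lo = max(0, pos - window - 2)
    hi = min(len(contig_seq) - 3, pos + window)
    for i in range(lo, hi + 1):
        if contig_seq[i + 1: i + 3] == "GG" or contig_seq[i: i + 2] == "CC":
            return True
    return False


def edit_to_variant(contig_seq: str, edit: EditSpec) -> tuple[str, int, str, str]:
    """Normalized (contig, pos, ref, alt) key of a programmed edit, for
    matching called variants against ground truth."""
    pos, ref, alt = left_normalize(contig_seq, edit.start, edit.ref_allele, edit.alt_allele)
    return (edit.contig, pos, ref, alt)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_vcf(
    calls: pd.DataFrame,
    ref: ReferenceSet,
    path: str | Path,
    sample_id: str = "sample",
) -> None:
    """Write calls as VCF 4.2 with anchored InDel records.

    A deletion at 0-based ``pos`` becomes POS ``pos`` (the 1-based anchor at
    ``pos - 1``) with REF = anchor + deleted bases; insertions mirror that.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=duplexumi",
    ]
    for name, seq in ref.contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines += [
        '##INFO=<ID=DPX,Number=1,Type=Integer,Description="Mutant duplex consensus count">',
        '##INFO=<ID=DPD,Number=1,Type=Integer,Description="Total duplex consensus depth at site">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Mutant duplex frequency">',
        '##INFO=<ID=STATUS,Number=1,Type=String,Description="Replicate filter status">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for row in calls.itertuples(index=False):
        seq = ref.contigs[row.contig]
        pos, vref, valt = int(row.pos), row.ref, row.alt
        if vref and valt:  # SNV / MNV
            vcf_pos, r, a = pos + 1, vref, valt
        else:  # anchored InDel
            if pos == 0:
                raise ValueError("cannot anchor an InDel at contig position 0")
            anchor = seq[pos - 1]
            vcf_pos = pos
            r = anchor + vref
            a = anchor + valt
        status = getattr(row, "status", None)
        info = (
            f"DPX={int(row.mutant_duplex_count)};DPD={int(row.total_duplex_depth)};"
            f"AF={float(row.frequency):.6g}"
        )
        if status is not None:
            info += f";STATUS={status}"
        lines.append(f"{row.contig}\t{vcf_pos}\t.\t{r}\t{a}\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Parse a VCF written by :func:`write_vcf` back into the internal
    normalized representation (round-trip safe)."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index else vf:
            for alt in rec.alts or ():
                ref, a = rec.ref, alt
                pos = rec.pos - 1
                while ref and a and ref[0] == a[0]:
                    pos += 1
                    ref, a = ref[1:], a[1:]
                kind = "SNV" if ref and a else ("deletion" if ref else "insertion")
                rows.append({
                    "contig": rec.chrom, "pos": pos, "ref": ref, "alt": a,
                    "kind": kind,
                    "mutant_duplex_count": int(rec.info["DPX"]),
                    "total_duplex_depth": int(rec.info["DPD"]),
                    "frequency": float(rec.info["AF"]),
                })
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "kind",
                       "mutant_duplex_count", "total_duplex_depth", "frequency"],
    )


def write_variant_table(calls: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated per-sample variant table."""
    calls.to_csv(path, sep="\t", index=False)
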