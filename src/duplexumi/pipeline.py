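"""End-to-end sample processing: tag -> align -> consensus -> call.

``run_sample`` consumes a stream of raw read pairs and produces the
per-sample duplex variant table plus stage reports; ``call_replicates``
applies the replicate-aware duplex-count filter across samples.  Alignment
happens against a per-locus reference slice that extends far enough past the
target window to place every read of any simulated or size-selected
fragment; variant reporting is restricted to the declared target windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import consensus as cns
from . import tagio, variants
from .simlib import ReferenceSet, revcomp
from .targetalign import Scoring, TargetAligner, project
from .variants import Observation

__all__ = ["PipelineConfig", "LocusResult", "SampleResult", "run_sample", "call_replicates"]

#: how far the alignment slice extends left of the primer 5' end and right
#: past it (the adapter-proximal fragment end of the longest fragments)
REGION_PAD_LEFT = 150
REGION_PAD_RIGHT = 760


@dataclass(frozen=True)
class PipelineConfig:
    tag: tagio.TagConfig = tagio.TagConfig()
    scoring: Scoring = Scoring()
    score_floor_frac: float = 0.4
    merge_size_ratio: int = 3
    min_reads_per_strand: int = 1
    plurality: float = 0.6
    edge_guard: int = variants.DEFAULT_EDGE_GUARD


class _ReadKey(NamedTuple):
    locus_id: str
    umi: str
    strand_tag: str


@dataclass
class LocusResult:
    locus_id: str
    contig: str
    region_start: int
    region_len: int
    n_read_pairs: int
    n_unaligned_pairs: int
    duplexes: list
    observations: list[Observation]
    variants: pd.DataFrame
    depth: np.ndarray  # per-position duplex depth over the region
    consensus_stats: dict


@dataclass
class SampleResult:
    sample_id: str
    variants: pd.DataFrame
    tag_report: tagio.StageReport
    loci: dict[str, LocusResult]

    def depth_at(self, contig: str, pos: int) -> int:
        for lr in self.loci.values():
            if lr.contig == contig and 0 <= pos - lr.region_start < lr.region_len:
                return int(lr.depth[pos - lr.region_start])
        return 0

    @property
    def stage_report(self) -> dict:
        rep = self.tag_report.as_dict()
        rep["unaligned_pairs"] = sum(l.n_unaligned_pairs for l in self.loci.values())
        rep["loci"] = {
            k: {"read_pairs": l.n_read_pairs, **l.consensus_stats}
            for k, l in self.loci.items()
        }
        return rep


def run_sample(
    ref: ReferenceSet,
    pairs: Iterable[tuple[str, str, str, str, str]],
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "sample",
) -> SampleResult:
    """Run the full per-sample workflow on a stream of read pairs."""
    primers = [(p.locus_id, p.sequence) for p in ref.spe_primers]
    tagged_stream, report = tagio.process_read_pairs(pairs, primers, config.tag)

    by_locus: dict[str, list] = {w.locus_id: [] for w in ref.target_windows}
    for t in tagged_stream:
        by_locus[t.locus_id].append(t)

    loci: dict[str, LocusResult] = {}
    all_tables = []
    for window in ref.target_windows:
        locus = window.locus_id
        primer = ref.primer(locus)
        contig_seq = ref.contigs[window.contig]
        region_start = max(0, primer.start - REGION_PAD_LEFT)
        region_end = min(len(contig_seq), primer.start + REGION_PAD_RIGHT)
        region = contig_seq[region_start:region_end]
        aligner = TargetAligner(
            region, config.scoring, config.score_floor_frac, region_start
        )
        proj_cache: dict[str, object] = {}

        def aligned_cols(insert: str):
            cols = proj_cache.get(insert)
            if cols is None and insert not in proj_cache:
                aln = aligner.align(insert)
                cols = None if aln is None else project(aln, insert)
                proj_cache[insert] = cols
            return cols

        records = []
        n_unaligned = 0
        reads = by_locus[locus]
        for t in reads:
            # read 1 sequences inward from the adapter-proximal fragment end,
            # i.e. it is the reverse complement of the forward amplicon
            c1 = aligned_cols(revcomp(t.insert_r1))
            c2 = aligned_cols(t.insert_r2)
            if c1 is None or c2 is None:
                n_unaligned += 1
                continue
            records.append((_ReadKey(locus, t.umi, t.strand_tag), c1, c2))
        del reads
        by_locus[locus] = []

        families = cns.group_families(records, config.merge_size_ratio)
        sscs = [
            s for s in (
                cns.build_ssc(f, plurality=config.plurality) for f in families
            ) if s is not None
        ]
        duplexes, _ = cns.pair_duplexes(sscs, config.min_reads_per_strand)
        stats = cns.consensus_report(families, sscs, duplexes)

        observations: list[Observation] = []
        for d in duplexes:
            observations.extend(
                variants.call_dcs_variants(
                    d, window.contig, contig_seq, region_start, window,
                    config.edge_guard,
                )
            )
        region_len = region_end - region_start
        table = variants.aggregate_counts(
            observations, duplexes, region_start, region_len, locus
        )
        depth = variants.duplex_depth(duplexes, region_len)
        loci[locus] = LocusResult(
            locus, window.contig, region_start, region_len,
            len(records), n_unaligned, duplexes, observations, table, depth, stats,
        )
        all_tables.append(table)

    merged = (
        pd.concat(all_tables, ignore_index=True)
        if all_tables else pd.DataFrame()
    )
    if len(merged):
        merged.insert(0, "sample_id", sample_id)
    return SampleResult(sample_id, merged, report, loci)


def call_replicates(
    results: Sequence[SampleResult],
    rules: tuple[tuple[int, int], ...] = variants.DEFAULT_RULES,
) -> pd.DataFrame:
    """Replicate-filter decisions across per-replicate sample results."""
    return variants.replicate_filter([r.variants for r in results], rules)
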