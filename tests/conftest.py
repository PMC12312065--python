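import numpy as np
import pytest

import duplexumi as d
from duplexumi import simlib


def zero_error_params(**kw) -> simlib.SimParams:
    base = dict(seq_error_rate=0.0, single_strand_rate=0.0,
                end_repair_rate=0.0, pcr_jackpot_rate=0.0)
    base.update(kw)
    return simlib.SimParams(**base)


def one_locus(ref: simlib.ReferenceSet, locus_id: str) -> simlib.ReferenceSet:
    w = ref.window(locus_id)
    return simlib.ReferenceSet(
        {w.contig: ref.contigs[w.contig]}, [w], [ref.primer(locus_id)]
    )


@pytest.fixture(scope="session")
def study():
    """Canonical four-locus study design (reference, lines, haplotypes,
    per-level mixtures)."""
    return d.study_design(11)


@pytest.fixture(scope="session")
def crt5(study):
    """One-locus slice of the study: the 5-bp-deletion line only."""
    ref, lines, haps, _ = study
    ref1 = one_locus(ref, "locus02")
    lines1 = [l for l in lines if l.line_id == "CrtD5"]
    haps1 = [h for h in haps if h.line_id == "CrtD5"]
    return ref1, lines1, haps1
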