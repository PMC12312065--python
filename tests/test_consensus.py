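"""Consensus logic: UMI grouping, plurality SSC, N-masked duplex merge,
and the duplex error-scrubbing guarantees audited against truth ledgers."""

import numpy as np
import pytest

from duplexumi import consensus as cns
from duplexumi import pipeline, simlib, tagio
from duplexumi.consensus import UmiFamily, build_dcs, build_ssc, group_families, pair_duplexes
from duplexumi.simlib import design_mixture, generate_read_pairs, revcomp, simulate_molecules
from duplexumi.tagio import TaggedRead
from duplexumi.targetalign import AlignedColumns
from conftest import zero_error_params


def cols(start: int, seq: str, insertions=()) -> AlignedColumns:
    return AlignedColumns(start, start + len(seq), seq.encode(), tuple(insertions))


DUMMY = cols(500, "ACGTACGTAC")  # far-away mate so it never interferes


def fam(reads, locus="L", umi="A" * 12, tag="TT") -> UmiFamily:
    return UmiFamily(locus, umi, tag, [(c, DUMMY) for c in reads])


def tr(umi, tag, locus="L"):
    return TaggedRead("r", umi, tag, locus, "", "", "", "")


def test_exact_grouping():
    recs = [(tr("A" * 12, "TT"), cols(0, "ACGT"), DUMMY) for _ in range(10)]
    fams = group_families(recs)
    assert len(fams) == 1
    assert fams[0].read_count == 10


def test_directional_umi_merge_absorbs_small_neighbour():
    big_umi = "A" * 12
    small_umi = "A" * 11 + "C"
    recs = [(tr(big_umi, "TT"), cols(0, "ACGT"), DUMMY) for _ in range(30)]
    recs += [(tr(small_umi, "TT"), cols(0, "ACGT"), DUMMY)]
    fams = group_families(recs)
    assert len(fams) == 1
    assert fams[0].umi == big_umi and fams[0].read_count == 31

    # equal-size neighbours are NOT merged (3x ratio required)
    recs = [(tr(big_umi, "TT"), cols(0, "ACGT"), DUMMY) for _ in range(5)]
    recs += [(tr(small_umi, "TT"), cols(0, "ACGT"), DUMMY) for _ in range(5)]
    assert len(group_families(recs)) == 2
    # opposite strand tags never merge
    recs = [(tr(big_umi, "TT"), cols(0, "ACGT"), DUMMY) for _ in range(30)]
    recs += [(tr(small_umi, "GG"), cols(0, "ACGT"), DUMMY)]
    assert len(group_families(recs)) == 2


def test_family_count_matches_captured_strands(crt5):
    """In a zero-sequencing-error simulation the family count equals the
    number of captured molecule strands from the truth table."""
    ref1, lines1, haps1 = crt5
    params = zero_error_params()
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 400, seed=51)
    pairs = list(generate_read_pairs(mols, params, 52))
    captured = {name.rsplit(":", 1)[0] for name, *_ in pairs}  # (mol, strand)
    primers = [(p.locus_id, p.sequence) for p in ref1.spe_primers]
    tagged, _ = tagio.process_read_pairs(pairs, primers)
    res = pipeline.run_sample(ref1, pairs)
    stats = res.loci["locus02"].consensus_stats
    # short-insert molecules lose *all* reads at QC, so compare against
    # strands with at least one QC-surviving read
    surviving = {t.read_id.rsplit(":", 1)[0] for t in tagged}
    assert stats["n_families"] == len(surviving)
    assert len(surviving) <= len(captured)


def test_ssc_plurality_rules():
    # unanimity
    s = build_ssc(fam([cols(0, "ACGT")] * 5))
    assert s.bases.tobytes()[:4] == b"ACGT"
    assert s.depth.tolist()[:4] == [5] * 4
    # exactly 0.6 keeps the base
    s = build_ssc(fam([cols(0, "A")] * 3 + [cols(0, "G")] * 2))
    assert chr(s.bases[0]) == "A"
    # 0.5/0.5 masks with N
    s = build_ssc(fam([cols(0, "A")] * 2 + [cols(0, "G")] * 2))
    assert chr(s.bases[0]) == "N"
    # below min_reads -> None
    assert build_ssc(fam([cols(0, "ACGT")]), min_reads=2) is None


def test_ssc_matches_exhaustive_column_majority():
    """For small families, the SSC equals a per-column exhaustive majority
    computation (gap treated as a base; ties and sub-0.6 fractions -> N)."""
    rng = np.random.default_rng(61)
    alphabet = "ACG-"
    for _ in range(150):
        n_reads = int(rng.integers(1, 7))
        n_cols = int(rng.integers(1, 11))
        start = int(rng.integers(0, 5))
        reads = ["".join(np.array(list(alphabet))[rng.integers(0, 4, n_cols)])
                 for _ in range(n_reads)]
        s = build_ssc(fam([cols(start, r) for r in reads]))
        for j in range(n_cols):
            column = [r[j] for r in reads]
            counts = {b: column.count(b) for b in set(column)}
            best = max(sorted(counts), key=lambda b: counts[b])
            expect = best if counts[best] / len(column) >= 0.6 - 1e-12 else "N"
            got = chr(s.bases[start + j - s.start])
            assert got == expect, (reads, j)


def test_ssc_insertion_slot_competes_with_absent():
    ins = (((1, 1), "T"),)
    with_ins = cols(0, "ACGT", ins)
    without = cols(0, "ACGT")
    # 3/4 reads report the insertion -> kept
    s = build_ssc(fam([with_ins] * 3 + [without]))
    assert s.insertions == {(1, 1): "T"}
    # 1/4 reports it -> absent wins, no slot
    s = build_ssc(fam([with_ins] + [without] * 3))
    assert s.insertions == {}
    # 50/50 -> neither reaches 0.6 -> slot masked as N
    s = build_ssc(fam([with_ins] * 2 + [without] * 2))
    assert s.insertions == {(1, 1): "N"}


def _ssc(seq, tag, start=0, umi="A" * 12, insertions=None, reads=3):
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    return cns.SingleStrandConsensus(
        "L", umi, tag, start, start + len(seq), arr,
        np.full(len(seq), reads, dtype=np.int32), insertions or {}, reads,
    )


def test_dcs_identity_and_masking():
    d = build_dcs(_ssc("ACGT", "TT"), _ssc("ACGT", "GG"))
    assert d.bases.tobytes() == b"ACGT"
    d = build_dcs(_ssc("ACGT", "TT"), _ssc("ACTT", "GG"))
    assert d.bases.tobytes() == b"ACNT"
    # N on one strand is discordance
    d = build_dcs(_ssc("ACGT", "TT"), _ssc("ACNT", "GG"))
    assert d.bases.tobytes() == b"ACNT"


def test_dcs_symmetric_and_span_intersection():
    rng = np.random.default_rng(71)
    for _ in range(100):
        la, lb = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        sa, sb = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        a = _ssc("".join(np.array(list("ACN"))[rng.integers(0, 3, la)]), "TT", sa)
        b = _ssc("".join(np.array(list("ACN"))[rng.integers(0, 3, lb)]), "GG", sb)
        d1 = build_dcs(a, b)
        d2 = build_dcs(b, a)
        if d1 is None:
            assert d2 is None
            continue
        assert (d1.start, d1.end) == (max(sa, sb), min(sa + la, sb + lb))
        assert d1.bases.tobytes() == d2.bases.tobytes()
        assert d1.insertions == d2.insertions


def test_dcs_rejects_same_tag():
    with pytest.raises(ValueError, match="opposite strand tags"):
        build_dcs(_ssc("ACGT", "TT"), _ssc("ACGT", "TT"))


def test_dcs_one_strand_insertion_is_masked():
    a = _ssc("ACGTACGT", "TT", insertions={(2, 1): "T"})
    b = _ssc("ACGTACGT", "GG")
    d = build_dcs(a, b)
    assert d.insertions == {}
    both = build_dcs(a, _ssc("ACGTACGT", "GG", insertions={(2, 1): "T"}))
    assert both.insertions == {(2, 1): "T"}


def test_min_reads_per_strand_monotone(crt5):
    """Raising the per-strand read minimum never increases duplex count."""
    ref1, lines1, haps1 = crt5
    params = simlib.SimParams()
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 300, seed=81)
    pairs = list(generate_read_pairs(mols, params, 82))
    primers = [(p.locus_id, p.sequence) for p in ref1.spe_primers]
    tagged, _ = tagio.process_read_pairs(pairs, primers)
    res = pipeline.run_sample(ref1, pairs)
    duplexes = res.loci["locus02"].duplexes
    sscs = []  # rebuild SSCs from scratch for the monotonicity sweep
    from duplexumi.targetalign import TargetAligner, project
    counts = []
    for k in (1, 2, 3, 4):
        cfg = pipeline.PipelineConfig(min_reads_per_strand=k)
        r = pipeline.run_sample(ref1, pairs, cfg)
        counts.append(len(r.loci["locus02"].duplexes))
    assert counts[0] == len(duplexes)
    assert counts == sorted(counts, reverse=True)


def test_duplex_scrubs_single_strand_but_keeps_end_repair_damage(crt5):
    """Against the truth ledger: single-strand damage never survives into a
    duplex base; end-repair damage always does when both strands are
    captured and the position is duplex-covered."""
    ref1, lines1, haps1 = crt5
    params = zero_error_params(single_strand_rate=0.35, end_repair_rate=0.25,
                               strand_capture_prob=1.0)
    mix = simlib.MixtureDesign(0.0, [])  # pure wild-type background
    mols = simulate_molecules(ref1, mix, haps1, params, 500, seed=91)
    pairs = generate_read_pairs(mols, params, 92)
    res = pipeline.run_sample(ref1, pairs)
    lr = res.loci["locus02"]
    by_umi = {d.umi: d for d in lr.duplexes}
    checked_ss = checked_er = 0
    for m in mols:
        d = by_umi.get(m.umi)
        if d is None:
            continue
        for a in m.artefacts:
            region_pos = m.frag_start + a.pos - lr.region_start
            col = region_pos - d.start
            if not (0 <= col < d.end - d.start) or d.bases[col] == 0:
                continue
            alt = ord(a.change[-1])
            if a.kind == "single_strand":
                assert d.bases[col] != alt
                checked_ss += 1
            elif a.kind == "end_repair":
                assert d.bases[col] == alt
                checked_er += 1
    assert checked_ss > 30 and checked_er > 30
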