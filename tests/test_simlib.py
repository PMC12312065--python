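"""Simulator unit and property tests: reference construction, edits,
mixtures, molecule drawing, artefact ledgers and read emission."""

import numpy as np
import pytest

from duplexumi import simlib
from duplexumi.simlib import (
    EditSpec,
    Line,
    MixtureComponent,
    MixtureDesign,
    SimParams,
    apply_edits,
    build_reference,
    design_mixture,
    generate_read_pairs,
    revcomp,
    simulate_molecules,
)
from conftest import zero_error_params


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def test_build_reference_structure_and_invariants():
    ref = build_reference(seed=1, n_loci=4, window_len=800)
    assert len(ref.target_windows) == 4
    assert len(ref.spe_primers) == 4
    ref.validate()  # windows inside contigs, primers unique and in-window
    for w in ref.target_windows:
        assert w.end - w.start == 800


def test_build_reference_deterministic():
    a = build_reference(seed=7, n_loci=3, window_len=300)
    b = build_reference(seed=7, n_loci=3, window_len=300)
    assert a.contigs == b.contigs
    assert a.spe_primers == b.spe_primers
    c = build_reference(seed=8, n_loci=3, window_len=300)
    assert c.contigs != a.contigs


def test_build_reference_rejects_tiny_windows():
    with pytest.raises(ValueError, match="too small"):
        build_reference(seed=1, n_loci=4, window_len=100)


# ---------------------------------------------------------------------------
# edits / haplotypes
# ---------------------------------------------------------------------------

def test_apply_edits_lengths_and_identity(study):
    ref, lines, haps, _ = study
    by_id = {h.haplotype_id: h for h in haps}
    # 5-bp deletion line: haplotype shorter by 5
    w2 = ref.window("locus02")
    assert len(by_id["CrtD5/a"].contigs[w2.contig]) == len(ref.contigs[w2.contig]) - 5
    # 1-bp insertion line: haplotype longer by 1
    w3 = ref.window("locus03")
    assert len(by_id["PsyIns1/a"].contigs[w3.contig]) == len(ref.contigs[w3.contig]) + 1
    # heterozygous line yields one haplotype per allele
    assert {"PsyHet/a", "PsyHet/b"} <= set(by_id)
    # no edits -> identical to reference
    [h] = apply_edits(ref, [Line("null", "homozygous", ())])
    assert h.contigs == ref.contigs


def test_apply_edits_rejects_ref_mismatch(study):
    ref, *_ = study
    w = ref.window("locus01")
    actual = ref.contigs[w.contig][w.start + 50]
    wrong = "A" if actual != "A" else "C"
    bad = EditSpec("x", "locus01", "deletion", w.contig, w.start + 50,
                   w.start + 51, wrong, "", "homozygous")
    with pytest.raises(ValueError, match="expected"):
        apply_edits(ref, [Line("x", "homozygous", (bad,))])


def test_design_mixture_zygosity_rule(study):
    _, lines, _, _ = study
    [mix] = design_mixture(lines, [0.009])
    comp = {c.line_id: c for c in mix.components}
    assert comp["CrtD1"].mass_fraction == comp["CrtD1"].per_allele_copy_ratio == 0.009
    # heterozygous line: double the mass for the same per-allele ratio
    assert comp["PsyHet"].per_allele_copy_ratio == 0.009
    assert comp["PsyHet"].mass_fraction == pytest.approx(0.018)
    [mix_low] = design_mixture(lines, [0.001])
    assert {c.line_id: c.mass_fraction for c in mix_low.components}["PsyHet"] == pytest.approx(0.002)


def test_design_mixture_rejects_bad_levels(study):
    _, lines, _, _ = study
    with pytest.raises(ValueError):
        design_mixture(lines, [0.0])
    with pytest.raises(ValueError):
        design_mixture(lines, [1.0])
    with pytest.raises(ValueError, match="> 1"):
        design_mixture(lines, [0.3])  # masses 0.3*3 + 0.6 > 1


# ---------------------------------------------------------------------------
# molecule simulation
# ---------------------------------------------------------------------------

def test_mutant_fraction_recovery(crt5):
    ref1, lines1, haps1 = crt5
    p = 0.01
    n = 12000
    mix = design_mixture(lines1, [p])[0]
    mols = simulate_molecules(ref1, mix, haps1, SimParams(), n, seed=3)
    k = sum(m.haplotype_id != "background" for m in mols)
    se = np.sqrt(n * p * (1 - p))
    assert abs(k - n * p) <= 3 * se


def test_zero_artefact_rates_give_clean_duplexes(crt5):
    ref1, lines1, haps1 = crt5
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, zero_error_params(), 500, seed=5)
    for m in mols:
        assert m.artefacts == ()
        assert revcomp(m.bottom_strand) == m.top_strand


def test_end_repair_artefacts_sit_near_adapter_end(crt5):
    ref1, lines1, haps1 = crt5
    params = zero_error_params(end_repair_rate=1.0)
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 1000, seed=6)
    n_with = 0
    for m in mols:
        ers = [a for a in m.artefacts if a.kind == "end_repair"]
        if not ers:
            continue
        n_with += 1
        frag_len = m.frag_end - m.frag_start
        for a in ers:
            assert frag_len - params.end_repair_window <= a.pos < frag_len
            assert a.strand == "both"
            assert a.change in ("G>T", "C>T")
    assert n_with == len(mols)  # a G/C always exists within 30 nt


def test_artefact_class_strand_separation(crt5):
    """single_strand entries appear on exactly one strand; end_repair on
    both -- asserted directly on the strand sequences."""
    ref1, lines1, haps1 = crt5
    params = zero_error_params(single_strand_rate=0.5, end_repair_rate=0.5)
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 400, seed=9)
    seen_ss = seen_er = 0
    for m in mols:
        bottom_ref = revcomp(m.bottom_strand)  # back to reference orientation
        diff = {i for i, (a, b) in enumerate(zip(m.top_strand, bottom_ref)) if a != b}
        ss_pos = {a.pos for a in m.artefacts if a.kind == "single_strand"}
        er_pos = {a.pos for a in m.artefacts if a.kind == "end_repair"}
        assert diff == ss_pos  # one-strand damage, and nothing else, differs
        seen_ss += len(ss_pos)
        for a in m.artefacts:
            if a.kind == "end_repair":
                seen_er += 1
                alt = a.change[-1]
                assert m.top_strand[a.pos] == alt and bottom_ref[a.pos] == alt
    assert seen_ss > 50 and seen_er > 50


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def test_read_structure_single_molecule(crt5):
    ref1, lines1, haps1 = crt5
    params = zero_error_params(reads_per_strand_poisson_mean=0.0,
                               strand_capture_prob=1.0)
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 1, seed=2)
    pairs = list(generate_read_pairs(mols, params, seed=4))
    assert len(pairs) == 2  # one read pair per strand
    tags = sorted(p[1][12:14] for p in pairs)
    assert tags == ["GG", "TT"]
    m = mols[0]
    primer = ref1.spe_primers[0].sequence
    for name, s1, q1, s2, q2 in pairs:
        assert s1[:12] == m.umi
        assert s2.startswith(primer)
        assert len(q1) == len(s1) and len(q2) == len(s2)


def test_no_bottom_reads_without_strand_capture(crt5):
    ref1, lines1, haps1 = crt5
    params = zero_error_params(strand_capture_prob=0.0)
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 200, seed=2)
    tags = {s1[12:14] for _, s1, _, _, _ in generate_read_pairs(mols, params, 3)}
    assert tags == {"TT"}


def test_mean_reads_per_molecule(crt5):
    """With 5 reads per strand and certain capture of both strands, a
    molecule yields ~10 read pairs on average (law of large numbers)."""
    ref1, lines1, haps1 = crt5
    params = zero_error_params(reads_per_strand_poisson_mean=4.0,
                               strand_capture_prob=1.0)
    mix = design_mixture(lines1, [0.01])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 1000, seed=12)
    n_pairs = sum(1 for _ in generate_read_pairs(mols, params, 13))
    assert abs(n_pairs / len(mols) - 10.0) < 0.05 * 10.0


def test_emission_deterministic(tmp_path, crt5):
    ref1, lines1, haps1 = crt5
    params = SimParams()
    mix = design_mixture(lines1, [0.05])[0]
    mols = simulate_molecules(ref1, mix, haps1, params, 50, seed=21)
    mols2 = simulate_molecules(ref1, mix, haps1, params, 50, seed=21)
    assert mols == mols2
    a = list(generate_read_pairs(mols, params, 22))
    b = list(generate_read_pairs(mols2, params, 22))
    assert a == b
    simlib.emit_fastq(mols, params, 22, tmp_path / "a.R1.fastq", tmp_path / "a.R2.fastq")
    simlib.emit_fastq(mols, params, 22, tmp_path / "b.R1.fastq", tmp_path / "b.R2.fastq")
    assert (tmp_path / "a.R1.fastq").read_bytes() == (tmp_path / "b.R1.fastq").read_bytes()
    assert (tmp_path / "a.R2.fastq").read_bytes() == (tmp_path / "b.R2.fastq").read_bytes()


def test_reference_files_round_trip(tmp_path, study):
    ref, *_ = study
    paths = simlib.write_reference_files(ref, tmp_path)
    back = simlib.load_reference_files(paths["fasta"], paths["bed"], paths["primers"])
    assert back.contigs == ref.contigs
    assert back.target_windows == ref.target_windows
    assert back.spe_primers == ref.spe_primers
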