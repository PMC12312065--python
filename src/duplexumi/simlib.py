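"""Synthetic duplex-UMI library simulator.

Generates random references with locus-specific primer-extension (SPE) target
windows, applies programmed edits (SNVs, short InDels) to build mutant
haplotypes, designs wild-type/mutant DNA mixtures at given copy-number ratios,
draws duplex molecules (sheared fragments carrying a 12-nt UMI shared by both
strands), injects the three library artefact classes

* ``single_strand`` -- base damage present on one strand only (e.g. from
  sonication); removed by duplex consensus,
* ``end_repair``    -- damage copied onto both strands during end repair,
  concentrated near the adapter-proximal fragment end (G>T / C>T); survives
  duplex consensus,
* ``pcr_jackpot``   -- an early-cycle PCR error shared by a subset of one
  strand family's reads,

and emits paired-end reads with the duplex-adapter read structure: read 1
starts with the UMI followed by a 2-nt strand tag (TT = top strand family,
GG = bottom), read 2 starts at the SPE primer and reads inward.

Every stochastic entry point takes an explicit integer seed and is
deterministic for fixed inputs; a per-molecule truth ledger (haplotype of
origin plus every injected artefact) is kept so downstream error-suppression
claims can be audited against ground truth.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSet",
    "TargetWindow",
    "SpePrimer",
    "EditSpec",
    "Line",
    "Haplotype",
    "MixtureComponent",
    "MixtureDesign",
    "SimParams",
    "Artefact",
    "DuplexMolecule",
    "build_reference",
    "apply_edits",
    "design_mixture",
    "simulate_molecules",
    "generate_read_pairs",
    "emit_fastq",
    "truth_table",
    "study_lines",
    "study_design",
    "revcomp",
]

NUCS = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

PRIMER_LEN = 24
#: offset of the primer 5' end from the window start
PRIMER_OFFSET = 8
#: flank of random sequence on each side of a target window so that sheared
#: fragments (up to ``fragment_len_max``) always fit inside the contig
CONTIG_FLANK = 760
MIN_WINDOW_LEN = 200


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase ACGTN)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetWindow:
    locus_id: str
    contig: str
    start: int  # 0-based half-open
    end: int


@dataclass(frozen=True)
class SpePrimer:
    locus_id: str
    name: str
    sequence: str
    strand: str  # '+' : primer extends toward increasing coordinates
    start: int   # 0-based position of the primer 5' end on the contig

    @property
    def end(self) -> int:
        """3'-anchor position (half-open end) from which extension proceeds."""
        return self.start + len(self.sequence)


@dataclass
class ReferenceSet:
    """Reference contigs plus target windows and SPE primer definitions."""

    contigs: dict[str, str]
    target_windows: list[TargetWindow]
    spe_primers: list[SpePrimer]

    def window(self, locus_id: str) -> TargetWindow:
        for w in self.target_windows:
            if w.locus_id == locus_id:
                return w
        raise KeyError(locus_id)

    def primer(self, locus_id: str) -> SpePrimer:
        for p in self.spe_primers:
            if p.locus_id == locus_id:
                return p
        raise KeyError(locus_id)

    def validate(self) -> None:
        for w in self.target_windows:
            if not (0 <= w.start < w.end <= len(self.contigs[w.contig])):
                raise ValueError(f"window {w.locus_id} outside its contig")
        joined = " ".join(self.contigs.values())
        for p in self.spe_primers:
            if joined.count(p.sequence) != 1:
                raise ValueError(f"primer {p.name} does not occur exactly once")
            w = self.window(p.locus_id)
            if not (w.start <= p.start and p.end <= w.end):
                raise ValueError(f"primer {p.name} not inside window {p.locus_id}")


@dataclass(frozen=True)
class EditSpec:
    """One programmed mutation on one allele of an edited line.

    Coordinates are 0-based half-open on the reference contig.  Insertions
    have ``start == end`` and an empty ``ref_allele``; deletions have an
    empty ``alt_allele`` and ``end - start == len(ref_allele)``.
    """

    line_id: str
    locus_id: str
    kind: str  # SNV | insertion | deletion
    contig: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # homozygous | heterozygous

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.kind == "deletion":
            if self.alt_allele or self.end - self.start != len(self.ref_allele) or not self.ref_allele:
                raise ValueError("deletion must span its ref_allele and have empty alt")
        elif self.kind == "insertion":
            if self.ref_allele or self.start != self.end or not self.alt_allele:
                raise ValueError("insertion must have start == end and empty ref")
        else:  # SNV
            if not (len(self.ref_allele) == len(self.alt_allele) == self.end - self.start == 1):
                raise ValueError("SNV must be a single-base substitution")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNV alleles must differ")


@dataclass(frozen=True)
class Line:
    """An edited line: a set of edits and a zygosity.

    A heterozygous line carries one haplotype per edit (the two alleles carry
    different mutations at the same site); a homozygous line carries a single
    edited haplotype applied to both alleles.
    """

    line_id: str
    zygosity: str
    edits: tuple[EditSpec, ...]


@dataclass(frozen=True)
class Haplotype:
    line_id: str
    allele_id: str
    contigs: dict[str, str] = field(hash=False)
    edits: tuple[EditSpec, ...] = ()

    @property
    def haplotype_id(self) -> str:
        return f"{self.line_id}/{self.allele_id}"


@dataclass(frozen=True)
class MixtureComponent:
    line_id: str
    zygosity: str
    mass_fraction: float
    per_allele_copy_ratio: float


@dataclass
class MixtureDesign:
    """One mixture: edited lines spiked into a wild-type background.

    For homozygous diploid material the per-allele copy-number ratio equals
    the mass fraction; a heterozygous line must be mixed at double the mass
    to reach the same per-allele copy ratio.
    """

    level: float  # nominal per-allele copy ratio of each spiked line
    components: list[MixtureComponent]
    background_id: str = "wild_type"
    n_replicates: int = 3

    def validate(self) -> None:
        total = sum(c.mass_fraction for c in self.components)
        if total > 1.0 + 1e-12:
            raise ValueError(f"component mass fractions sum to {total:.4f} > 1")
        for c in self.components:
            if c.zygosity == "homozygous":
                if not math.isclose(c.per_allele_copy_ratio, c.mass_fraction):
                    raise ValueError("homozygous line: copy ratio must equal mass fraction")
            else:
                if not math.isclose(c.mass_fraction, 2.0 * c.per_allele_copy_ratio):
                    raise ValueError("heterozygous line: mass fraction must be 2x copy ratio")

    @property
    def background_fraction(self) -> float:
        return 1.0 - sum(c.mass_fraction for c in self.components)


@dataclass(frozen=True)
class SimParams:
    """Library simulation parameters.

    Defaults emulate a sonicated, size-selected library: ~550 bp fragments,
    ~10 reads per UMI (1 + Poisson(4.5) read pairs per captured strand, both
    strands of a molecule captured for 85 % of molecules), 2 x 150 reads at
    constant quality, and low per-molecule artefact rates.
    """

    fragment_len_mean: float = 550.0
    fragment_len_sd: float = 40.0
    fragment_len_min: int = 400
    fragment_len_max: int = 700
    reads_per_strand_poisson_mean: float = 4.5
    strand_capture_prob: float = 0.85
    seq_error_rate: float = 1e-3
    pcr_jackpot_rate: float = 5e-5  # per base-duplication opportunity (per fragment base)
    end_repair_rate: float = 3e-4  # per molecule
    end_repair_window: int = 30  # nt from the adapter-proximal fragment end
    single_strand_rate: float = 1e-3  # per molecule
    read_len: int = 150
    umi_len: int = 12
    quality_char: str = "?"  # Q30

    def __post_init__(self) -> None:
        for name in ("strand_capture_prob", "seq_error_rate", "pcr_jackpot_rate",
                     "end_repair_rate", "single_strand_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_len_min < PRIMER_LEN + 1:
            raise ValueError("fragments must be able to contain a primer site")


@dataclass(frozen=True)
class Artefact:
    pos: int  # fragment-relative position (reference orientation)
    change: str  # e.g. "G>T"
    kind: str  # single_strand | end_repair | pcr_jackpot
    strand: str  # top | bottom | both
    read_fraction: float = 1.0  # pcr_jackpot only: fraction of the family's reads hit


@dataclass(frozen=True)
class DuplexMolecule:
    """One original double-stranded fragment after damage injection.

    ``top_strand`` is stored in reference orientation; ``bottom_strand`` is
    the physical complementary strand (reverse-complement orientation).  The
    two are exact reverse complements except at ledger positions of class
    ``single_strand`` (``pcr_jackpot`` entries are applied at read emission,
    not on the strands).
    """

    molecule_id: int
    locus_id: str
    haplotype_id: str
    contig: str
    frag_start: int  # haplotype coordinates
    frag_end: int
    umi: str
    primer_offset: int  # offset of the primer 5' end within the fragment
    top_strand: str
    bottom_strand: str
    artefacts: tuple[Artefact, ...]

    @property
    def insert_len(self) -> int:
        """Length of the amplifiable insert (primer 5' end to fragment end)."""
        return (self.frag_end - self.frag_start) - self.primer_offset


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NUCS))[rng.integers(0, 4, size=n)])


def build_reference(seed: int, n_loci: int, window_len: int = 240) -> ReferenceSet:
    """Build a random reference with ``n_loci`` target windows.

    Each locus sits on its own contig; its window contains exactly one
    embedded forward SPE primer site (24 nt) near the window start, with
    enough flanking sequence on the contig for any simulated fragment.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if window_len < MIN_WINDOW_LEN:
        raise ValueError(
            f"window_len {window_len} too small to host a primer site and an "
            f"amplicon region (minimum {MIN_WINDOW_LEN})"
        )
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        contigs: dict[str, str] = {}
        windows: list[TargetWindow] = []
        primers: list[SpePrimer] = []
        contig_len = CONTIG_FLANK + window_len + CONTIG_FLANK
        for i in range(n_loci):
            locus = f"locus{i + 1:02d}"
            contig = f"ctg{i + 1:02d}"
            seq = _random_seq(rng, contig_len)
            w0 = CONTIG_FLANK
            contigs[contig] = seq
            windows.append(TargetWindow(locus, contig, w0, w0 + window_len))
            p0 = w0 + PRIMER_OFFSET
            primers.append(
                SpePrimer(locus, f"{locus}_spe_f", seq[p0:p0 + PRIMER_LEN], "+", p0)
            )
        ref = ReferenceSet(contigs, windows, primers)
        joined = " ".join(contigs.values())
        if all(joined.count(p.sequence) == 1 for p in primers):
            ref.validate()
            return ref
    raise RuntimeError("could not build a reference with unique primer sites")


# ---------------------------------------------------------------------------
# edits and haplotypes
# ---------------------------------------------------------------------------

def _apply_edit_set(contigs: dict[str, str], edits: Sequence[EditSpec]) -> dict[str, str]:
    out = dict(contigs)
    for e in sorted(edits, key=lambda e: e.start, reverse=True):
        seq = out[e.contig]
        if seq[e.start:e.end] != e.ref_allele:
            raise ValueError(
                f"edit {e.line_id}:{e.kind}@{e.start}: reference has "
                f"{seq[e.start:e.end]!r}, expected {e.ref_allele!r}"
            )
        out[e.contig] = seq[:e.start] + e.alt_allele + seq[e.end:]
    return out


def apply_edits(ref: ReferenceSet, lines: Sequence[Line]) -> list[Haplotype]:
    """Build edited haplotypes: one per homozygous line, one per edit of a
    heterozygous line (each allele carries a different mutation)."""
    haplotypes: list[Haplotype] = []
    for line in lines:
        if line.zygosity == "heterozygous":
            allele_sets: list[tuple[EditSpec, ...]] = [(e,) for e in line.edits]
        else:
            allele_sets = [tuple(line.edits)]
        for i, edits in enumerate(allele_sets):
            allele = chr(ord("a") + i)
            haplotypes.append(
                Haplotype(line.line_id, allele, _apply_edit_set(ref.contigs, edits), edits)
            )
    return haplotypes


def design_mixture(
    lines: Sequence[Line],
    levels: Sequence[float],
    background_id: str = "wild_type",
    n_replicates: int = 3,
) -> list[MixtureDesign]:
    """One mixture per level: every line spiked at that per-allele copy ratio.

    Homozygous lines are mixed at mass fraction == level; heterozygous lines
    at double the mass so each allele reaches the same copy ratio.
    """
    designs = []
    for level in levels:
        if not 0.0 < level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {level}")
        comps = []
        for line in lines:
            if line.zygosity == "homozygous":
                comps.append(MixtureComponent(line.line_id, line.zygosity, level, level))
            else:
                comps.append(MixtureComponent(line.line_id, line.zygosity, 2.0 * level, level))
        design = MixtureDesign(level, comps, background_id, n_replicates)
        design.validate()
        designs.append(design)
    return designs


# ---------------------------------------------------------------------------
# molecule simulation
# ---------------------------------------------------------------------------

def _substitute(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1:]


def simulate_molecules(
    ref: ReferenceSet,
    mixture: MixtureDesign,
    haplotypes: Sequence[Haplotype],
    params: SimParams,
    n_molecules_per_locus: int,
    seed: int,
) -> list[DuplexMolecule]:
    """Draw duplex molecules for every locus of the reference.

    Each molecule is drawn from an edited haplotype with probability equal to
    its per-allele copy ratio (wild-type background fills the remainder), gets
    a fragment of Gaussian length spanning the locus SPE primer site with a
    uniform breakpoint, an i.i.d. uniform 12-nt UMI shared by both strands,
    and artefacts injected per ``params`` and recorded in its ledger.
    """
    if n_molecules_per_locus < 1:
        raise ValueError("n_molecules_per_locus must be >= 1")
    mixture.validate()
    rng = np.random.default_rng(seed)
    hap_by_line: dict[str, list[Haplotype]] = {}
    for h in haplotypes:
        hap_by_line.setdefault(h.line_id, []).append(h)

    # sampling distribution over haplotypes (shared across loci: a line's
    # genome is wild type away from its own edits)
    choices: list[Haplotype | None] = [None]  # background
    probs = [mixture.background_fraction]
    for comp in mixture.components:
        haps = hap_by_line.get(comp.line_id)
        if not haps:
            raise ValueError(f"no haplotypes supplied for line {comp.line_id}")
        for h in haps:
            choices.append(h)
            probs.append(comp.per_allele_copy_ratio)
    probs_arr = np.asarray(probs, dtype=float)
    probs_arr = probs_arr / probs_arr.sum()

    molecules: list[DuplexMolecule] = []
    mol_id = 0
    nuc_arr = np.array(list(NUCS))
    for window in ref.target_windows:
        primer = ref.primer(window.locus_id)
        # primer anchor position within each haplotype (unique occurrence)
        anchors: dict[int, int] = {}
        for ci, h in enumerate(choices):
            seq = ref.contigs[window.contig] if h is None else h.contigs[window.contig]
            a = seq.find(primer.sequence)
            if a < 0 or seq.find(primer.sequence, a + 1) >= 0:
                raise ValueError(f"primer {primer.name} not unique in haplotype")
            anchors[ci] = a

        n = n_molecules_per_locus
        hap_idx = rng.choice(len(choices), size=n, p=probs_arr)
        lengths = np.clip(
            np.rint(rng.normal(params.fragment_len_mean, params.fragment_len_sd, size=n)),
            params.fragment_len_min,
            params.fragment_len_max,
        ).astype(int)
        # uniform breakpoint: the fragment contains the full primer site and
        # ends a uniform distance past the primer 5' end
        offsets = rng.integers(0, lengths - PRIMER_LEN + 1)
        umis = nuc_arr[rng.integers(0, 4, size=(n, params.umi_len))]
        u_ss = rng.random(n)
        u_er = rng.random(n)
        u_jp = rng.random(n)

        for k in range(n):
            ci = int(hap_idx[k])
            h = choices[ci]
            hap_seq = ref.contigs[window.contig] if h is None else h.contigs[window.contig]
            anchor = anchors[ci]
            L = int(lengths[k])
            frag_start = anchor - int(offsets[k])
            frag_end = frag_start + L
            frag = hap_seq[frag_start:frag_end]
            primer_offset = anchor - frag_start

            artefacts: list[Artefact] = []
            top_changes: dict[int, str] = {}
            bottom_changes: dict[int, str] = {}
            if u_ss[k] < params.single_strand_rate:
                pos = int(rng.integers(0, L))
                old = frag[pos]
                new = NUCS[(NUCS.index(old) + 1 + int(rng.integers(0, 3))) % 4]
                strand = "top" if rng.random() < 0.5 else "bottom"
                (top_changes if strand == "top" else bottom_changes)[pos] = new
                artefacts.append(Artefact(pos, f"{old}>{new}", "single_strand", strand))
            if u_er[k] < params.end_repair_rate:
                # oxidative G>T / deaminative C>T damage copied to both strands
                # during end repair, near the adapter-proximal (read-1) end
                lo = max(0, L - params.end_repair_window)
                cand = [p for p in range(lo, L) if frag[p] in "GC"]
                if cand:
                    pos = cand[int(rng.integers(0, len(cand)))]
                    old = frag[pos]
                    top_changes[pos] = "T"
                    bottom_changes[pos] = "T"
                    artefacts.append(Artefact(pos, f"{old}>T", "end_repair", "both"))
            if u_jp[k] < params.pcr_jackpot_rate * L:
                pos = int(rng.integers(0, L))
                old = frag[pos]
                new = NUCS[(NUCS.index(old) + 1 + int(rng.integers(0, 3))) % 4]
                strand = "top" if rng.random() < 0.5 else "bottom"
                frac = float(rng.uniform(0.1, 0.9))
                artefacts.append(Artefact(pos, f"{old}>{new}", "pcr_jackpot", strand, frac))

            top = frag
            for pos, base in top_changes.items():
                top = _substitute(top, pos, base)
            if bottom_changes:
                bot_ref = frag
                for pos, base in bottom_changes.items():
                    bot_ref = _substitute(bot_ref, pos, base)
                bottom = revcomp(bot_ref)
            else:
                bottom = revcomp(frag)

            molecules.append(
                DuplexMolecule(
                    molecule_id=mol_id,
                    locus_id=window.locus_id,
                    haplotype_id="background" if h is None else h.haplotype_id,
                    contig=window.contig,
                    frag_start=frag_start,
                    frag_end=frag_end,
                    umi="".join(umis[k]),
                    primer_offset=primer_offset,
                    top_strand=top,
                    bottom_strand=bottom,
                    artefacts=tuple(artefacts),
                )
            )
            mol_id += 1
    return molecules


def truth_table(molecules: Sequence[DuplexMolecule]) -> pd.DataFrame:
    """Per-molecule ground truth: origin haplotype and artefact ledger."""
    rows = []
    for m in molecules:
        rows.append(
            {
                "molecule_id": m.molecule_id,
                "locus_id": m.locus_id,
                "haplotype_id": m.haplotype_id,
                "contig": m.contig,
                "frag_start": m.frag_start,
                "frag_end": m.frag_end,
                "umi": m.umi,
                "artefacts": ";".join(
                    f"{a.kind}:{a.pos}:{a.change}:{a.strand}" for a in m.artefacts
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

class _ErrorInjector:
    """Exact i.i.d. per-base substitution errors, cheap on the clean path."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._p_clean: dict[int, float] = {}

    def inject(self, seq: str) -> str:
        rate = self.rate
        if rate <= 0.0:
            return seq
        n = len(seq)
        p_clean = self._p_clean.get(n)
        if p_clean is None:
            p_clean = (1.0 - rate) ** n
            self._p_clean[n] = p_clean
        u = self.rng.random()
        if u < p_clean:
            return seq
        # conditional inverse-CDF draw of the Binomial(n, rate) error count
        k = 0
        acc = p_clean
        pk = p_clean
        while acc < u and k < n:
            k += 1
            pk = pk * (n - k + 1) / k * rate / (1.0 - rate)
            acc += pk
        k = max(k, 1)
        pos = self.rng.choice(n, size=k, replace=False)
        out = list(seq)
        for p in pos:
            old = out[p]
            if old in NUCS:
                out[p] = NUCS[(NUCS.index(old) + 1 + int(self.rng.integers(0, 3))) % 4]
        return "".join(out)


def generate_read_pairs(
    molecules: Sequence[DuplexMolecule],
    params: SimParams,
    seed: int,
) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield ``(name, r1_seq, r1_qual, r2_seq, r2_qual)`` tuples.

    Read 1 = [12-nt UMI][2-nt strand tag][genomic sequence from the
    adapter-proximal fragment end, read inward]; read 2 = [SPE primer]
    [genomic sequence read inward].  The top strand family is always
    sequenced; the bottom strand only with ``strand_capture_prob``.  Each
    captured strand yields ``1 + Poisson(mean)`` read pairs.
    """
    if len(molecules) == 0:
        raise ValueError("no molecules to emit")
    rng = np.random.default_rng(seed)
    err = _ErrorInjector(params.seq_error_rate, rng)
    n = len(molecules)
    bottom_captured = rng.random(n) < params.strand_capture_prob
    n_top = 1 + rng.poisson(params.reads_per_strand_poisson_mean, size=n)
    n_bot = 1 + rng.poisson(params.reads_per_strand_poisson_mean, size=n)
    rl = params.read_len
    qchar = params.quality_char
    quals: dict[int, str] = {}

    def qual(m: int) -> str:
        q = quals.get(m)
        if q is None:
            q = qchar * m
            quals[m] = q
        return q

    for idx, mol in enumerate(molecules):
        strands: list[tuple[str, str, int]] = [("TT", "top", int(n_top[idx]))]
        if bottom_captured[idx]:
            strands.append(("GG", "bottom", int(n_bot[idx])))
        for tag, strand_name, n_reads in strands:
            if strand_name == "top":
                tpl = mol.top_strand
            else:
                tpl = revcomp(mol.bottom_strand)  # back to reference orientation
            jackpots = [
                a for a in mol.artefacts
                if a.kind == "pcr_jackpot" and a.strand == strand_name
            ]
            hit_sets: list[set[int]] = []
            for a in jackpots:
                n_hit = max(1, int(round(a.read_fraction * n_reads)))
                hit = rng.choice(n_reads, size=min(n_hit, n_reads), replace=False)
                hit_sets.append(set(int(x) for x in hit))
            base_r1, base_r2 = _mol_reads(mol, tpl, rl)
            for r in range(n_reads):
                r1, r2 = base_r1, base_r2
                for a, hits in zip(jackpots, hit_sets):
                    if r in hits:
                        tpl2 = _substitute(tpl, a.pos, a.change[-1])
                        r1, r2 = _mol_reads(mol, tpl2, rl)
                r1 = err.inject(r1)
                r2 = err.inject(r2)
                name = f"mol{mol.molecule_id}:{tag}:{r}"
                yield (name, mol.umi + tag + r1, qual(len(mol.umi) + 2 + len(r1)),
                       r2, qual(len(r2)))


def _mol_reads(mol: DuplexMolecule, tpl: str, read_len: int) -> tuple[str, str]:
    """Genomic portions of (read 1, read 2) for one template strand.

    ``tpl`` is the strand in reference orientation.  Read 2 starts at the SPE
    primer site and reads inward; read 1 reads in from the adapter-proximal
    fragment end (its first genomic base sits right after the strand tag).
    """
    amplicon = tpl[mol.primer_offset:]
    r2 = amplicon[:read_len]
    g1 = min(read_len - 14, len(amplicon))
    r1 = revcomp(amplicon[len(amplicon) - g1:])
    return r1, r2


def emit_fastq(
    molecules: Sequence[DuplexMolecule],
    params: SimParams,
    seed: int,
    r1_path: str | Path,
    r2_path: str | Path,
) -> int:
    """Write paired FASTQ files (gzipped if the suffix is .gz); returns the
    number of read pairs written.  Byte-identical for identical inputs."""
    def opener(path):
        path = Path(path)
        if path.suffix == ".gz":
            return gzip.open(path, "wt", compresslevel=4)
        return open(path, "w")

    n = 0
    with opener(r1_path) as f1, opener(r2_path) as f2:
        for name, s1, q1, s2, q2 in generate_read_pairs(molecules, params, seed):
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# reference / edit file interchange
# ---------------------------------------------------------------------------

def write_reference_files(ref: ReferenceSet, out_dir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, target-window BED (0-based half-open) and a
    primer TSV under ``out_dir``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "reference.fasta"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.contigs.items()],
        str(fasta), "fasta",
    )
    bed = out / "target_windows.bed"
    with open(bed, "w") as fh:
        for w in ref.target_windows:
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.locus_id}\n")
    primers = out / "primers.tsv"
    pd.DataFrame(
        [
            {"locus_id": p.locus_id, "name": p.name, "sequence": p.sequence,
             "strand": p.strand, "start": p.start}
            for p in ref.spe_primers
        ]
    ).to_csv(primers, sep="\t", index=False)
    return {"fasta": fasta, "bed": bed, "primers": primers}


def load_reference_files(
    fasta: str | Path, bed: str | Path, primers_tsv: str | Path
) -> ReferenceSet:
    """Load a reference set from FASTA + BED + primer TSV."""
    from Bio import SeqIO

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    windows = []
    with open(bed) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, start, end, locus = line.split("\t")[:4]
            windows.append(TargetWindow(locus.strip(), contig, int(start), int(end)))
    pdf = pd.read_csv(primers_tsv, sep="\t")
    primers = [
        SpePrimer(r.locus_id, r.name, r.sequence, r.strand, int(r.start))
        for r in pdf.itertuples(index=False)
    ]
    ref = ReferenceSet(contigs, windows, primers)
    ref.validate()
    return ref


def load_edits_tsv(path: str | Path) -> list[Line]:
    """Load edited lines from a TSV with columns line_id, locus_id, kind,
    contig, start, end, ref_allele, alt_allele, zygosity."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    lines: dict[str, list[EditSpec]] = {}
    zyg: dict[str, str] = {}
    for r in df.itertuples(index=False):
        e = EditSpec(r.line_id, r.locus_id, r.kind, r.contig, int(r.start),
                     int(r.end), r.ref_allele, r.alt_allele, r.zygosity)
        lines.setdefault(r.line_id, []).append(e)
        zyg[r.line_id] = r.zygosity
    return [Line(lid, zyg[lid], tuple(edits)) for lid, edits in lines.items()]


def write_edits_tsv(lines: Sequence[Line], path: str | Path) -> None:
    rows = [
        {"line_id": e.line_id, "locus_id": e.locus_id, "kind": e.kind,
         "contig": e.contig, "start": e.start, "end": e.end,
         "ref_allele": e.ref_allele, "alt_allele": e.alt_allele,
         "zygosity": e.zygosity}
        for line in lines for e in line.edits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# canonical study design: four edited tomato lines, four SPE loci
# ---------------------------------------------------------------------------

#: window-relative offset of the canonical edit site (40 nt past the primer
#: 3' end, well inside read-2 coverage)
EDIT_OFFSET = PRIMER_OFFSET + PRIMER_LEN + 40


def study_lines(ref: ReferenceSet) -> list[Line]:
    """The four edited lines of the tomato study design.

    locus01: CrtR-B2 line with a 1-bp deletion (-C), homozygous.
    locus02: CrtR-B2 line with a 5-bp deletion (-CAGTT), homozygous.
    locus03: Psy1 line with a 1-bp insertion (+A), homozygous, plus a
             heterozygous Psy1 line carrying a 1-bp deletion (-A) on one
             allele and a 1-bp insertion (+C) on the other at the same site.
    locus04: no edit (negative-control target region).

    The reference must come from :func:`study_design`, which plants the
    required reference bases at the canonical edit sites.
    """
    w1, w2, w3 = (ref.window(f"locus{i:02d}") for i in (1, 2, 3))
    e1 = w1.start + EDIT_OFFSET
    e2 = w2.start + EDIT_OFFSET
    e3 = w3.start + EDIT_OFFSET
    return [
        Line("CrtD1", "homozygous", (
            EditSpec("CrtD1", "locus01", "deletion", w1.contig, e1, e1 + 1, "C", "", "homozygous"),
        )),
        Line("CrtD5", "homozygous", (
            EditSpec("CrtD5", "locus02", "deletion", w2.contig, e2, e2 + 5, "CAGTT", "", "homozygous"),
        )),
        Line("PsyIns1", "homozygous", (
            EditSpec("PsyIns1", "locus03", "insertion", w3.contig, e3, e3, "", "A", "homozygous"),
        )),
        Line("PsyHet", "heterozygous", (
            EditSpec("PsyHet", "locus03", "deletion", w3.contig, e3, e3 + 1, "A", "", "heterozygous"),
            EditSpec("PsyHet", "locus03", "insertion", w3.contig, e3 + 1, e3 + 1, "", "C", "heterozygous"),
        )),
    ]


def study_design(
    seed: int,
    window_len: int = 240,
    levels: Sequence[float] = (0.10, 0.009, 0.005, 0.001),
    n_replicates: int = 3,
) -> tuple[ReferenceSet, list[Line], list[Haplotype], list[MixtureDesign]]:
    """Reference + lines + haplotypes + per-level mixtures for the canonical
    four-locus, five-mutation titration design (levels are per-allele copy
    ratios: 10 %, 0.9 %, 0.5 %, 0.1 %)."""
    ref = build_reference(seed, n_loci=4, window_len=window_len)
    # plant the bases the canonical edits require, with guard bases that pin
    # left-normalisation so truth and called variants share coordinates
    plants = {1: "ACA", 2: "GCAGTTA", 3: "GAT"}
    for i, planted in plants.items():
        w = ref.window(f"locus{i:02d}")
        e = w.start + EDIT_OFFSET - 1
        seq = ref.contigs[w.contig]
        ref.contigs[w.contig] = seq[:e] + planted + seq[e + len(planted):]
    # planting may have duplicated/broken a primer site in principle; recheck
    ref.validate()
    lines = study_lines(ref)
    haplotypes = apply_edits(ref, lines)
    mixtures = design_mixture(lines, levels, n_replicates=n_replicates)
    return ref, lines, haplotypes, mixtures
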