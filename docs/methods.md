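# Methods

## The problem and the measurement model

Genome-edited (NGT) organisms carry only a few altered nucleotides — an SNV
or a short InDel — so detecting and quantifying them in a mixed sample at
mass fractions down to 0.1 % is beyond the per-read error rate of standard
sequencing (~10⁻³) and beyond PCR fidelity. Duplex-UMI sequencing solves
this by tagging every original double-stranded DNA fragment with a random
12-nt unique molecular identifier (UMI) shared by both strands, plus a 2-nt
strand tag (TT on top-strand progeny, GG on bottom). Reads sharing
(locus, UMI, strand tag) are collapsed into a single-strand consensus (SSC),
which removes independent sequencing errors; the two opposite-strand SSCs of
one molecule are merged into a duplex consensus sequence (DCS), masking any
discordant column with N, which removes PCR errors present on one strand
only. The frequency of a mutation is then a *molecule count ratio*:

    f = (# DCS carrying the exact mutation) / (# DCS making a non-N call at the position)

Target enrichment uses a single locus-specific primer-extension (SPE)
oligonucleotide per target region, so no mutation-specific assay design is
needed: any variant in the window is observable.

## Pipeline

1. **tagio** — read 1 is split into [12-nt UMI][2-nt tag][genomic insert];
   read 2 must begin with an SPE primer (≤1 mismatch, anchored at position
   0). The strand tag must match TT/GG exactly: with a 2-nt tag, any
   mismatch tolerance would merge opposite strands, the one error duplex
   logic cannot absorb. UMIs containing N are rejected, not repaired.
   QC defaults: mean Phred ≥ 20, insert ≥ 30 nt. Every input pair lands in
   exactly one pass/reject counter.
2. **targetalign** — glocal alignment (global in the read, free end
   positioning in the reference) against a per-locus reference slice that
   extends ~150 nt left and ~760 nt right of the primer, so any fragment
   geometry fits. Scores: match +1, mismatch −2, gap open −4, gap extend −1,
   where a length-k gap costs `open + (k−1)·extend`. Reads scoring below
   0.4 × length are excluded with a counter. Two exact shortcuts (substring
   match; ungapped scan accepted only when `q·(match−mismatch) < −gap_open`,
   i.e. when no gapped alignment can beat it) and a banded DP around the
   best ungapped diagonal (margin 60 ≫ 2 × longest expected indel + 10,
   with an unbanded fallback whenever the banded optimum touches the band
   edge) keep the unbanded optimum as the contract.
3. **consensus** — exact grouping by (locus, UMI, tag), then a directional
   merge: a family is absorbed by a ≥3×-larger family at UMI Hamming
   distance 1. Without this, UMI sequencing errors inflate family counts by
   roughly UMI length × error rate. SSC columns keep the plurality base when
   its fraction is ≥ 0.6 (boundary inclusive), else N; insertion slots are
   treated identically, with "no insertion" competing as a base. The DCS
   keeps agreeing columns, masks disagreement (including one-sided N) with
   N, and intersects the two spans; an insertion present on one strand only
   is masked. `min_reads_per_strand` defaults to 1: a duplex needs both
   strands, but each may be a single read — duplex masking, not per-strand
   depth, is the error control.
4. **variants** — every non-N DCS column differing from the reference
   yields an observation; adjacent gap columns merge into one deletion;
   insertion slots yield insertions; InDels are left-normalized so "the same
   exact mutation" is identity of the normalized (contig, pos, ref, alt)
   tuple. The frequency denominator counts only DCSs making a non-N call at
   the position (an N supports neither allele). Calls are restricted to the
   declared target windows. The replicate filter accepts a variant seen with
   ≥ 2 duplex counts in all 3 replicates or ≥ 5 duplex counts in ≥ 2
   replicates; counts (4, 4, 0) are rejected. A PAM annotation flags NGG/CCN
   motifs within 3 nt of a variant.
5. **metrics** — CV % (sample SD, n−1), bias % against the nominal level,
   with acceptance flags CV ≤ 25 % (relaxed to < 50 % below the 0.2 %
   level) and |bias| ≤ 25 %; quasi-binomial regression of frequency on
   level, fitted on (successes, totals) pairs with a logit link (identity
   link behind a flag) and moment dispersion = Pearson χ²/df; Poisson
   regression with a fixed log-offset and likelihood-ratio χ² per factor
   (LRT rather than Wald, for invariance to parameterization); the
   distance-from-UMI artefact trend with 20-nt bins represented by their
   midpoints (1–20 → 10); deterministic uniform down-sampling of intact
   read pairs.

### Two calling guards that matter

* **Edge guard (8 columns).** An InDel that sits within a few bases of an
  alignment end is systematically misrepresented: for a trailing stub of
  ≤ 4 bases, the score-optimal alignment prefers mismatches over opening a
  5-bp gap, so molecules whose amplicon ends just past a deletion junction
  produce satellite SNVs at the junction. These satellites recur in every
  replicate (they are a property of the reference context, not noise) and
  can reach the replicate filter. The guard must therefore exceed the
  longest expected edit length; the default of 8 covers the 5-bp deletion
  with margin and is configurable. Observations within the guard of any
  coverage-run edge are discarded; coverage (depth) is unaffected.
* **Masked-flank deletions.** A DCS gap run abutting an N column is a
  truncated representation of a longer discordant event (the two strands
  placed the gap differently); calling it would produce shifted/shortened
  satellite deletions. Such runs are never called.

## The simulator and what it does (not) emulate

`simlib` draws molecules per locus: haplotype with probability equal to its
per-allele copy ratio (homozygous lines: mass fraction = copy ratio;
heterozygous lines: double mass for the same per-allele ratio, one
haplotype per allele), fragment length N(550, 40) clipped to [400, 700]
with a uniform breakpoint constrained to contain the primer site, i.i.d.
uniform UMIs, and three artefact classes recorded in a per-molecule truth
ledger:

* `single_strand` (10⁻³/molecule): a substitution on one strand only —
  must never survive the duplex merge;
* `end_repair` (3×10⁻⁴/molecule): G→T or C→T damage copied to both strands,
  placed within 30 nt of the adapter-proximal fragment end — survives the
  duplex merge by construction and is what the replicate filter must
  remove;
* `pcr_jackpot` (5×10⁻⁵ per fragment base): an early-cycle PCR error
  shared by a random subset of one strand family's reads.

Read emission: the top strand is always sequenced, the bottom with
probability 0.85; each captured strand yields 1 + Poisson(4.5) read pairs
(~10 reads per molecule, the observed reads-per-UMI regime); 2 × 150 reads
at constant Q30 with i.i.d. 10⁻³ substitution errors injected independently
of the written qualities. PCR is not simulated cycle-by-cycle — jackpot
errors are injected as shared-subset read changes, which is observationally
equivalent at consensus level. Not modelled: ligation efficiency, adapter
dimers, index hopping, instrument-specific quality/error profiles,
off-target priming, and the merging of the two amplifiable ends of one
fragment (each molecule has one amplifiable end). Passing tests therefore
demonstrate the consensus/filter logic under a faithful error taxonomy, not
robustness to instrument-specific systematics.

The canonical `study_design` builds four target windows (240 nt, primer
near the window start) and plants the reference context for five edits in
four lines: a 1-bp deletion (−C) and a 5-bp deletion (−CAGTT) in the two
CrtR-B2 windows (homozygous), a 1-bp insertion (+A) in the Psy1 window
(homozygous), and a heterozygous line with −A and +C on opposite alleles at
the same Psy1 site; the fourth window carries no edit. Guard bases pin
left-normalisation so truth and calls share coordinates.

## Problem sizes and numerical choices

The acceptance script simulates 3 replicate libraries at per-allele levels
10 %, 0.9 %, 0.5 % and 0.1 % with 11,000 molecules per locus per replicate,
chosen to yield ≈ 8,600 duplex consensus molecules covering each edit site
— the high-input (450 ng) depth regime. That is ~5×10⁵ molecules and
~5×10⁶ read pairs overall. The test suite runs the same regime restricted
to one locus, plus smaller seeded simulations for the statistical
properties (frequency recovery at 0.9 % over 50 seeds; the Poisson CV law
at 0.1 %, where CV ≈ 100/√(p·D) for duplex depth D, checked as a pooled CV
over 50 runs with a reduced reads-per-strand mean of 1.0, which changes
per-read redundancy but not the molecule-counting statistics being tested).

Tie-breaks and degenerate inputs: alignment ties prefer the smallest window
end position and diagonal > deletion > insertion during traceback (a total,
deterministic rule); SSC plurality at exactly 0.6 keeps the base; insertion
ties go to "no insertion"; the quasi-binomial fit requires ≥ 2 distinct
levels; Poisson fits flag (rather than silently accept) factor levels whose
counts are all zero; every stochastic entry point takes an explicit seed
and identical inputs give byte-identical outputs.

## Known limitations

* Frequency denominators vary per position with fragment-geometry coverage;
  near the far end of a window the duplex depth is lower than at the edit
  sites close to the primer.
* The directional UMI merge can absorb a genuine small family into an
  unrelated ≥3×-larger family whose UMI happens to lie at Hamming distance
  1 (~3 % of families at 10⁴ molecules with 12-nt UMIs); this is the usual
  cost of UMI error correction and slightly dampens mutant counts.
* Molecules sequenced on one strand only contribute to SSC statistics but
  never to calls; quantification is conditional on duplex capture (85 %
  by default).
* No germline/background SNP subtraction beyond the replicate filter, no
  structural variants, and no attribution of a detected mutation to an
  editing vs natural origin (the PAM flag is an annotation, not a claim).
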