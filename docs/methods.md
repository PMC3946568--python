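# Methods

This note records the models, conventions and numerical choices behind
`earlyburst`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and evidence units

All public coordinates are 1-based inclusive, matching GFF3 and the way
gene coordinates are reported for viral genomes. Reads carry no strand
information (poly(A)+ libraries here are unstranded): the unit of evidence
everywhere is the *read species*, the set of identical reads irrespective
of strand, canonicalized as min(seq, revcomp(seq)). Species retain
per-timepoint multiplicities, so pooled and per-timepoint counts are both
derivable; validation thresholds ("two independent reads" for cleavage
sites, "five read species" for junctions) count distinct species, never
duplicates.

Positions around a cleavage site use −1 for the last templated base and +1
for the first base past it; there is no position 0. Promoter windows put
the A of the ATG at +1.

## Read mapping

Full-length alignment allows at most 2 mismatches and requires a unique
locus across genome(s) plus the junction contig library; "unique" means
exactly one locus within the mismatch budget (strictest reading). The one
sanctioned exception is a species hitting exactly the two registered
copies of an inverted terminal repeat: both alignments are kept at weight
0.5, so each copy receives half the reads and total weight is conserved.
The aligner is a pigeonhole seed-and-verify method (a <=2-mismatch hit on a
50-mer leaves one of three contiguous segments exact) and is
property-tested equal to a brute-force scan of every position and
orientation; it is exact, not heuristic.

Split-read search enumerates diagonal pairs from exact 8-mer matches and
scores every split point with both segments >= 8 nt and total mismatches
<= 2, with the intron required to be shorter than 2000 bp. Ties at equal
mismatch count prefer a split whose implied intron ends in a canonical
splice dinucleotide pair (either strand orientation), then the longest
first segment, then the leftmost position. The motif preference matters:
whenever the genome repeats around the seam the intron coordinate is
genuinely ambiguous, and without it the coordinate drifts by the length of
the repeat. Junction contigs take flank = read length − 1 on each side of
the seam; counted junction alignments must straddle the seam by at least
one base on each side (discovery itself requires 8).

## Expression: MRPN and depth scaling

Coverage accumulates alignment weight x species multiplicity over
alignment blocks only (junction reads contribute nothing across the
excised intron), strandlessly. MRPN is the exact median of the per-base
coverage over the annotated ORF span; genes are quantified over their full
span with no masking of overlaps — the median is the robustness mechanism,
and tests assert it is invariant when any minority (< half) of positions
is inflated arbitrarily.

Depth scaling divides by s_t = total mapped reads at t / total at T0
(host + virus pooled). Division (rather than multiplication) is the only
direction under which doubling a library's depth halves nothing — i.e.
normalized values stay comparable at T0 depth; s_T0 = 1 identically.

Temporal clustering uses Lloyd's K-means (Euclidean, k = 6, best of 100
seeded random restarts) on profiles over T7..T60 scaled to unit maximum.
Unit-max scaling is a deliberate choice: the clusters of interest are
temporal *shapes*, and unscaled magnitudes spanning orders of magnitude
would dominate Euclidean distance. Raw and log10 variants remain available
by flag. The implementation keeps the per-iteration objective, asserts it
never increases, and is cross-checked against scikit-learn's KMeans
objective in the test suite.

## Poly(A) cleavage sites

A tail read has one extremity aligned and the other a poly(A) tract (3')
or poly(T) tract (5' — the same pattern on the reverse complement, which
is how it is detected). The anchor is the longest read prefix with a
unique *exact* genome hit and length >= 20; the remainder must be >= 5 nt,
>= 90% A, and begin with an A. Two non-default decisions deserve note:

- **Exact anchors.** Allowing mismatches in the anchor lets it absorb the
  first tail bases wherever the genome happens to continue A-rich,
  systematically shifting the called site downstream; the "last matching
  nucleotide" is only well defined when the anchor matches exactly. The
  mismatch budget is exposed (`anchor_mm`) but defaults to 0.
- **Tail starts with A.** Without this, a sequencing error at the last
  templated base produces an off-by-one phantom site supported by real
  reads; requiring the clipped tract to look like a tail from its first
  base suppresses these at negligible cost to sensitivity.

Sites are grouped at exact (position, strand); a `merge_radius` option
pools neighbouring positions onto the best-supported one. Validation
requires two distinct species. Note an intrinsic limit: when the genome
itself continues with adenosines past the true site, the cleavage position
is unidentifiable from tail reads by any method; the simulator therefore
pins two non-A bases after each planted site, and real-data users should
expect one-to-few-base uncertainty inside genomic A-runs.

Pentamer enrichment counts overlapping occurrences over the −50..−1
windows of all sites and compares with 1000 per-sequence mononucleotide
shuffles (composition preserved exactly per sequence); z = (obs − null
mean)/null sd with an upper-tail normal p. The mononucleotide null ignores
higher-order composition and therefore overstates significance for
homopolymer-like words; it is used because it is the test the pipeline is
built around, and its type-I behaviour on composition-free sequences is
verified (0.05 ± 0.02).

## Splicing frequency

For a validated junction, J = junction-spanning reads (raw multiplicity,
pooled over timepoints) and M = median of the timepoint-summed coverage
across the intron (the unspliced transcripts' contribution). The reported
frequency is J/(J+M): it is bounded by 1, equals 0 with no junction reads,
is monotone in J, and estimates the spliced fraction of transcripts (up to
a factor (L−1)/L from the one-base straddle requirement, < 2% for 50-nt
reads). The literal ratio J/M is also emitted. Two known biases: reads
with a 1–2 base seam overhang that also match the genome within 2
mismatches are discarded by the uniqueness rule (slightly deflating J),
and read-through transcription from a neighbouring gene inflates intron
coverage (deflating the estimate); the junction-recovery test therefore
isolates the estimator on read-through-free mixtures, where the absolute
error is <= 0.05 at high depth.

Consequences are classified against a same-strand containing gene: intron
length not divisible by 3 is a frameshift; otherwise the spliced CDS is
translated and an internal stop means premature_stop, else
in_frame_deletion; junctions without a same-strand host gene are
noncoding_or_antisense.

## Spatial clustering statistic

AMD(S) = mean over genes g in S of min_{h in S, h != g} |rank(g) −
rank(h)|, on the linear gene order (the genome is a linear molecule; a
circular variant is available by flag). The alternative convention
"number of unselected genes between neighbours" (rank difference − 1) is
implemented as `genes_between`; `rank_diff` is the default because only it
reproduces, for a 50-of-416 selection, a null expectation (≈ 4.5) and
z-scale consistent with the published analysis this statistic follows.
The permutation test draws k ranks uniformly without replacement, uses the
lower tail (clustering), and reports p = (1 + #{null <= observed}) /
(n_perm + 1) so p is never 0. Calibration (p uniform under the null) and
agreement with exhaustive enumeration at small N are tested.

## The simulator

The generator emulates the statistical structure the analysis assumes, at
desk scale (default 60 genes plus 2 ITR duplicates, ~55 kb genome, 12,000
reads per timepoint at 50 nt — the study-scale genome has 416 genes and
~10^8 reads; sizes were reduced to keep the full pipeline in seconds):

- **Temporal program.** Six fixed piecewise archetypes in two families —
  three peak-then-decline shapes differing in peak time, three
  monotone-increase shapes differing in onset, including a late-burst
  shape silent through 14 min and surging at 40 min — scaled by lognormal
  per-gene amplitudes (sigma 0.8). Viral abundance at T0 is forced to 0.
- **Library composition.** The viral share of reads per timepoint is
  (0, 2%, 10%, 20%, 33%, 41%) for T0..T60 — anchored at the reported ~2%
  (7 min) and 41% (60 min) endpoints, interpolated between — and
  per-timepoint depth multipliers (1.0, 1.2, 0.9, 1.1, 1.3, 0.8) make the
  scaling factors non-trivial. The host is a single random 100-kb decoy.
- **3' ends.** Every gene gets one cleavage site 25–60 nt past its stop;
  72% carry TGTAA with first base at −17 (the planted fraction matches
  the 26/36 reported for the real virus); tails are uniform 30–120 nt;
  the two bases past each site are pinned non-A (see above).
- **Introns.** GT..AG introns at codon boundaries in ~8 genes with
  spliced fractions uniform in a configurable range; the protein
  consequence is fixed *by construction* (length % 3 for frameshifts, an
  engineered stop codon in the first post-junction codon for
  premature_stop, stop-free codons elsewhere), so consequence recovery is
  scored against an independent truth, not a reimplementation.
- **Read-through.** With probability 0.1 per transcript the molecule
  extends through the downstream neighbour. Read-through variants emit no
  tail-bearing fragments: a read-through molecule terminates at a
  downstream cleavage site, not one of its own, and modelling it
  otherwise would plant phantom poly(A) sites the detector would rightly
  find.
- **Errors.** Substitutions i.i.d. per base (default 0.005); no indels,
  no quality model, no coverage bias, single-end only.

ITR duplicates are reverse-complemented copies at the genome ends with
strand flipped, so oriented gene sequences are byte-identical and every
read from either copy is a two-locus mapper. All randomness flows from
explicit seeds; identical seeds give byte-identical FASTQ.

What passing tests show — and do not. Recovery results on this simulator
demonstrate the pipeline's correctness under its own assumptions (uniform
fragment sampling, substitution-only errors, exact annotation, planted
signals at fixed offsets). They do not establish performance under real
base-caller behaviour on homopolymers (which in practice depletes
tail-bearing reads), real promoter/terminator heterogeneity, RNA
degradation, or host transcriptome complexity.

## Defaults

| parameter | default | note |
|---|---|---|
| max mismatches (full length) | 2 | uniqueness also enforced within this budget |
| max intron | 2000 bp | upper bound for split search and validation |
| min intron | 20 bp | lower bound, configurable |
| junction species threshold | 5 | distinct species, pooled timepoints |
| CS species threshold | 2 | distinct species, exact position |
| anchor_min / tail_min / purity | 20 / 5 / 0.9 | tail-read rescue |
| anchor mismatches | 0 | see poly(A) section |
| shuffles | 1000 | pentamer null |
| K-means k / restarts | 6 / 100 | seeded |
| permutations | 10,000 | AMD null |
| profile smoothing | 5 positions | centred, clipped at edges |
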