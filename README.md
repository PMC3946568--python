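# earlyburst

Analysis toolkit for the earliest stage of a lytic virus infection assayed
by poly(A)+ RNA-seq: a compact, fully tested re-implementation of the
bespoke computations needed to profile a small dsDNA virus (a
chlorovirus-like genome with ~400 tightly packed genes, inverted terminal
repeats and pervasive transcriptional read-through) over a 0–60 minute
post-infection time course — together with a seeded synthetic read
simulator whose planted ground truth makes every stage testable.

It is written for computational biologists who want the individual
primitives (quantification, poly(A)-site calling, junction discovery,
genome-organization statistics) as an importable library; a thin
`earlyburst` command wraps the end-to-end pipeline.

## What it computes

- **MRPN expression quantification.** For gene *g* at timepoint *t*,
  MRPN(g,t) = median over ORF positions of the per-base weighted read
  coverage. The median (unlike the mean behind RPKM) resists the local
  coverage inflation that read-through transcripts cause in a gene-dense
  genome. Depth normalization divides by
  s_t = (mapped reads at t) / (mapped reads at T0), host and virus pooled,
  so values are comparable at pre-infection depth; s_T0 = 1 by
  construction.
- **Two-step unique mapping.** Read *species* (identical reads irrespective
  of strand) are aligned full length with at most 2 mismatches; only unique
  loci count, except reads hitting exactly the two copies of an inverted
  terminal repeat, which contribute weight 0.5 to each copy. A junction
  contig library (flank + flank around each candidate intron) rescues
  seam-spanning reads into two-block alignments. The aligner is
  property-tested against a brute-force scan of every position and
  orientation.
- **Poly(A) cleavage sites.** Unmapped reads with one exactly aligned
  extremity and a poly(A) (or poly(T), opposite orientation) remainder
  locate the cleavage site at the last templated base; sites need >= 2
  independent read species. Around validated sites the package computes
  smoothed positional nucleotide profiles, overlapping pentamer counts
  scored by z against a per-sequence mononucleotide-shuffle null, and
  positional histograms (the TGTAA signal concentrates near position −17).
- **Splice junctions.** Split reads propose introns (< 2000 bp); junctions
  validated by >= 5 read species are classified by terminal dinucleotides
  (GT–AG / GC–AG / AT–AC, forward or reverse complemented — which also
  infers the transcription strand), given a protein-level consequence
  (frameshift / in-frame deletion / premature stop / noncoding-antisense),
  and a splicing frequency f = J/(J+M), with J junction reads pooled over
  timepoints and M the intron's median pooled coverage.
- **Genome organization.** IUPAC promoter-motif scanning (−150..+50 around
  the ATG) and a permutation test for spatial clustering of a gene set
  using the average minimal distance (AMD): mean over selected genes of the
  minimum absolute gene-rank difference to another selected gene.

## Worked example

```
python examples/04_gene_clustering_test.py
```

prints

```
clustered selection: AMD=1.00, null=4.51+/-0.47, p=0.0001
random selection:    AMD=4.62, p=0.6015
```

A 50-gene selection packed into three contiguous blocks of a 416-gene
genome has AMD 1.0 — every selected gene is adjacent to another — while
random 50-gene selections average AMD 4.51 ± 0.47, so the clustered set is
significant at p = 1e-4 (the add-one floor of a 10,000-permutation test);
a random selection is not (p = 0.60). The other examples simulate an
infection and run quantification (`01`), cleavage-site calling with the
TGTAA enrichment landing on the planted −17 position (`02`), and junction
discovery with frequency estimates within a few percent of the planted
spliced fractions (`03`).

The full pipeline on synthetic data:

```
earlyburst run --outdir run1 --seed 1
```

writes the simulated experiment, alignments, expression table, cleavage
sites, junctions and a JSON/text report (per-timepoint viral read
fraction, top-expressed genes, clustering test, promoter-motif counts).

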