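"""Exon-junction discovery, splicing-frequency estimation and consequences.

Candidate junctions come from two routes: alignments to the junction contig
library (canonical splice sites) and de novo split-read hits (which also
capture spliceosome-independent excisions). A junction is validated when at
least 5 distinct read species support it, pooled over all timepoints.

The intron's terminal dinucleotides classify the motif and infer the
transcription strand: GT..AG / GC..AG / AT..AC read forward imply a +
strand transcript; their reverse complements (CT..AC / CT..GC / GT..AT)
imply -; anything else is noncanonical with unknown strand.

Splicing frequency is estimated from J junction-spanning reads (raw reads,
cumulated over all timepoints) and M, the MRPN of the timepoint-pooled
coverage across the intron (contributed by unspliced transcripts):
``frequency = J / (J + M)``, a bounded spliced-fraction estimate; the
literal ratio J / M is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .formats import GenomeAnnotation
from .mapping import AlignmentRecord, SplitHit

__all__ = [
    "SpliceJunction",
    "discover_junctions",
    "splicing_frequency",
    "classify_consequence",
    "junction_table",
]

#: forward intron motifs (donor, acceptor) -> class; reverse complements -> '-'
_FORWARD_MOTIFS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG",
                   ("AT", "AC"): "AT-AC"}
_REVERSE_MOTIFS = {("CT", "AC"): "GT-AG", ("CT", "GC"): "GC-AG",
                   ("GT", "AT"): "AT-AC"}


@dataclass
class SpliceJunction:
    intron_start: int
    intron_end: int
    motif_class: str                 # GT-AG | GC-AG | AT-AC | noncanonical
    inferred_strand: str             # + | - | unknown
    n_species: int
    n_reads_total: int
    frequency: float | None = None   # bounded J/(J+M)
    frequency_literal: float | None = None
    consequence: str | None = None
    flagged: bool = False

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


def _classify_motif(genome: GenomeAnnotation, i_start: int,
                    i_end: int) -> tuple[str, str]:
    donor = genome.subseq(i_start, i_start + 1)
    acceptor = genome.subseq(i_end - 1, i_end)
    if (donor, acceptor) in _FORWARD_MOTIFS:
        return _FORWARD_MOTIFS[(donor, acceptor)], "+"
    if (donor, acceptor) in _REVERSE_MOTIFS:
        return _REVERSE_MOTIFS[(donor, acceptor)], "-"
    return "noncanonical", "unknown"


def discover_junctions(split_hits: Sequence[SplitHit],
                       junction_alignments: Sequence[AlignmentRecord],
                       genome: GenomeAnnotation,
                       min_species: int = 5, min_intron: int = 20,
                       max_intron: int = 2000) -> list[SpliceJunction]:
    """Validated junctions keyed by exact intron coordinates.

    Species are counted pooled over all timepoints; junction reads are raw
    read counts (multiplicity summed). Junctions shorter than ``min_intron``
    or not shorter than ``max_intron`` are dropped.
    """
    support: dict[tuple[int, int], dict[str, int]] = {}
    for hit in split_hits:
        key = hit.intron
        support.setdefault(key, {})[hit.species.canonical] = hit.species.total
    for aln in junction_alignments:
        if len(aln.blocks) != 2:
            continue
        key = (aln.blocks[0][1] + 1, aln.blocks[1][0] - 1)
        support.setdefault(key, {})[aln.species.canonical] = aln.species.total
    out = []
    for (i_start, i_end), species in sorted(support.items()):
        length = i_end - i_start + 1
        if not (min_intron <= length < max_intron):
            continue
        if len(species) < min_species:
            continue
        motif, strand = _classify_motif(genome, i_start, i_end)
        out.append(SpliceJunction(i_start, i_end, motif, strand,
                                  n_species=len(species),
                                  n_reads_total=sum(species.values())))
    return out


def splicing_frequency(junction: SpliceJunction,
                       pooled_coverage: np.ndarray) -> SpliceJunction:
    """Attach frequency estimates; ``pooled_coverage`` is the timepoint-summed
    per-base genome coverage (0-based array)."""
    m = float(np.median(
        pooled_coverage[junction.intron_start - 1:junction.intron_end]))
    j = junction.n_reads_total
    if j == 0 and m == 0:
        junction.frequency = None
        junction.frequency_literal = None
        junction.flagged = True
        return junction
    junction.frequency = j / (j + m)
    junction.frequency_literal = float("inf") if m == 0 else j / m
    return junction


def classify_consequence(junction: SpliceJunction,
                         genome: GenomeAnnotation) -> str:
    """Protein-level consequence of the excision against the annotation.

    An intron inside a same-strand gene's CDS span causes a frameshift when
    its length is not a multiple of 3; otherwise the spliced CDS is
    translated and an internal stop yields premature_stop, else
    in_frame_deletion. Without a same-strand overlapping gene the excision
    is noncoding_or_antisense. A junction spanning multiple genes is
    classified against the gene containing the donor and flagged.
    """
    i_start, i_end = junction.intron_start, junction.intron_end
    strand = junction.inferred_strand
    if strand not in "+-":
        junction.consequence = "noncoding_or_antisense"
        return junction.consequence
    donor_pos = i_start if strand == "+" else i_end
    containing = [g for g in genome.genes if g.strand == strand
                  and g.start <= i_start and i_end <= g.end]
    if not containing:
        host_genes = [g for g in genome.genes if g.strand == strand
                      and g.start <= donor_pos <= g.end]
        if host_genes:
            junction.flagged = True      # spans beyond the donor's gene
            containing = host_genes
        else:
            junction.consequence = "noncoding_or_antisense"
            return junction.consequence
    gene = containing[0]
    if junction.intron_length % 3 != 0:
        junction.consequence = "frameshift"
        return junction.consequence
    def _span(a: int, b: int) -> str:
        return genome.subseq(a, b) if a <= b else ""

    cds = _span(gene.start, min(i_start - 1, gene.end)) + \
        _span(max(i_end + 1, gene.start), gene.end)
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    prot = str(Seq(cds[:len(cds) // 3 * 3]).translate())
    junction.consequence = ("premature_stop" if "*" in prot[:-1]
                            else "in_frame_deletion")
    return junction.consequence


def junction_table(junctions: Sequence[SpliceJunction]):
    import pandas as pd

    return pd.DataFrame([{
        "intron_start": j.intron_start, "intron_end": j.intron_end,
        "intron_length": j.intron_length, "motif_class": j.motif_class,
        "strand": j.inferred_strand, "n_species": j.n_species,
        "n_reads": j.n_reads_total, "frequency_bounded": j.frequency,
        "frequency_literal": j.frequency_literal,
        "consequence": j.consequence, "flagged": j.flagged,
    } for j in junctions])
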