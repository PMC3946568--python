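"""Domain types, coordinate conventions and on-disk formats.

All public coordinates are 1-based inclusive (GFF3 convention). Internal
0-based half-open slices are used freely but never exposed through the API.

Reads are treated as strandless: the unit of evidence everywhere downstream
is the *read species*, a group of identical reads irrespective of strand,
keyed by the lexicographic minimum of the sequence and its reverse
complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneRecord",
    "GenomeAnnotation",
    "ReadSpecies",
    "Timepoint",
    "DEFAULT_TIMEPOINTS",
    "revcomp",
    "canonical_sequence",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_fastq",
    "write_fastq",
    "read_manifest",
    "write_manifest",
    "dedupe_to_species",
    "load_annotation",
]


class FormatError(ValueError):
    """Malformed input file (duplicate ids, empty file, bad syntax)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes tolerated)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_sequence(seq: str) -> str:
    """Strand-symmetric representative: min(seq, revcomp(seq))."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass(frozen=True, order=True)
class Timepoint:
    """A sampling time, e.g. T7 = 7 minutes post infection."""

    label: str
    minutes_pi: float

    def __post_init__(self) -> None:
        if self.minutes_pi < 0:
            raise ValidationError(f"negative minutes_pi for {self.label}")


#: The infection time course assayed by the study: minutes post infection.
DEFAULT_TIMEPOINTS: tuple[Timepoint, ...] = (
    Timepoint("T0", 0),
    Timepoint("T7", 7),
    Timepoint("T14", 14),
    Timepoint("T20", 20),
    Timepoint("T40", 40),
    Timepoint("T60", 60),
)


@dataclass(frozen=True)
class GeneRecord:
    """A gene (CDS span) on the genome, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Genome sequence plus ordered gene records and ITR partner links.

    ``itr_pairs`` lists pairs of gene ids located in the inverted terminal
    repeats whose strand-oriented sequences are byte-identical; reads from
    either copy map ambiguously to both loci.
    """

    genome_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    itr_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice of the genome."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValidationError(f"subseq [{start},{end}] outside genome")
        return self.sequence[start - 1:end]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_sequence(self, gene: GeneRecord | str) -> str:
        """Strand-oriented (5'->3' on the coding strand) gene sequence."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        s = self.subseq(gene.start, gene.end)
        return s if gene.strand == "+" else revcomp(s)

    def validate(self) -> None:
        n = len(self.sequence)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene ids")
        for g in self.genes:
            if g.start < 1 or g.end > n:
                raise ValidationError(
                    f"{g.gene_id}: [{g.start},{g.end}] outside genome of length {n}")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValidationError("genes not sorted by start")
        if sorted(g.rank for g in self.genes) != list(range(1, len(self.genes) + 1)):
            raise ValidationError("gene ranks are not a permutation of 1..N")
        for a, b in self.itr_pairs:
            if self.gene_sequence(a) != self.gene_sequence(b):
                raise ValidationError(f"ITR pair ({a},{b}) sequences differ")


@dataclass
class ReadSpecies:
    """Group of identical reads irrespective of strand.

    ``multiplicity`` maps timepoint label -> number of raw reads observed;
    both per-timepoint and pooled views are derivable from it.
    """

    canonical: str
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.canonical != canonical_sequence(self.canonical):
            raise ValidationError("sequence is not in canonical orientation")

    @property
    def total(self) -> int:
        return sum(self.multiplicity.values())

    def __len__(self) -> int:
        return len(self.canonical)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercased sequence} mapping.

    Non-ACGT characters are preserved but flagged with a warning; they never
    match any motif or read base downstream.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGT"):
            warnings.warn(f"sequence {rec.id!r} contains non-ACGT characters")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3(path: str | Path, genome: GenomeAnnotation) -> list[GeneRecord]:
    """Read gene features from GFF3 and attach them (sorted, ranked) to *genome*.

    ITR partner links are taken from an ``itr_partner=<gene_id>`` attribute.
    Coordinates are validated against the genome length.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                            keep_order=True)
    feats = []
    partners: dict[str, str] = {}
    for f in db.all_features(featuretype=("gene", "CDS")):
        if f.featuretype != "gene":
            continue
        gid = f.attributes.get("ID", [f.id])[0]
        if f.end > len(genome.sequence) or f.start < 1:
            raise ValidationError(
                f"{gid}: [{f.start},{f.end}] outside genome of length "
                f"{len(genome.sequence)}")
        feats.append((f.start, gid, f.end, f.strand))
        if "itr_partner" in f.attributes:
            partners[gid] = f.attributes["itr_partner"][0]
    feats.sort()
    genes = [GeneRecord(gid, start, end, strand, rank=i + 1)
             for i, (start, gid, end, strand) in enumerate(feats)]
    genome.genes = genes
    pairs = set()
    for a, b in partners.items():
        pairs.add(tuple(sorted((a, b))))
    genome.itr_pairs = sorted(pairs)
    genome.validate()
    return genes


def write_gff3(genome: GenomeAnnotation, path: str | Path) -> None:
    partner = {}
    for a, b in genome.itr_pairs:
        partner[a], partner[b] = b, a
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.gene_id in partner:
                attrs += f";itr_partner={partner[g.gene_id]}"
            fh.write("\t".join([genome.genome_id, "earlyburst", "gene",
                                str(g.start), str(g.end), ".", g.strand, ".",
                                attrs]) + "\n")


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from FASTQ; qualities are parsed then ignored."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


MANIFEST_COLUMNS = ["sample", "timepoint", "minutes", "fastq_path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns {sorted(missing)}")
    if df["timepoint"].duplicated().any():
        raise FormatError("duplicate timepoint labels in manifest")
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: Sequence[Mapping], path: str | Path) -> None:
    pd.DataFrame(list(rows))[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read species
# ---------------------------------------------------------------------------

def dedupe_to_species(reads: Iterable[tuple[str, str]]) -> list[ReadSpecies]:
    """Collapse (sequence, timepoint) reads into strand-irrespective species.

    Forward and reverse-complement copies merge into one species; the total
    multiplicity over all species equals the number of input reads. Output is
    sorted by canonical sequence for deterministic downstream behaviour.
    """
    table: dict[str, dict[str, int]] = {}
    for seq, tp in reads:
        if not seq:
            raise ValidationError("empty read sequence")
        key = canonical_sequence(seq.upper())
        mult = table.setdefault(key, {})
        mult[tp] = mult.get(tp, 0) + 1
    return [ReadSpecies(k, table[k]) for k in sorted(table)]


def load_annotation(fasta_path: str | Path, gff_path: str | Path) -> GenomeAnnotation:
    """Load genome FASTA + GFF3 gene annotation into one GenomeAnnotation."""
    seqs = read_fasta(fasta_path)
    genome_id, sequence = next(iter(seqs.items()))
    genome = GenomeAnnotation(genome_id, sequence)
    read_gff3(gff_path, genome)
    return genome
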