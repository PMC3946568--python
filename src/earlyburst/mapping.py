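"""Desk-scale two-step read mapping.

Step one compiles a junction contig library; step two aligns every read
species full length against the reference genome(s) plus the library,
keeping only species with a *unique* alignment at <=2 mismatches. Species
hitting exactly the two copies of an inverted terminal repeat are kept with
weight 0.5 per copy; all other multi-mappers are discarded from counting.
Species that fail full-length alignment feed the split-read search used for
de novo junction discovery and the poly(A)-tail rescue.

The aligner is a seed-and-verify exact method: by pigeonhole, a full-length
hit with at most ``max_mm`` mismatches leaves at least one of ``max_mm + 1``
contiguous read segments mismatch-free, so exact matching of those segments
enumerates every candidate locus. It is equivalent to a brute-force scan of
every position and orientation (property-tested against one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import GenomeAnnotation, ReadSpecies, revcomp

__all__ = [
    "AlignmentRecord",
    "SplitHit",
    "JunctionContig",
    "ReferenceIndex",
    "map_unique",
    "resolve_itr",
    "find_split_hits",
    "build_junction_library",
    "brute_force_hits",
    "write_alignments_tsv",
]


@dataclass
class AlignmentRecord:
    """A full-length alignment of a read species, possibly junction-spanning.

    ``blocks`` are 1-based inclusive genomic segments: one block for a
    contiguous alignment, two for a junction-spanning one. ``weight`` is 1.0
    for unique hits and 0.5 for each copy of an ITR-resolved double hit.
    """

    species: ReadSpecies
    target: str
    start: int
    orientation: str                     # "forward" | "revcomp"
    mismatches: int
    blocks: tuple[tuple[int, int], ...]
    weight: float = 1.0

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class SplitHit:
    """Two segments of one read mapped to two nearby loci (same orientation)."""

    species: ReadSpecies
    orientation: str
    read_split: int                      # first segment = read[:read_split]
    seg1: tuple[int, int]                # 1-based genomic span of segment 1
    seg2: tuple[int, int]
    mismatches: int
    target: str = "virus"

    @property
    def gap(self) -> int:
        """Genomic distance skipped between the segments (intron length)."""
        return self.seg2[0] - self.seg1[1] - 1

    @property
    def intron(self) -> tuple[int, int]:
        return self.seg1[1] + 1, self.seg2[0] - 1


#: canonical (donor, acceptor) dinucleotides, forward and reverse-complement
_CANONICAL_ENDS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC"),
                   ("CT", "AC"), ("CT", "GC"), ("GT", "AT")}


@dataclass
class JunctionContig:
    contig_id: str
    sequence: str
    intron_start: int
    intron_end: int
    flank_left: int                      # bases of sequence left of the seam
    truncated: bool = False
    genome_id: str = "virus"


class ReferenceIndex:
    """Exact substring index over one reference sequence.

    Supports mismatch-bounded full-length search via pigeonhole seeding; the
    reference is also held as a byte array for O(length) Hamming checks.
    """

    def __init__(self, name: str, sequence: str):
        self.name = name
        self.sequence = sequence
        self.arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
        self._kmer_cache: dict[int, dict[str, list[int]]] = {}

    def __len__(self) -> int:
        return len(self.sequence)

    def _kmers(self, k: int) -> dict[str, list[int]]:
        if k not in self._kmer_cache:
            table: dict[str, list[int]] = {}
            s = self.sequence
            for i in range(len(s) - k + 1):
                table.setdefault(s[i:i + k], []).append(i)
            self._kmer_cache[k] = table
        return self._kmer_cache[k]

    def _candidates(self, query: str, max_mm: int) -> set[int]:
        """Candidate 0-based start positions via pigeonhole seeds."""
        L = len(query)
        n_parts = max_mm + 1
        bounds = np.linspace(0, L, n_parts + 1).astype(int)
        part_len = int(min(np.diff(bounds)))
        out: set[int] = set()
        if part_len >= 12:
            # seed with the leading k bases of each part from the k-mer table
            k = min(16, part_len)
            table = self._kmers(k)
            for b in bounds[:-1]:
                for p in table.get(query[b:b + k], ()):
                    start = p - int(b)
                    if 0 <= start <= len(self.sequence) - L:
                        out.add(start)
        else:
            # short query: locate each part exactly with str.find
            s = self.sequence
            for i in range(n_parts):
                part = query[bounds[i]:bounds[i + 1]]
                j = s.find(part)
                while j != -1:
                    start = j - int(bounds[i])
                    if 0 <= start <= len(s) - L:
                        out.add(start)
                    j = s.find(part, j + 1)
        return out

    def hamming(self, query_arr: np.ndarray, start: int) -> int:
        ref = self.arr[start:start + query_arr.size]
        return int(np.count_nonzero(ref != query_arr))

    def hits(self, query: str, max_mm: int) -> list[tuple[int, int]]:
        """All (0-based start, mismatches) with mismatches <= max_mm."""
        if len(query) > len(self.sequence):
            return []
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        found = []
        for start in self._candidates(query, max_mm):
            mm = self.hamming(q, start)
            if mm <= max_mm:
                found.append((start, mm))
        return sorted(found)


def brute_force_hits(query: str, sequence: str, max_mm: int) -> list[tuple[int, int]]:
    """Independent oracle: scan every position; returns (0-based start, mm)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    s = np.frombuffer(sequence.encode(), dtype=np.uint8)
    L = q.size
    if L > s.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(s, L)
    mm = (windows != q).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mm)[0]]


def _orientation_hits(index: ReferenceIndex, seq: str, max_mm: int,
                      ) -> dict[tuple[int], tuple[int, str]]:
    """Best (mm, orientation) per locus, searching both orientations."""
    loci: dict[int, tuple[int, str]] = {}
    for orient, q in (("forward", seq), ("revcomp", revcomp(seq))):
        for start, mm in index.hits(q, max_mm):
            cur = loci.get(start)
            if cur is None or mm < cur[0]:
                loci[start] = (mm, orient)
    return loci


def map_unique(species: Sequence[ReadSpecies],
               references: GenomeAnnotation | Mapping[str, str],
               junction_library: Sequence[JunctionContig] = (),
               max_mm: int = 2,
               ) -> tuple[list[AlignmentRecord],
                          list[tuple[ReadSpecies, list[AlignmentRecord]]],
                          list[ReadSpecies]]:
    """Full-length unique alignment of read species.

    Returns ``(alignments, ambiguous, unmapped)``: species with exactly one
    <=max_mm locus across genome(s) + junction library are aligned; species
    with exactly two genomic loci are returned under ``ambiguous`` (as two
    candidate records) for ITR resolution; species with no locus are
    ``unmapped``; species with 3+ loci are silently discarded from counting.

    Alignments to junction contigs must straddle the exon seam by at least
    one base on each side and are translated back to 2-block genome
    coordinates.
    """
    if isinstance(references, GenomeAnnotation):
        refs = {references.genome_id: references.sequence}
    else:
        refs = dict(references)
    if not refs or any(not s for s in refs.values()):
        raise ValueError("empty reference sequence")
    indexes = {name: ReferenceIndex(name, seq) for name, seq in refs.items()}
    combined = _CombinedContigs(junction_library) if junction_library else None

    alignments: list[AlignmentRecord] = []
    ambiguous: list[tuple[ReadSpecies, list[AlignmentRecord]]] = []
    unmapped: list[ReadSpecies] = []
    for sp in species:
        seq = sp.canonical
        L = len(seq)
        records: list[AlignmentRecord] = []
        for name, index in indexes.items():
            for start, (mm, orient) in _orientation_hits(index, seq, max_mm).items():
                records.append(AlignmentRecord(
                    sp, name, start + 1, orient, mm,
                    ((start + 1, start + L),)))
        if combined is not None:
            for start, (mm, orient) in _orientation_hits(combined.index, seq,
                                                         max_mm).items():
                located = combined.locate(start, L)
                if located is None:
                    continue
                contig, local_start = located
                rec = _translate_contig_hit(sp, contig, local_start, L, mm,
                                            orient)
                if rec is not None:
                    records.append(rec)
        if not records:
            unmapped.append(sp)
        elif len(records) == 1:
            alignments.append(records[0])
        elif len(records) == 2:
            ambiguous.append((sp, records))
        # 3+ loci: discarded
    return alignments, ambiguous, unmapped


class _CombinedContigs:
    """All junction contigs concatenated (N-separated) under one index.

    The separator guarantees a read overlapping two contigs accrues more
    mismatches than any allowed threshold, so hits stay within one contig.
    """

    _SEP = "N" * 4

    def __init__(self, contigs: Sequence[JunctionContig]):
        self.contigs = list(contigs)
        offsets = []
        pos = 0
        parts = []
        for c in self.contigs:
            offsets.append(pos)
            parts.append(c.sequence)
            pos += len(c.sequence) + len(self._SEP)
            parts.append(self._SEP)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.index = ReferenceIndex("junctions", "".join(parts))

    def locate(self, start: int, length: int,
               ) -> tuple[JunctionContig, int] | None:
        i = int(np.searchsorted(self.offsets, start, side="right")) - 1
        contig = self.contigs[i]
        local = start - int(self.offsets[i])
        if local + length > len(contig.sequence):
            return None                  # runs into the separator
        return contig, local


def _translate_contig_hit(sp: ReadSpecies, contig: JunctionContig, start: int,
                          L: int, mm: int, orient: str,
                          ) -> AlignmentRecord | None:
    """Contig coordinates -> 2-block genome alignment; None if not straddling."""
    left = contig.flank_left - start          # bases aligned left of the seam
    right = L - left
    if left < 1 or right < 1:
        return None                           # must straddle by >=1 base each side
    block1 = (contig.intron_start - left, contig.intron_start - 1)
    block2 = (contig.intron_end + 1, contig.intron_end + right)
    return AlignmentRecord(sp, contig.genome_id, block1[0], orient, mm,
                           (block1, block2))


def resolve_itr(ambiguous: Sequence[tuple[ReadSpecies, list[AlignmentRecord]]],
                genome: GenomeAnnotation) -> list[AlignmentRecord]:
    """Keep exactly-2-locus species whose hits fall in partnered ITR genes.

    Both alignments are emitted with weight 0.5 each, so the total weight a
    species contributes equals its multiplicity. Non-ITR double hits stay
    discarded.
    """
    spans = {g.gene_id: g for g in genome.genes}
    partners = {frozenset(p) for p in genome.itr_pairs}
    out: list[AlignmentRecord] = []
    for sp, records in ambiguous:
        if len(records) != 2 or any(len(r.blocks) != 1 for r in records):
            continue
        homes = []
        for r in records:
            gid = next((g.gene_id for g in genome.genes
                        if r.target == genome.genome_id
                        and g.start <= r.start and r.end <= g.end), None)
            homes.append(gid)
        if None in homes or frozenset(homes) not in partners:
            continue
        for r in records:
            r.weight = 0.5
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Split-read search
# ---------------------------------------------------------------------------

def find_split_hits(unmapped: Sequence[ReadSpecies],
                    genome: GenomeAnnotation | str,
                    min_anchor: int = 8, max_gap: int = 2000,
                    max_mm: int = 2, target: str = "virus",
                    ) -> list[SplitHit]:
    """Two-segment alignment of species that failed full-length mapping.

    For each species and orientation, candidate diagonals are collected from
    exact 8-mer matches; every diagonal pair separated by less than
    ``max_gap`` is scored over all split points with both segments >=
    ``min_anchor`` and total mismatches <= ``max_mm``. The best split wins:
    fewest mismatches, then a split whose implied intron ends with a
    canonical splice motif (either strand) over one that does not — the
    intron coordinate is otherwise ambiguous whenever the genome repeats
    around the seam — then longest first segment, then leftmost position.
    """
    if min_anchor < 8:
        raise ValueError("min_anchor must be >= 8")
    seq = genome.sequence if isinstance(genome, GenomeAnnotation) else genome
    index = ReferenceIndex(target, seq)
    table = index._kmers(8)
    ref = index.arr
    out: list[SplitHit] = []
    for sp in unmapped:
        best: tuple | None = None
        for orient, q in (("forward", sp.canonical),
                          ("revcomp", revcomp(sp.canonical))):
            L = len(q)
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            diags: set[int] = set()
            for j in range(0, L - 8 + 1):
                for p in table.get(q[j:j + 8], ()):
                    d = p - j
                    if -L < d <= len(seq) - L + max_gap:
                        diags.add(d)
            dlist = sorted(diags)
            for i1, d1 in enumerate(dlist):
                if d1 < 0 or d1 + L > len(seq):
                    continue
                mm1 = np.cumsum(np.concatenate(
                    [[0], (ref[d1:d1 + L] != qa).astype(np.int32)]))
                for d2 in dlist[i1 + 1:]:
                    if d2 - d1 >= max_gap:
                        break
                    if d2 + L > len(seq):
                        continue
                    diff2 = (ref[d2:d2 + L] != qa).astype(np.int32)
                    mm2 = np.concatenate([[0], np.cumsum(diff2)])
                    total2 = mm2[-1]
                    for s in range(min_anchor, L - min_anchor + 1):
                        mm = int(mm1[s] + (total2 - mm2[s]))
                        if mm > max_mm:
                            continue
                        motif = (seq[d1 + s:d1 + s + 2],
                                 seq[d2 + s - 2:d2 + s])
                        penalty = 0 if motif in _CANONICAL_ENDS else 1
                        cand = (mm, penalty, -s, d1, d2, orient)
                        if best is None or cand < best:
                            best = cand
        if best is not None:
            mm, _, neg_s, d1, d2, orient = best
            s = -neg_s
            L = len(sp.canonical)
            out.append(SplitHit(sp, orient, s,
                                (d1 + 1, d1 + s),
                                (d2 + s + 1, d2 + L),
                                mm, target))
    return out


def build_junction_library(junctions: Iterable, genome: GenomeAnnotation,
                           flank: int) -> list[JunctionContig]:
    """Exon-seam contigs: ``flank`` nt before the donor + after the acceptor.

    ``junctions`` yields objects (or pairs) with intron_start/intron_end.
    Contigs at genome edges are truncated and flagged.
    """
    contigs = []
    n = len(genome)
    for j in junctions:
        if isinstance(j, tuple):
            i_start, i_end = j
        else:
            i_start, i_end = j.intron_start, j.intron_end
        left_lo = max(1, i_start - flank)
        right_hi = min(n, i_end + flank)
        seq = genome.subseq(left_lo, i_start - 1) + genome.subseq(i_end + 1, right_hi)
        truncated = (left_lo > i_start - flank) or (right_hi < i_end + flank)
        contigs.append(JunctionContig(f"J:{i_start}-{i_end}", seq, i_start,
                                      i_end, i_start - left_lo, truncated,
                                      genome.genome_id))
    return contigs


def write_alignments_tsv(alignments: Sequence[AlignmentRecord], path) -> None:
    import pandas as pd

    rows = [{
        "species": a.species.canonical,
        "target": a.target,
        "start": a.start,
        "end": a.end,
        "orientation": a.orientation,
        "mismatches": a.mismatches,
        "blocks": ",".join(f"{s}-{e}" for s, e in a.blocks),
        "weight": a.weight,
    } for a in alignments]
    pd.DataFrame(rows, columns=["species", "target", "start", "end",
                                "orientation", "mismatches", "blocks",
                                "weight"]).to_csv(path, sep="\t", index=False)
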