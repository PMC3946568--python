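"""Seeded simulator of a virus+host infection time course with known truth.

Emulates the statistical structure the downstream analysis assumes: a small
double-stranded DNA virus genome with genes on both strands and inverted
terminal repeat (ITR) duplicates, six sampling timepoints with temporally
programmed viral transcription (zero viral signal at T0), a host decoy
contributing a declining share of the library, poly(A) tails appended at
defined cleavage sites carrying a TGTAA signal at position -17, spliced /
unspliced transcript mixtures with canonical intron motifs, read-through
transcripts across gene boundaries, and i.i.d. substitution sequencing
errors on fixed-length unstranded single-end reads.

Every planted parameter is recorded in a :class:`TruthSet` so that recovery
by the analysis modules can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (DEFAULT_TIMEPOINTS, GeneRecord, GenomeAnnotation,
                      Timepoint, revcomp, write_fasta, write_fastq,
                      write_gff3, write_manifest)

__all__ = [
    "SimConfig",
    "TrueCleavageSite",
    "TrueIntron",
    "TruthSet",
    "SimRead",
    "SimulatedReadSet",
    "ARCHETYPES",
    "generate_genome",
    "assign_truth",
    "simulate_reads",
    "simulate_experiment",
    "write_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted({a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
                         - _STOPS)

#: Temporal archetypes over (T7, T14, T20, T40, T60); T0 is always zero.
#: Two broad families: peak-then-decline (three shapes differing in peak
#: time) and monotone-increase (three shapes differing in onset); the
#: "late_burst" shape appears at 20 min and rises sharply at 40 min.
ARCHETYPES: dict[str, tuple[float, ...]] = {
    "early_peak": (1.00, 0.85, 0.50, 0.25, 0.10),
    "mid_peak": (0.35, 0.80, 1.00, 0.60, 0.30),
    "late_peak": (0.10, 0.40, 0.75, 1.00, 0.60),
    "ramp_early": (0.15, 0.35, 0.55, 0.80, 1.00),
    "ramp_mid": (0.00, 0.20, 0.45, 0.75, 1.00),
    "late_burst": (0.00, 0.00, 0.10, 0.70, 1.00),
}


@dataclass
class SimConfig:
    """Simulation parameters; defaults define the study-like conditions.

    The viral share of the library anchors the endpoints reported for the
    real infection (~2% viral poly(A)+ RNA at 7 min p.i., 41% at 60 min);
    intermediate timepoints are interpolated. Per-timepoint depth
    multipliers make the depth-scaling factor non-trivial.
    """

    n_genes: int = 60
    mean_gene_len: int = 450
    genome_pad: int = 250
    itr_genes: int = 2
    host_len: int = 100_000
    # truth assignment
    tgtaa_fraction: float = 0.72
    n_intron_genes: int = 8
    intron_len_range: tuple[int, int] = (60, 400)
    max_intron: int = 2000
    splicing_frac_range: tuple[float, float] = (0.10, 0.90)
    readthrough_prob: float = 0.1
    cs_offset_range: tuple[int, int] = (25, 60)
    amplitude_sigma: float = 0.8
    viral_fraction: tuple[float, ...] = (0.0, 0.02, 0.10, 0.20, 0.33, 0.41)
    depth_multiplier: tuple[float, ...] = (1.0, 1.2, 0.9, 1.1, 1.3, 0.8)
    # read emission
    base_depth: int = 12_000
    read_len: int = 50
    error_rate: float = 0.005
    tail_len_range: tuple[int, int] = (30, 120)
    timepoints: tuple[Timepoint, ...] = DEFAULT_TIMEPOINTS


@dataclass
class TrueCleavageSite:
    gene_id: str
    position: int            # 1-based genome coordinate of last templated base
    strand: str
    has_tgtaa: bool
    usage_fraction: float = 1.0


@dataclass
class TrueIntron:
    gene_id: str
    intron_start: int        # 1-based first intronic base
    intron_end: int          # 1-based last intronic base
    motif_class: str
    strand: str
    frequency: float         # fraction of transcripts spliced
    consequence: str         # planted by construction, not recomputed


@dataclass
class TruthSet:
    """The simulator's planted parameters — the recovery oracle."""

    profiles: pd.DataFrame               # gene x timepoint transcript abundance
    archetype: dict[str, str]
    cleavage_sites: list[TrueCleavageSite]
    introns: list[TrueIntron]
    readthrough_prob: float
    viral_fraction: dict[str, float]
    depth: dict[str, int]
    error_rate: float
    seed: int

    def cs_by_gene(self) -> dict[str, TrueCleavageSite]:
        return {cs.gene_id: cs for cs in self.cleavage_sites}

    def introns_by_gene(self) -> dict[str, TrueIntron]:
        return {i.gene_id: i for i in self.introns}


@dataclass
class SimRead:
    sequence: str
    origin: str              # gene id, "host", "tail:<gene>", "junction:<gene>"
    chrom: str
    start: int               # 1-based leftmost templated genomic base (0 if none)
    end: int
    tail_bases: int = 0      # non-templated poly(A) bases carried by the read


@dataclass
class SimulatedReadSet:
    timepoint: str
    reads: list[SimRead] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free codons + TAA, so premature stops only arise by design."""
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


def generate_genome(n_genes: int = 60, mean_gene_len: int = 450,
                    genome_pad: int = 250, itr_genes: int = 2,
                    seed: int = 0) -> GenomeAnnotation:
    """Generate a random viral genome with genes on both strands.

    ``itr_genes`` genes placed at the left end are duplicated, reverse
    complemented, at the right end (an inverted terminal repeat), giving
    strand-oriented byte-identical gene pairs registered in ``itr_pairs``.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if itr_genes < 0:
        raise ValueError("itr_genes must be >= 0")
    if itr_genes > n_genes:
        raise ValueError("itr_genes cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[tuple[str, int, int, str]] = []
    pos = 0

    def pad() -> None:
        nonlocal pos
        n = int(genome_pad * rng.uniform(0.7, 1.3)) + 120
        parts.append(_random_seq(rng, n))
        pos += n

    pad()
    itr_records: list[tuple[str, str]] = []   # (gene_id, oriented cds)
    for i in range(n_genes):
        n_codons = max(34, int(rng.normal(mean_gene_len, mean_gene_len / 5)) // 3)
        cds = _random_cds(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"vg{i + 1:03d}"
        text = cds if strand == "+" else revcomp(cds)
        genes.append((gid, pos + 1, pos + len(cds), strand))
        parts.append(text)
        pos += len(cds)
        if i < itr_genes:
            itr_records.append((gid, cds))
        pad()
    # right-end inverted copies of the left-end ITR genes, in reverse order
    itr_pairs: list[tuple[str, str]] = []
    src_strand = {g[0]: g[3] for g in genes}
    for src_id, cds in reversed(itr_records):
        gid = f"{src_id}_itr"
        strand = "-" if src_strand[src_id] == "+" else "+"
        text = cds if strand == "+" else revcomp(cds)
        genes.append((gid, pos + 1, pos + len(cds), strand))
        parts.append(text)
        pos += len(cds)
        itr_pairs.append((src_id, gid))
        pad()
    sequence = "".join(parts)
    genes.sort(key=lambda g: g[1])
    records = [GeneRecord(gid, s, e, st, rank=i + 1)
               for i, (gid, s, e, st) in enumerate(genes)]
    genome = GenomeAnnotation("virus", sequence, records, sorted(itr_pairs))
    genome.validate()
    return genome


def _edit(sequence: str, pos0: int, replacement: str) -> str:
    return sequence[:pos0] + replacement + sequence[pos0 + len(replacement):]


def assign_truth(genome: GenomeAnnotation, config: SimConfig,
                 seed: int = 0) -> TruthSet:
    """Plant temporal profiles, cleavage sites and introns; edits the genome.

    Every gene gets one cleavage site downstream of its stop codon; a
    ``tgtaa_fraction`` share of sites carries TGTAA with its first base at
    position -17 relative to the CS (-1 = last templated base). The two
    genomic bases immediately past each CS are forced non-A so the planted
    position is identifiable at base resolution. Intron donor GT / acceptor
    AG dinucleotides are written into the genome at codon boundaries, with
    the protein-level consequence fixed by construction. All edits to ITR
    genes' flanks fall outside the duplicated spans, so the repeats stay
    byte-identical.
    """
    if config.intron_len_range[1] >= config.max_intron:
        raise ValueError("configured intron length exceeds max_intron")
    rng = np.random.default_rng(seed)
    itr_ids = {g for pair in genome.itr_pairs for g in pair}
    copy_of = {b: a for a, b in genome.itr_pairs}
    tp_labels = [t.label for t in config.timepoints]

    # --- temporal profiles -------------------------------------------------
    names = list(ARCHETYPES)
    arch_of: dict[str, str] = {}
    rows: dict[str, np.ndarray] = {}
    k = 0
    for g in genome.genes:
        if g.gene_id in copy_of:
            continue
        arch = names[k % len(names)]
        k += 1
        amp = float(np.exp(rng.normal(0.0, config.amplitude_sigma))) * 100.0
        prof = np.concatenate([[0.0], np.asarray(ARCHETYPES[arch]) * amp])
        arch_of[g.gene_id] = arch
        rows[g.gene_id] = prof
    for cp, src in copy_of.items():
        arch_of[cp] = arch_of[src]         # ITR copies share the program
        rows[cp] = rows[src]
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=tp_labels)
    profiles = profiles.loc[[g.gene_id for g in genome.genes]]
    profiles.index.name = "gene_id"

    # --- cleavage sites ----------------------------------------------------
    sites: list[TrueCleavageSite] = []
    seq = genome.sequence
    n = len(seq)
    for g in genome.genes:
        off = int(rng.integers(*config.cs_offset_range))
        has_tgtaa = bool(rng.random() < config.tgtaa_fraction)
        if g.strand == "+":
            cs = min(g.end + off, n - 2)
            seq = _edit(seq, cs, "CT")                    # bases +1,+2 non-A
            if has_tgtaa:
                seq = _edit(seq, cs - 17, "TGTAA")        # first base at -17
        else:
            cs = max(g.start - off, 3)
            seq = _edit(seq, cs - 3, revcomp("CT"))
            if has_tgtaa:
                seq = _edit(seq, cs + 11, revcomp("TGTAA"))
        sites.append(TrueCleavageSite(g.gene_id, cs, g.strand, has_tgtaa))

    # --- introns -----------------------------------------------------------
    introns: list[TrueIntron] = []
    i_min, i_max = config.intron_len_range
    candidates = [g for g in genome.genes
                  if g.gene_id not in itr_ids and g.length >= i_min + 250]
    idxs = rng.choice(len(candidates),
                      size=min(config.n_intron_genes, len(candidates)),
                      replace=False)
    consequences = ["frameshift", "in_frame_deletion", "premature_stop"]
    for j, ci in enumerate(sorted(int(x) for x in idxs)):
        g = candidates[ci]
        want = consequences[j % 3]
        ilen = int(rng.integers(i_min, min(i_max, g.length - 250) + 1))
        if want == "frameshift":
            if ilen % 3 == 0:
                ilen += 1
        else:
            ilen -= ilen % 3
        hi = (g.length - ilen) // 3 - 20
        codon_off = int(rng.integers(20, hi)) * 3       # donor at codon boundary
        freq = float(rng.uniform(*config.splicing_frac_range))
        if g.strand == "+":
            i_start = g.start + codon_off               # first intronic base
            i_end = i_start + ilen - 1
            seq = _edit(seq, i_start - 1, "GT")
            seq = _edit(seq, i_end - 2, "AG")
            if want == "premature_stop":
                # first exon2 codon becomes an in-frame stop after splicing
                seq = _edit(seq, i_end, "TAA")
        else:
            i_end = g.end - codon_off                   # donor side for '-'
            i_start = i_end - ilen + 1
            seq = _edit(seq, i_end - 2, revcomp("GT"))
            seq = _edit(seq, i_start - 1, revcomp("AG"))
            if want == "premature_stop":
                seq = _edit(seq, i_start - 4, revcomp("TAA"))
        introns.append(TrueIntron(g.gene_id, i_start, i_end, "GT-AG",
                                  g.strand, freq, want))

    genome.sequence = seq
    genome.validate()

    vf = dict(zip(tp_labels, config.viral_fraction))
    if vf.get("T0", 0.0) != 0.0:
        raise ValueError("viral fraction at T0 must be 0 (no viral RNA pre-infection)")
    depth = {t: int(config.base_depth * m)
             for t, m in zip(tp_labels, config.depth_multiplier)}
    return TruthSet(profiles, arch_of, sites, introns, config.readthrough_prob,
                    vf, depth, config.error_rate, seed)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _gene_variants(genome: GenomeAnnotation, truth: TruthSet,
                   ) -> dict[str, list[tuple[float, list[tuple[int, int]],
                                             bool, bool]]]:
    """Per gene: (weight, genomic blocks left-to-right, is_spliced, tailed).

    Read-through variants extend the transcript through the downstream
    neighbour but are emitted without tail-overlapping fragments: a
    read-through molecule terminates at a downstream cleavage site, not at
    a site of its own, so it must not plant spurious poly(A) evidence.
    """
    cs_by_gene = truth.cs_by_gene()
    intron_by_gene = truth.introns_by_gene()
    order = genome.genes
    rt = truth.readthrough_prob
    out: dict[str, list[tuple[float, list[tuple[int, int]], bool, bool]]] = {}
    for idx, g in enumerate(order):
        cs = cs_by_gene[g.gene_id]
        span = (g.start, cs.position) if g.strand == "+" else (cs.position, g.end)
        intron = intron_by_gene.get(g.gene_id)
        base: list[tuple[float, list[tuple[int, int]], bool]] = []
        if intron:
            spliced = [(span[0], intron.intron_start - 1),
                       (intron.intron_end + 1, span[1])]
            base.append((intron.frequency, spliced, True))
            base.append((1.0 - intron.frequency, [span], False))
        else:
            base.append((1.0, [span], False))
        nxt = None
        if g.strand == "+" and idx + 1 < len(order):
            nxt = order[idx + 1]
        elif g.strand == "-" and idx > 0:
            nxt = order[idx - 1]
        v: list[tuple[float, list[tuple[int, int]], bool, bool]] = []
        for w, blocks, spl in base:
            if nxt is not None and rt > 0:
                if g.strand == "+":
                    ext = blocks[:-1] + [(blocks[-1][0],
                                          max(blocks[-1][1], nxt.end + 20))]
                else:
                    ext = [(min(blocks[0][0], max(1, nxt.start - 20)),
                            blocks[0][1])] + blocks[1:]
                v.append((w * (1 - rt), blocks, spl, True))
                v.append((w * rt, ext, spl, False))
            else:
                v.append((w, blocks, spl, True))
        out[g.gene_id] = v
    return out


def simulate_reads(genome: GenomeAnnotation, truth: TruthSet,
                   config: SimConfig, seed: int = 0,
                   host_seq: str | None = None,
                   ) -> tuple[dict[str, SimulatedReadSet], str]:
    """Emit per-timepoint read sets; returns (readsets, host sequence).

    Reads are sampled uniformly along transcripts (spliced variants omit the
    intron; every transcript carries a poly(A) tail of uniform random length
    after its cleavage site; read-through variants extend into the
    downstream neighbour). Half the reads are emitted reverse complemented;
    substitution errors are i.i.d. per base. Host reads come from a random
    decoy sequence so library size and composition vary by timepoint.
    """
    if not 0 <= config.error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    if host_seq is None:
        host_seq = _random_seq(np.random.default_rng(seed + 7919), config.host_len)
    L = config.read_len
    genes = {g.gene_id: g for g in genome.genes}
    intron_by_gene = truth.introns_by_gene()
    variants = _gene_variants(genome, truth)

    # cache rendered transcripts: oriented text + per-base genomic coordinates
    render_cache: dict[tuple[str, int], tuple[str, np.ndarray]] = {}

    def render(gid: str, vi: int) -> tuple[str, np.ndarray]:
        key = (gid, vi)
        if key not in render_cache:
            blocks = variants[gid][vi][1]
            txt = "".join(genome.subseq(s, e) for s, e in blocks)
            pos = np.concatenate([np.arange(s, e + 1) for s, e in blocks])
            if genes[gid].strand == "-":
                txt = revcomp(txt)
                pos = pos[::-1]
            render_cache[key] = (txt, pos)
        return render_cache[key]

    tp_labels = list(truth.profiles.columns)
    gene_ids = list(truth.profiles.index)
    abund = truth.profiles.to_numpy(dtype=float)
    out: dict[str, SimulatedReadSet] = {}

    for ti, tp in enumerate(tp_labels):
        rs = SimulatedReadSet(tp)
        depth = truth.depth[tp]
        n_viral = int(round(depth * truth.viral_fraction[tp]))
        n_host = depth - n_viral
        starts = rng.integers(0, len(host_seq) - L + 1, size=n_host)
        flips = rng.random(n_host) < 0.5
        for s0, flip in zip(starts, flips):
            seq = host_seq[s0:s0 + L]
            if flip:
                seq = revcomp(seq)
            seq = _apply_errors(seq, rng, truth.error_rate)
            rs.reads.append(SimRead(seq, "host", "host", int(s0) + 1, int(s0) + L))
        w = abund[:, ti]
        counts = (rng.multinomial(n_viral, w / w.sum())
                  if w.sum() > 0 and n_viral > 0
                  else np.zeros(len(gene_ids), dtype=int))
        for gi, cnt in enumerate(counts):
            if cnt == 0:
                continue
            gid = gene_ids[gi]
            vlist = variants[gid]
            weights = np.array([v[0] for v in vlist])
            picks = rng.choice(len(vlist), size=cnt, p=weights / weights.sum())
            for vi in picks:
                txt, gpos = render(gid, int(vi))
                tailed = variants[gid][vi][3]
                tail = int(rng.integers(*config.tail_len_range)) if tailed else 0
                tlen = len(txt)
                start = int(rng.integers(0, tlen + tail - L + 1))
                frag = (txt + "A" * tail)[start:start + L]
                n_tail = max(0, start + L - tlen)
                tmpl = L - n_tail
                origin, g_start, g_end = gid, 0, 0
                if tmpl > 0:
                    covered = gpos[start:start + tmpl]
                    g_start, g_end = int(covered.min()), int(covered.max())
                if n_tail >= 1:
                    origin = f"tail:{gid}"
                elif variants[gid][vi][2]:
                    intr = intron_by_gene[gid]
                    if g_start < intr.intron_start and g_end > intr.intron_end:
                        origin = f"junction:{gid}"
                seq = _apply_errors(frag, rng, truth.error_rate)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                rs.reads.append(SimRead(seq, origin, "virus",
                                        g_start, g_end, n_tail))
        assert len(rs.reads) == depth
        out[tp] = rs
    return out, host_seq


# ---------------------------------------------------------------------------
# Convenience wrappers
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig | None = None, seed: int = 0,
                        ) -> tuple[GenomeAnnotation, TruthSet,
                                   dict[str, SimulatedReadSet], str]:
    """Generate genome, truth and reads in one deterministic call."""
    config = config or SimConfig()
    genome = generate_genome(config.n_genes, config.mean_gene_len,
                             config.genome_pad, config.itr_genes, seed)
    truth = assign_truth(genome, config, seed + 1)
    readsets, host_seq = simulate_reads(genome, truth, config, seed + 2)
    return genome, truth, readsets, host_seq


def write_experiment(outdir: str | Path, genome: GenomeAnnotation,
                     truth: TruthSet, readsets: dict[str, SimulatedReadSet],
                     host_seq: str, config: SimConfig | None = None) -> None:
    """Write FASTA/GFF3/FASTQ plus truth tables and a sample manifest."""
    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({genome.genome_id: genome.sequence}, outdir / "genome.fasta")
    write_fasta({"host": host_seq}, outdir / "host.fasta")
    write_gff3(genome, outdir / "genes.gff3")
    minutes = {t.label: t.minutes_pi for t in config.timepoints}
    rows = []
    for tp, rs in readsets.items():
        path = outdir / f"reads_{tp}.fastq"
        write_fastq(((f"{tp}_{i}", r.sequence) for i, r in enumerate(rs.reads)),
                    path)
        rows.append({"sample": tp, "timepoint": tp,
                     "minutes": minutes.get(tp, 0), "fastq_path": str(path)})
    write_manifest(rows, outdir / "manifest.tsv")
    truth.profiles.to_csv(outdir / "truth_profiles.tsv", sep="\t")
    pd.DataFrame([vars(c) for c in truth.cleavage_sites]).to_csv(
        outdir / "truth_cs.tsv", sep="\t", index=False)
    pd.DataFrame([vars(i) for i in truth.introns]).to_csv(
        outdir / "truth_junctions.tsv", sep="\t", index=False)
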