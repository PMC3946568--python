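"""Poly(A) cleavage-site detection and signal-motif statistics.

Cleavage sites (CS) are inferred from reads that fail full-length mapping
because one extremity is a non-templated poly(A) (or, on the opposite
orientation, poly(T)) tract: the aligned anchor's last templated base is
the CS. Sites validated by at least two independent read species are kept.

Motif statistics around validated sites: per-position nucleotide frequency
profiles (smoothed over 5 neighbouring positions), overlapping pentamer
counts in the 50 nt upstream windows against a per-sequence mononucleotide
shuffle null ("Z-score test"), and positional histograms of a chosen word.

Position convention: -1 is the last templated base (the CS itself); +1 is
the first base past the CS; there is no position 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formats import GenomeAnnotation, ReadSpecies, revcomp
from .mapping import ReferenceIndex

__all__ = [
    "TailEvidence",
    "CleavageSite",
    "EnrichmentResult",
    "find_tail_reads",
    "call_cleavage_sites",
    "upstream_sequences",
    "nucleotide_profile",
    "pentamer_enrichment",
    "motif_positional_distribution",
    "window_positions",
]


@dataclass
class TailEvidence:
    species: ReadSpecies
    position: int            # 1-based genome coordinate of last templated base
    strand: str
    anchor_len: int
    tail_len: int


@dataclass
class CleavageSite:
    position: int
    strand: str
    n_species: int
    n_reads: int
    nearest_gene: str | None = None


@dataclass
class EnrichmentResult:
    word: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_shuffles: int
    seed: int


def _purity(seq: str, base: str) -> float:
    return seq.count(base) / len(seq) if seq else 0.0


def find_tail_reads(unmapped: Sequence[ReadSpecies],
                    genome: GenomeAnnotation | str,
                    anchor_min: int = 20, tail_min: int = 5,
                    tail_purity: float = 0.9, anchor_mm: int = 0,
                    ) -> list[TailEvidence]:
    """Rescue species with one aligned extremity and a poly(A)/(T) tract.

    Both orientations of each species are screened for a 3'-terminal A-rich
    remainder after the longest uniquely mapping anchor prefix (length >=
    ``anchor_min``); a poly(T) tract on the 5' side is the same pattern on
    the reverse complement. The CS is the anchor base adjacent to the tail;
    the strand follows from the anchor's genomic orientation: a forward
    anchor before a poly(A) remainder means a + strand transcript, a
    reverse-complement anchor means the transcript runs - on the genome.

    Anchors align exactly by default (``anchor_mm=0``): allowing anchor
    mismatches lets the anchor absorb the first tail bases wherever the
    genome continues A-rich, systematically shifting the called position
    downstream, so the last *matching* nucleotide is only well defined for
    exact anchors.
    """
    seq = genome.sequence if isinstance(genome, GenomeAnnotation) else genome
    index = ReferenceIndex("genome", seq)
    out: list[TailEvidence] = []
    for sp in unmapped:
        seen: set[tuple[int, str]] = set()
        for oriented in (sp.canonical, revcomp(sp.canonical)):
            L = len(oriented)
            for alen in range(L - tail_min, anchor_min - 1, -1):
                remainder = oriented[alen:]
                # the clipped tract must look like a tail from its first base;
                # without this, a sequencing error at the last templated base
                # spawns an off-by-one phantom site
                if remainder[0] != "A" or _purity(remainder, "A") < tail_purity:
                    continue
                anchor = oriented[:alen]
                fwd = index.hits(anchor, anchor_mm)
                rev = index.hits(revcomp(anchor), anchor_mm)
                if len(fwd) + len(rev) != 1:
                    continue
                if fwd:
                    pos0 = fwd[0][0]
                    cs, strand = pos0 + alen, "+"        # last anchor base
                else:
                    pos0 = rev[0][0]
                    cs, strand = pos0 + 1, "-"
                if (cs, strand) not in seen:
                    seen.add((cs, strand))
                    out.append(TailEvidence(sp, cs, strand, alen, L - alen))
                break
    return out


def call_cleavage_sites(evidence: Sequence[TailEvidence],
                        min_species: int = 2, merge_radius: int = 0,
                        genome: GenomeAnnotation | None = None,
                        ) -> list[CleavageSite]:
    """Group tail evidence by (position, strand); validate by species count.

    "Independent reads" means distinct read species — duplicates of one
    species never validate a site. With ``merge_radius`` > 0 nearby
    positions on the same strand are pooled onto the best-supported one.
    """
    groups: dict[tuple[int, str], list[TailEvidence]] = {}
    for ev in evidence:
        groups.setdefault((ev.position, ev.strand), []).append(ev)
    if merge_radius > 0:
        merged: dict[tuple[int, str], list[TailEvidence]] = {}
        for strand in ("+", "-"):
            keys = sorted(k for k in groups if k[1] == strand)
            cluster: list[tuple[int, str]] = []
            for key in keys + [(None, None)]:
                if cluster and (key[0] is None
                                or key[0] - cluster[-1][0] > merge_radius):
                    rep = max(cluster, key=lambda c: (len(groups[c]), -c[0]))
                    merged[rep] = [e for c in cluster for e in groups[c]]
                    cluster = []
                if key[0] is not None:
                    cluster.append(key)
        groups = merged
    sites = []
    for (pos, strand), evs in sorted(groups.items()):
        n_species = len({e.species.canonical for e in evs})
        if n_species < min_species:
            continue
        n_reads = sum(sp.total for sp in
                      {e.species.canonical: e.species for e in evs}.values())
        sites.append(CleavageSite(pos, strand, n_species, n_reads,
                                  _nearest_gene(pos, strand, genome)))
    return sites


def _nearest_gene(pos: int, strand: str,
                  genome: GenomeAnnotation | None) -> str | None:
    """Same-strand gene whose 3' end is closest upstream of the site."""
    if genome is None:
        return None
    best: tuple[int, str] | None = None
    for g in genome.genes:
        if g.strand != strand:
            continue
        d = pos - g.end if strand == "+" else g.start - pos
        if d >= 0 and (best is None or d < best[0]):
            best = (d, g.gene_id)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Sequence windows around sites
# ---------------------------------------------------------------------------

def window_positions(window: tuple[int, int]) -> list[int]:
    """Relative positions covered by a window; no position 0 exists."""
    lo, hi = window
    return [p for p in range(lo, hi + 1) if p != 0]


def upstream_sequences(sites: Sequence[CleavageSite],
                       genome: GenomeAnnotation,
                       window: tuple[int, int] = (-100, -1),
                       ) -> list[tuple[CleavageSite, str, bool]]:
    """Strand-oriented sequence around each site; returns (site, seq, truncated).

    Sequences read 5'->3' on the transcript strand; truncated windows at the
    genome edge are padded with N (and flagged) so positions stay aligned.
    """
    n = len(genome)
    out = []
    positions = window_positions(window)
    for site in sites:
        chars = []
        truncated = False
        for r in positions:
            if site.strand == "+":
                g = site.position + r + (1 if r < 0 else 0)
            else:
                g = site.position - r - (1 if r < 0 else 0)
            if 1 <= g <= n:
                base = genome.sequence[g - 1]
                chars.append(base if site.strand == "+" else revcomp(base))
            else:
                chars.append("N")
                truncated = True
        out.append((site, "".join(chars), truncated))
    return out


def nucleotide_profile(seqs: Sequence[str], window: tuple[int, int] = (-100, -1),
                       smooth: int = 5) -> pd.DataFrame:
    """Per-position A/C/G/T frequencies across sequences, smoothed.

    Raw frequencies at each position sum to 1 over the sequences with a
    defined (non-N) base there; smoothing averages each position with its
    <= ``smooth`` neighbours (window clipped at the edges).
    """
    if not seqs:
        raise ValueError("no sequences")
    positions = window_positions(window)
    width = len(positions)
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences do not match the window width")
    arr = np.array([list(s) for s in seqs])
    freq = np.zeros((width, 4))
    for j, b in enumerate("ACGT"):
        freq[:, j] = (arr == b).sum(axis=0)
    denom = freq.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    freq = freq / denom
    half = smooth // 2
    sm = np.empty_like(freq)
    for i in range(width):
        lo, hi = max(0, i - half), min(width, i + half + 1)
        sm[i] = freq[lo:hi].mean(axis=0)
    df = pd.DataFrame(sm, columns=list("ACGT"))
    df.insert(0, "position", positions)
    raw = pd.DataFrame(freq, columns=[f"raw_{b}" for b in "ACGT"])
    return pd.concat([df, raw], axis=1)


# ---------------------------------------------------------------------------
# Pentamer enrichment with a shuffled-sequence null
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_counts(rows: np.ndarray, k: int, n_words: int) -> np.ndarray:
    """Count overlapping k-mers over encoded rows (-1 = undefined base)."""
    n, width = rows.shape
    codes = np.zeros((n, width - k + 1), dtype=np.int64)
    valid = np.ones((n, width - k + 1), dtype=bool)
    for j in range(k):
        part = rows[:, j:j + width - k + 1]
        codes = codes * 4 + np.where(part < 0, 0, part)
        valid &= part >= 0
    return np.bincount(codes[valid].ravel(), minlength=n_words)


def pentamer_enrichment(seqs: Sequence[str], n_shuffles: int = 1000,
                        seed: int = 0, k: int = 5) -> pd.DataFrame:
    """Overlapping k-mer counts vs a per-sequence mononucleotide-shuffle null.

    Each shuffle replicate independently permutes the bases within every
    sequence (exactly preserving its composition), recounts all k-mers, and
    the observed count is scored as z = (obs - null mean) / null sd with an
    upper-tail normal p ("Z-score test"). Results are ranked by z.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if any(len(s) < k for s in seqs):
        raise ValueError(f"all sequences must be at least {k} nt")
    width = max(len(s) for s in seqs)
    rows = np.full((len(seqs), width), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        rows[i, :len(s)] = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    n_words = 4 ** k
    observed = _kmer_counts(rows, k, n_words)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, n_words), dtype=np.int64)
    for r in range(n_shuffles):
        keys = rng.random(rows.shape)
        keys[rows < 0] = np.inf              # keep padding at the row tail
        perm = np.take_along_axis(rows, np.argsort(keys, axis=1), axis=1)
        null[r] = _kmer_counts(perm, k, n_words)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    z = np.where(null_sd > 0, z,
                 np.where(observed > null_mean, np.inf,
                          np.where(observed < null_mean, -np.inf, 0.0)))
    p = norm.sf(z)
    words = ["".join("ACGT"[(c >> (2 * (k - 1 - j))) & 3] for j in range(k))
             for c in range(n_words)]
    df = pd.DataFrame({"word": words, "observed": observed,
                       "null_mean": null_mean, "null_sd": null_sd,
                       "z": z, "p": p})
    df["n_shuffles"] = n_shuffles
    df["seed"] = seed
    return df.sort_values(["z", "observed"], ascending=False,
                          kind="mergesort").reset_index(drop=True)


def motif_positional_distribution(seqs: Sequence[str], word: str,
                                  window: tuple[int, int] = (-100, -1),
                                  ) -> pd.DataFrame:
    """Histogram of word occurrences indexed by the word's first base.

    Positions follow the window convention (-1 = CS; no 0). Overlapping
    occurrences all count.
    """
    positions = window_positions(window)
    counts = {p: 0 for p in positions}
    wlen = len(word)
    for s in seqs:
        for i in range(len(s) - wlen + 1):
            if s[i:i + wlen] == word:
                counts[positions[i]] += 1
    return pd.DataFrame({"position": positions,
                         "count": [counts[p] for p in positions]})
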