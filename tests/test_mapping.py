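import numpy as np
import pytest

from earlyburst.formats import GenomeAnnotation, dedupe_to_species, revcomp
from earlyburst.mapping import (brute_force_hits, build_junction_library,
                                find_split_hits, map_unique, resolve_itr)
from earlyburst.simulate import generate_genome

from conftest import random_dna


def species_of(*seqs, tp="T7"):
    return dedupe_to_species([(s, tp) for s in seqs])


class TestMapUnique:
    def test_exact_read_aligns(self, toy_genome):
        read = toy_genome.subseq(100, 149)
        (sp,) = species_of(read)
        aln, amb, un = map_unique([sp], toy_genome)
        assert len(aln) == 1 and not amb and not un
        assert aln[0].start == 100 and aln[0].mismatches == 0
        assert aln[0].blocks == ((100, 149),)

    def test_revcomp_read_aligns_to_same_locus(self, toy_genome):
        read = revcomp(toy_genome.subseq(100, 149))
        (sp,) = species_of(read)
        aln, _, _ = map_unique([sp], toy_genome)
        assert len(aln) == 1 and aln[0].start == 100

    def test_two_mismatches_accepted_three_rejected(self, toy_genome):
        read = list(toy_genome.subseq(200, 249))
        for i in (5, 20):
            read[i] = "A" if read[i] != "A" else "C"
        aln, _, un = map_unique(species_of("".join(read)), toy_genome)
        assert len(aln) == 1 and aln[0].mismatches == 2
        read[40] = "A" if read[40] != "A" else "C"
        aln, _, un = map_unique(species_of("".join(read)), toy_genome)
        assert not aln and len(un) == 1

    def test_multi_locus_read_discarded(self, toy_genome):
        dup = toy_genome.subseq(300, 349)
        genome2 = GenomeAnnotation("v", toy_genome.sequence + "TTTT" + dup,
                                   toy_genome.genes)
        aln, amb, un = map_unique(species_of(dup), genome2)
        assert not aln and not un and len(amb) == 1   # exactly-2 hits reported

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            map_unique([], {"v": ""})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_brute_force(self, seed):
        """Seed-and-verify alignment equals a full positional scan."""
        rng = np.random.default_rng(seed)
        genome = GenomeAnnotation("v", random_dna(rng, 3000))
        reads = []
        for _ in range(120):
            start = int(rng.integers(0, 2950))
            read = list(genome.sequence[start:start + 50])
            for i in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
                read[i] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        species = dedupe_to_species([(r, "T7") for r in reads])
        aln, amb, un = map_unique(species, genome)
        by_unique = {a.species.canonical: a for a in aln}
        for sp in species:
            expected = {}
            for q in (sp.canonical, revcomp(sp.canonical)):
                for pos, mm in brute_force_hits(q, genome.sequence, 2):
                    if pos not in expected or mm < expected[pos]:
                        expected[pos] = mm
            if len(expected) == 1:
                ((pos, mm),) = expected.items()
                a = by_unique[sp.canonical]
                assert (a.start - 1, a.mismatches) == (pos, mm)
            else:
                assert sp.canonical not in by_unique
                if not expected:
                    assert sp in un

    def test_emitted_alignments_hamming_consistent(self, small_experiment):
        genome = small_experiment["genome"]
        host = small_experiment["host"]
        refs = {"virus": genome.sequence, "host": host}
        for a in small_experiment["alignments"][:2000]:
            assert a.mismatches <= 2
            ref = refs[a.target]
            rebuilt = "".join(ref[s - 1:e] for s, e in a.blocks)
            q = a.species.canonical
            if a.orientation == "revcomp":
                q = revcomp(q)
            assert sum(x != y for x, y in zip(q, rebuilt)) == a.mismatches


class TestResolveItr:
    def test_itr_double_hits_weighted_half(self):
        genome = generate_genome(n_genes=6, itr_genes=1, seed=11)
        (src, cp) = genome.itr_pairs[0]
        g = genome.gene(src)
        read = genome.subseq(g.start + 3, g.start + 52)
        species = dedupe_to_species([(read, "T7")] * 100)
        aln, amb, un = map_unique(species, genome)
        assert not aln and len(amb) == 1
        resolved = resolve_itr(amb, genome)
        assert len(resolved) == 2
        assert all(r.weight == 0.5 for r in resolved)
        total = sum(r.weight * r.species.total for r in resolved)
        assert total == 100                      # weight conservation

    def test_non_itr_double_hits_stay_discarded(self, toy_genome):
        dup = toy_genome.subseq(600, 649)
        genome2 = GenomeAnnotation("v", toy_genome.sequence + "GGGG" + dup,
                                   toy_genome.genes)
        _, amb, _ = map_unique(species_of(dup), genome2)
        assert resolve_itr(amb, genome2) == []


class TestSplitHits:
    def test_constructed_split_read(self, toy_genome):
        read = toy_genome.subseq(100, 124) + toy_genome.subseq(300, 324)
        (sp,) = species_of(read)
        hits = find_split_hits([sp], toy_genome)
        assert len(hits) == 1
        h = hits[0]
        assert h.seg1 == (100, 124) and h.seg2 == (300, 324)
        assert h.gap == 175 and h.intron == (125, 299)

    def test_far_segments_rejected(self, toy_genome):
        read = toy_genome.subseq(100, 124) + toy_genome.subseq(2600, 2624)
        hits = find_split_hits(species_of(read), toy_genome, max_gap=2000)
        assert hits == []

    def test_min_anchor_enforced(self, toy_genome):
        with pytest.raises(ValueError):
            find_split_hits([], toy_genome, min_anchor=4)

    def test_split_orientation_revcomp(self, toy_genome):
        read = revcomp(toy_genome.subseq(100, 124) + toy_genome.subseq(300, 324))
        hits = find_split_hits(species_of(read), toy_genome)
        assert len(hits) == 1 and hits[0].intron == (125, 299)


class TestJunctionLibrary:
    def test_contig_arithmetic(self, toy_genome):
        (contig,) = build_junction_library([(101, 200)], toy_genome, flank=49)
        assert len(contig.sequence) == 98
        assert contig.sequence == (toy_genome.subseq(52, 100)
                                   + toy_genome.subseq(201, 249))
        assert contig.flank_left == 49 and not contig.truncated

    def test_edge_contig_truncated_and_flagged(self, toy_genome):
        (contig,) = build_junction_library([(20, 200)], toy_genome, flank=49)
        assert contig.truncated and contig.flank_left == 19

    def test_seam_straddling_read_gets_two_blocks(self, toy_genome):
        library = build_junction_library([(1000, 1199)], toy_genome, flank=49)
        read = toy_genome.subseq(970, 999) + toy_genome.subseq(1200, 1219)
        aln, _, _ = map_unique(species_of(read), toy_genome, library)
        assert len(aln) == 1
        assert aln[0].blocks == ((970, 999), (1200, 1219))

    def test_read_within_one_flank_not_counted_as_junction(self, toy_genome):
        library = build_junction_library([(1000, 1199)], toy_genome, flank=49)
        read = toy_genome.subseq(951, 999)       # entirely in the left flank
        aln, _, _ = map_unique(species_of(read), toy_genome, library)
        assert len(aln) == 1 and len(aln[0].blocks) == 1   # genomic hit only

    def test_true_origin_recovery_on_simulated_reads(self, small_experiment):
        """Error-free unique gene reads map back to their true coordinates."""
        genome = small_experiment["genome"]
        truth = small_experiment["truth"]
        itr_genes = {g for pair in genome.itr_pairs for g in pair}
        by_species = {}
        for a in small_experiment["alignments"]:
            by_species.setdefault(a.species.canonical, []).append(a)
        from earlyburst.formats import canonical_sequence

        total = correct = 0
        for rs in small_experiment["readsets"].values():
            for r in rs.reads:
                if r.chrom != "virus" or r.origin.split(":")[0] != r.origin:
                    continue                      # skip tail/junction reads
                if r.origin in itr_genes:
                    continue
                total += 1
                alns = by_species.get(canonical_sequence(r.sequence), [])
                if any(a.start == r.start and a.end == r.end for a in alns):
                    correct += 1
        assert total > 2000
        assert correct / total >= 0.99
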