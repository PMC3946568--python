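import itertools

import numpy as np
import pytest

from earlyburst.formats import dedupe_to_species, revcomp
from earlyburst.polya import (CleavageSite, call_cleavage_sites,
                              find_tail_reads, motif_positional_distribution,
                              nucleotide_profile, pentamer_enrichment,
                              upstream_sequences, window_positions)


def species_of(*seqs, tp="T7"):
    return dedupe_to_species([(s, tp) for s in seqs])


class TestFindTailReads:
    def test_forward_anchor_polya(self, toy_genome):
        read = toy_genome.subseq(1000, 1039) + "A" * 10
        (ev,) = find_tail_reads(species_of(read), toy_genome)
        assert (ev.position, ev.strand) == (1039, "+")
        assert ev.anchor_len == 40 and ev.tail_len == 10

    def test_polyt_prefix_minus_strand(self, toy_genome):
        read = "T" * 10 + toy_genome.subseq(2000, 2039)
        (ev,) = find_tail_reads(species_of(read), toy_genome)
        assert (ev.position, ev.strand) == (2000, "-")

    def test_polya_after_revcomp_anchor(self, toy_genome):
        read = revcomp(toy_genome.subseq(2000, 2039)) + "A" * 10
        (ev,) = find_tail_reads(species_of(read), toy_genome)
        assert (ev.position, ev.strand) == (2000, "-")

    def test_low_purity_remainder_rejected(self, toy_genome):
        read = toy_genome.subseq(1000, 1041) + "AATATAAT"
        assert find_tail_reads(species_of(read), toy_genome) == []

    def test_short_anchor_rejected(self, toy_genome):
        read = toy_genome.subseq(1000, 1014) + "A" * 35
        assert find_tail_reads(species_of(read), toy_genome,
                               anchor_min=20) == []

    def test_nonunique_anchor_rejected(self, toy_genome):
        from earlyburst.formats import GenomeAnnotation

        dup = toy_genome.subseq(1000, 1039)
        genome2 = GenomeAnnotation("v", toy_genome.sequence + "CCCC" + dup)
        read = dup + "A" * 10
        assert find_tail_reads(species_of(read), genome2) == []


class TestCallSites:
    def _ev(self, genome, n_species, pos=1000):
        reads = [genome.subseq(pos - 39 - i, pos) + "A" * (10 + i)
                 for i in range(n_species)]
        return find_tail_reads(species_of(*reads), genome)

    def test_two_species_validate(self, toy_genome):
        sites = call_cleavage_sites(self._ev(toy_genome, 2))
        assert len(sites) == 1
        assert (sites[0].position, sites[0].n_species) == (1000, 2)

    def test_duplicates_of_one_species_do_not_validate(self, toy_genome):
        read = toy_genome.subseq(961, 1000) + "A" * 10
        ev = find_tail_reads(dedupe_to_species([(read, "T7")] * 10), toy_genome)
        assert ev[0].species.total == 10
        assert call_cleavage_sites(ev, min_species=2) == []

    def test_adjacent_positions_not_pooled_by_default(self, toy_genome):
        ev = self._ev(toy_genome, 1, pos=1000) + self._ev(toy_genome, 1, pos=1001)
        assert call_cleavage_sites(ev, min_species=2) == []

    def test_merge_radius_pools_neighbours(self):
        from earlyburst.polya import TailEvidence

        def ev_at(pos, *seqs):
            return [TailEvidence(sp, pos, "+", 40, 10)
                    for sp in species_of(*seqs)]

        ev = (ev_at(1000, "AC" * 25, "AG" * 25) + ev_at(1001, "AT" * 25))
        (site,) = call_cleavage_sites(ev, min_species=2, merge_radius=1)
        assert site.position == 1000 and site.n_species == 3
        assert call_cleavage_sites(ev, min_species=3, merge_radius=0) == []


class TestWindows:
    def test_plus_strand_window(self, toy_genome):
        site = CleavageSite(1039, "+", 2, 2)
        ((_, seq, trunc),) = upstream_sequences([site], toy_genome, (-5, -1))
        assert seq == toy_genome.subseq(1035, 1039) and not trunc

    def test_minus_strand_window(self, toy_genome):
        site = CleavageSite(2000, "-", 2, 2)
        ((_, seq, _),) = upstream_sequences([site], toy_genome, (-5, -1))
        assert seq == revcomp(toy_genome.subseq(2000, 2004))

    def test_edge_window_truncated_flagged(self, toy_genome):
        site = CleavageSite(3, "+", 2, 2)
        ((_, seq, trunc),) = upstream_sequences([site], toy_genome, (-5, -1))
        assert trunc and seq.startswith("NN")

    def test_window_positions_skip_zero(self):
        assert window_positions((-3, 2)) == [-3, -2, -1, 1, 2]


class TestProfile:
    def test_uniform_sequences_idempotent_smoothing(self):
        df = nucleotide_profile(["AAAAA"] * 4, window=(-5, -1))
        assert np.allclose(df["A"], 1.0) and np.allclose(df["raw_A"], 1.0)

    def test_raw_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(20)]
        df = nucleotide_profile(seqs, window=(-10, -1))
        sums = df[[f"raw_{b}" for b in "ACGT"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_planted_motif_creates_local_excursion(self):
        rng = np.random.default_rng(5)
        seqs = []
        for i in range(40):
            s = list("".join(rng.choice(list("ACGT"), 50)))
            if i < 28:                        # 70% of sites
                s[50 - 17:50 - 12] = "TGTAA"
            seqs.append("".join(s))
        df = nucleotide_profile(seqs, window=(-50, -1)).set_index("position")
        assert df.loc[-16, "raw_G"] > 0.6     # G of TGTAA at -16
        assert df.loc[-17, "raw_T"] > 0.6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_profile([], (-5, -1))


class TestEnrichment:
    def test_overlapping_homopolymer_count(self):
        df = pentamer_enrichment(["AAAAAAAAAA"], n_shuffles=5, seed=0)
        row = df[df.word == "AAAAA"].iloc[0]
        assert row.observed == 6

    def test_shuffle_preserves_composition(self):
        """Null counts only ever land on words writable from each sequence's
        own letters -- the mononucleotide multiset is preserved exactly."""
        df = pentamer_enrichment(["TGTAA"], n_shuffles=400, seed=1)
        support = df[df.null_mean > 0]
        allowed = {"".join(p) for p in itertools.permutations("TGTAA")}
        assert set(support.word) <= allowed
        assert support.null_mean.sum() == pytest.approx(1.0)   # one 5-mer/seq

    def test_tiny_case_matches_exhaustive_expectation(self):
        """Null mean agrees with the exact mean over all distinct shuffles."""
        seqs = ["ACGTACGT", "AATTGGCC", "TTTACGTA"]
        word = "ACGTA"
        exact = 0.0
        for s in seqs:
            perms = set(itertools.permutations(s))
            counts = [sum(1 for i in range(len(s) - 4)
                          if "".join(p[i:i + 5]) == word) for p in perms]
            exact += float(np.mean(counts))
        df = pentamer_enrichment(seqs, n_shuffles=3000, seed=2)
        row = df[df.word == word].iloc[0]
        se = row.null_sd / np.sqrt(row.n_shuffles)
        assert abs(row.null_mean - exact) < 3 * max(se, 1e-9)

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            pentamer_enrichment(["ACGTACGT"], n_shuffles=1)

    def test_deterministic_for_seed(self):
        seqs = ["ACGTACGTAC", "GGGTTTACCA"]
        a = pentamer_enrichment(seqs, n_shuffles=50, seed=9)
        b = pentamer_enrichment(seqs, n_shuffles=50, seed=9)
        assert a.equals(b)


class TestPositionalDistribution:
    def test_construction_at_minus_17(self):
        # window (-50,-1): string index 33 corresponds to position -17
        seq = "C" * 33 + "TGTAA" + "G" * 12
        df = motif_positional_distribution([seq], "TGTAA", (-50, -1))
        hit = df[df["count"] > 0]
        assert list(hit.position) == [-17] and int(hit["count"].iloc[0]) == 1

    def test_absent_word_all_zero(self):
        df = motif_positional_distribution(["C" * 50], "TGTAA", (-50, -1))
        assert (df["count"] == 0).all()

    def test_overlapping_occurrences_counted(self):
        df = motif_positional_distribution(["A" * 12], "AAAAA", (-12, -1))
        assert df["count"].sum() == 8
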