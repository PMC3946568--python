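import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earlyburst.expression import (CoverageTrack, build_coverage,
                                   expression_table, kmeans_profiles,
                                   library_totals, mrpn, scaling_factors,
                                   top_n)
from earlyburst.formats import (GeneRecord, GenomeAnnotation,
                                dedupe_to_species)
from earlyburst.mapping import AlignmentRecord
from earlyburst.simulate import ARCHETYPES


def _aln(seq, mult, blocks, weight=1.0, target="virus"):
    (sp,) = dedupe_to_species([(seq, tp) for tp, n in mult.items()
                               for _ in range(n)])
    return AlignmentRecord(sp, target, blocks[0][0], "forward", 0,
                           tuple(blocks), weight)


def _track(values, tp="T60", ref="virus"):
    arr = np.asarray(values, dtype=float)
    return CoverageTrack({tp: {ref: arr}})


class TestCoverage:
    def test_single_block_adds_weight(self):
        a = _aln("A" * 50, {"T7": 1}, [(100, 149)])
        track = build_coverage([a], {"virus": 400}, ["T7"])
        cov = track.get("T7", "virus")
        assert cov[99:149].sum() == 50 and cov.sum() == 50

    def test_itr_half_weight_conserves_mass(self):
        a1 = _aln("C" * 50, {"T7": 2}, [(10, 59)], weight=0.5)
        a2 = AlignmentRecord(a1.species, "virus", 200, "forward", 0,
                             ((200, 249),), 0.5)
        track = build_coverage([a1, a2], {"virus": 400}, ["T7"])
        cov = track.get("T7", "virus")
        assert cov[9] == 1.0 and cov[199] == 1.0
        assert cov.sum() == 2 * 50            # multiplicity x read length

    def test_junction_read_skips_intron(self):
        a = _aln("G" * 50, {"T7": 1}, [(100, 124), (300, 324)])
        track = build_coverage([a], {"virus": 400}, ["T7"])
        cov = track.get("T7", "virus")
        assert cov[124:299].sum() == 0 and cov.sum() == 50

    def test_block_outside_genome_rejected(self):
        a = _aln("T" * 50, {"T7": 1}, [(380, 429)])
        with pytest.raises(ValueError):
            build_coverage([a], {"virus": 400}, ["T7"])


class TestMrpn:
    @pytest.mark.parametrize("cov,expected", [
        ([7.0] * 10, 7.0),
        ([1, 2, 3, 4, 100], 3.0),
        ([0, 0, 5, 5], 2.5),
    ])
    def test_closed_forms(self, cov, expected):
        gene = GeneRecord("g", 1, len(cov), "+")
        assert mrpn(_track(cov), gene, "T60") == expected

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1e5), min_size=3, max_size=60),
           st.floats(0, 100))
    def test_brute_force_median_and_shift(self, cov, c):
        gene = GeneRecord("g", 1, len(cov), "+")
        assert mrpn(_track(cov), gene, "T60") == np.median(cov)
        shifted = [x + c for x in cov]
        assert mrpn(_track(shifted), gene, "T60") == \
            pytest.approx(np.median(cov) + c)

    def test_robust_to_minority_inflation(self):
        rng = np.random.default_rng(1)
        cov = np.full(101, 8.0)
        gene = GeneRecord("g", 1, 101, "+")
        idx = rng.choice(101, size=50, replace=False)   # < half the span
        inflated = cov.copy()
        inflated[idx] += rng.uniform(100, 1e6, size=50)
        assert mrpn(_track(inflated), gene, "T60") == 8.0


class TestScaling:
    def test_ratio_and_identity(self):
        s = scaling_factors({"T0": 1e6, "T7": 2e6})
        assert s == {"T0": 1.0, "T7": 2.0}

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            scaling_factors({"T7": 10.0})

    def test_norm_divides_by_s_t(self):
        genome = GenomeAnnotation("virus", "A" * 40,
                                  [GeneRecord("g", 1, 20, "+", 1)])
        track = CoverageTrack({"T0": {"virus": np.full(40, 5.0)},
                               "T7": {"virus": np.full(40, 10.0)}})
        table = expression_table(track, genome, {"T0": 100, "T7": 200})
        t7 = table[table.timepoint == "T7"].iloc[0]
        assert t7.raw_mrpn == 10.0 and t7.s_t == 2.0 and t7.norm_mrpn == 5.0

    def test_global_rescale_equivariance(self):
        """Doubling depth everywhere leaves s_t invariant and scales the
        normalized values by exactly the same factor."""
        genome = GenomeAnnotation("virus", "A" * 40,
                                  [GeneRecord("g", 1, 20, "+", 1)])
        cov = {"T0": np.full(40, 5.0), "T7": np.full(40, 12.0)}
        t1 = expression_table(CoverageTrack({t: {"virus": c}
                                             for t, c in cov.items()}),
                              genome, {"T0": 100, "T7": 300})
        t2 = expression_table(CoverageTrack({t: {"virus": 2 * c}
                                             for t, c in cov.items()}),
                              genome, {"T0": 200, "T7": 600})
        assert np.allclose(t1.s_t, t2.s_t)
        assert np.allclose(2 * t1.norm_mrpn, t2.norm_mrpn)


class TestTopN:
    def _table(self, values):
        return pd.DataFrame([{"gene_id": f"g{i}", "timepoint": "T7",
                              "norm_mrpn": v} for i, v in enumerate(values)])

    def _genome(self, n):
        genes = [GeneRecord(f"g{i}", 10 * i + 1, 10 * i + 5, "+", i + 1)
                 for i in range(n)]
        return GenomeAnnotation("virus", "A" * (10 * n + 10), genes)

    def test_orders_by_expression(self):
        top = top_n(self._table([5, 1, 9]), self._genome(3), "T7", n=2)
        assert top == ["g2", "g0"]

    def test_tie_broken_by_genome_rank(self):
        top = top_n(self._table([5, 3, 3]), self._genome(3), "T7", n=2)
        assert top == ["g0", "g1"]

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_n(self._table([1, 2]), self._genome(2), "T7", n=3)


class TestKmeans:
    def _profiles(self, n=416, noise=0.15, seed=7):
        rng = np.random.default_rng(seed)
        names = list(ARCHETYPES)
        rows, labels = [], []
        for i in range(n):
            a = i % 6
            amp = np.exp(rng.normal(0, 0.8)) * 100
            base = np.array(ARCHETYPES[names[a]]) * amp
            rows.append(base * np.exp(rng.normal(0, noise, size=5)))
            labels.append(a)
        wide = pd.DataFrame(rows, columns=["T7", "T14", "T20", "T40", "T60"],
                            index=[f"g{i}" for i in range(n)])
        return wide, labels

    def test_duplicate_shapes_recovered_exactly(self):
        wide = pd.DataFrame([[1, 2, 3], [2, 4, 6], [9, 4, 1], [18, 8, 2]],
                            columns=["T7", "T14", "T20"],
                            index=list("abcd"))
        res = kmeans_profiles(wide, k=2, restarts=20, seed=0)
        assert res.within_cluster_ss == pytest.approx(0.0, abs=1e-12)
        assert res.assignments["a"] == res.assignments["b"]
        assert res.assignments["c"] == res.assignments["d"]
        assert res.assignments["a"] != res.assignments["c"]

    def test_reproducible_for_fixed_seed(self):
        wide, _ = self._profiles(n=60)
        r1 = kmeans_profiles(wide, k=6, restarts=10, seed=3)
        r2 = kmeans_profiles(wide, k=6, restarts=10, seed=3)
        assert r1.assignments == r2.assignments
        assert r1.within_cluster_ss == r2.within_cluster_ss

    def test_objective_never_increases(self):
        wide, _ = self._profiles(n=120)
        res = kmeans_profiles(wide, k=6, restarts=5, seed=1)
        hist = res.iteration_inertia
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_matches_sklearn_objective(self):
        """Independent cross-check: best-of-restarts WCSS is as good as
        scikit-learn's on the same unit-max-scaled matrix."""
        from sklearn.cluster import KMeans

        wide, _ = self._profiles(n=150)
        res = kmeans_profiles(wide, k=6, restarts=50, seed=2)
        X = wide.to_numpy()
        X = X / X.max(axis=1, keepdims=True)
        sk = KMeans(n_clusters=6, n_init=50, random_state=2).fit(X)
        assert res.within_cluster_ss <= sk.inertia_ * 1.01

    def test_k_exceeding_distinct_profiles_rejected(self):
        wide = pd.DataFrame([[1, 2], [2, 4]], columns=["T7", "T14"],
                            index=["a", "b"])
        with pytest.raises(ValueError):
            kmeans_profiles(wide, k=3, restarts=2, seed=0)


def test_library_totals_weighted(small_experiment):
    totals = library_totals(small_experiment["alignments"],
                            list(small_experiment["truth"].depth))
    depth = small_experiment["truth"].depth
    for tp, tot in totals.items():
        assert tot <= depth[tp]
        assert tot >= 0.9 * depth[tp]     # nearly everything maps, error-free
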