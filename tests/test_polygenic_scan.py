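import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from adaptscan import polygenic_scan as P
from adaptscan.datatypes import GeneMap, TermMap, ValidationError


def bh_oracle(pvals):
    """Step-up BH: q_(i) = min_{j>=i} p_(j) * m / j, mapped back."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def _bins_of(sizes, window=11):
    gm = GeneMap({"G": {f"rs{i}" for i in range(sizes)}})
    pos = {f"rs{i}": i for i in range(sizes)}
    return [len(b.snps) for b in P.make_bins(gm, pos, window=window)]


class TestMakeBins:
    @pytest.mark.parametrize("n,expected", [
        (11, [11]),
        (3, [3]),
        (25, [11, 14]),   # remainder 3 < 6 merges into the last full bin
        (28, [11, 11, 6]),
        (22, [11, 11]),
        (16, [16]),       # 11 + remainder 5 merges -> one bin
        (17, [11, 6]),
    ])
    def test_remainder_rule(self, n, expected):
        assert _bins_of(n) == expected

    @given(st.integers(min_value=1, max_value=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bins_partition_and_bounded(self, n):
        sizes = _bins_of(n)
        assert sum(sizes) == n
        assert all(s == 11 for s in sizes[:-1])
        if n > 11:
            assert 6 <= sizes[-1] <= 16

    def test_snps_ordered_by_position(self):
        gm = GeneMap({"G": {"a", "b", "c"}})
        pos = {"a": 300, "b": 100, "c": 200}
        bins = P.make_bins(gm, pos)
        assert bins[0].snps == ("b", "c", "a")

    def test_missing_position_rejected(self):
        with pytest.raises(ValidationError, match="G"):
            P.make_bins(GeneMap({"G": {"a"}}), {})


class TestNullMeanPbs:
    def test_constant_pool(self):
        null = P.null_mean_pbs(np.full(100, 2.5), k=5, n_perm=200, seed=0)
        np.testing.assert_allclose(null, 2.5)

    def test_mean_of_means_matches_pool_mean(self, rng):
        pool = rng.normal(size=500)
        null = P.null_mean_pbs(pool, k=8, n_perm=20_000, seed=1)
        mc_se = pool.std() / np.sqrt(8) / np.sqrt(20_000)
        assert abs(null.mean() - pool.mean()) < 3 * mc_se

    def test_draws_have_distinct_indices(self):
        # pool of one-hot values: a duplicated index would double-count a spike
        pool = np.zeros(12)
        pool[0] = 1.0
        null = P.null_mean_pbs(pool, k=11, n_perm=500, seed=2)
        # every draw of 11 distinct SNPs from 12 contains the spike 11/12 of
        # the time, never twice: means are only 0 or 1/11
        assert np.all(np.isclose(null, 0.0) | np.isclose(null, 1.0 / 11.0))
        assert np.isclose(null, 1.0 / 11.0).any()

    def test_k_larger_than_pool_rejected(self):
        with pytest.raises(ValidationError):
            P.null_mean_pbs(np.zeros(5), k=6)


def _mk_bins(spec):
    """spec: {gene: [bin SNP lists]}"""
    out = []
    for gene, snp_lists in spec.items():
        for i, snps in enumerate(snp_lists):
            out.append(P.BinSpec(gene, i, tuple(snps)))
    return out


class TestSelectionIndex:
    def test_extreme_bin_gets_minimum_index(self, rng):
        pool_vals = rng.uniform(0, 1, 200)
        pbs = {f"s{i}": v for i, v in enumerate(pool_vals)}
        pbs["hi1"], pbs["hi2"] = 5.0, 6.0
        bins = _mk_bins({"G": [["hi1", "hi2"]]})
        res = P.selection_index(bins, pbs, pool_vals, n_perm=999, seed=3)
        assert res[0].index == pytest.approx(1.0 / 1000.0)

    def test_bottom_bin_near_one(self, rng):
        pool_vals = rng.uniform(1, 2, 200)
        pbs = {f"s{i}": v for i, v in enumerate(pool_vals)}
        pbs["lo1"], pbs["lo2"] = -5.0, -6.0
        bins = _mk_bins({"G": [["lo1", "lo2"]]})
        res = P.selection_index(bins, pbs, pool_vals, n_perm=999, seed=4)
        assert res[0].index == pytest.approx(1.0)

    def test_missing_pbs_skips_bin(self, rng):
        pbs = {"a": 0.1, "b": np.nan}
        bins = _mk_bins({"G": [["a", "b"]]})
        res = P.selection_index(bins, pbs, np.array([0.1, 0.2, 0.3]), n_perm=99, seed=5)
        assert res == []

    def test_null_indices_uniform(self, rng):
        """Bins drawn from the pool itself get uniform tail probabilities."""
        pool = rng.normal(size=3000)
        pbs = {f"s{i}": v for i, v in enumerate(pool)}
        ids = np.array(list(pbs))
        bins = []
        for g in range(400):
            snps = rng.choice(ids, size=11, replace=False)
            bins.append(P.BinSpec(f"G{g}", 0, tuple(snps)))
        res = P.selection_index(bins, pbs, pool, n_perm=5000, seed=6)
        ks = stats.kstest([r.index for r in res], "uniform")
        assert ks.pvalue > 0.01

    def test_shared_null_per_size_is_deterministic(self, rng):
        pool = rng.normal(size=500)
        pbs = {f"s{i}": v for i, v in enumerate(pool)}
        bins = _mk_bins({"G1": [["s0", "s1"]], "G2": [["s2", "s3"]]})
        r1 = P.selection_index(bins, pbs, pool, n_perm=500, seed=7)
        r2 = P.selection_index(list(reversed(bins)), pbs, pool, n_perm=500, seed=7)
        by_gene_1 = {r.bin.gene: r.index for r in r1}
        by_gene_2 = {r.bin.gene: r.index for r in r2}
        assert by_gene_1 == by_gene_2


class TestBhFdr:
    def test_forced_examples(self):
        np.testing.assert_allclose(P.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(P.bh_fdr([0.2]), [0.2])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(P.bh_fdr(p), bh_oracle(list(p)), atol=1e-12)

    def test_permutation_equivariant(self, rng):
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(P.bh_fdr(p)[perm], P.bh_fdr(p[perm]))

    def test_bounds(self, rng):
        p = rng.uniform(0, 1, 50)
        q = P.bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1.0)


class TestGeneIndex:
    def _results(self, spec):
        out = []
        for gene, indices in spec.items():
            for i, v in enumerate(indices):
                out.append(P.BinIndexResult(P.BinSpec(gene, i, ("x",)), 0.0, v, q=v))
        return out

    def test_single_bin_gene(self):
        res = P.gene_index(self._results({"G": [0.2]}))
        assert res[0].index == 0.2 and res[0].n_bins == 1

    def test_mean_at_threshold_not_significant(self):
        res = P.gene_index(self._results({"G": [0.005, 0.015]}))
        assert res[0].index == pytest.approx(0.010)
        assert not res[0].significant  # strict <

    def test_hand_computed_fixture(self):
        spec = {"A": [0.001], "B": [0.02, 0.04], "C": [0.009, 0.005], "D": [0.5], "E": [0.3, 0.1, 0.2]}
        res = {r.gene: r for r in P.gene_index(self._results(spec))}
        assert res["B"].index == pytest.approx(0.03)
        assert res["C"].index == pytest.approx(0.007)
        assert res["E"].index == pytest.approx(0.2)
        assert {g for g, r in res.items() if r.significant} == {"A", "C"}


class TestSizeBias:
    def test_constant_index_flat(self):
        res = [P.GeneIndexResult(f"G{i}", 0.5, 0.5, 1, False) for i in range(10)]
        slope, r2, p = P.check_size_bias(res, {f"G{i}": i + 1 for i in range(10)})
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_perfect_linear(self):
        res = [P.GeneIndexResult(f"G{i}", 0.01 * (i + 1), 0.0, 1, False) for i in range(10)]
        slope, r2, p = P.check_size_bias(res, {f"G{i}": i + 1 for i in range(10)})
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_normal_equations(self, rng):
        y = rng.uniform(0, 1, 10)
        x = rng.uniform(1, 40, 10)
        res = [P.GeneIndexResult(f"G{i}", y[i], 0.0, 1, False) for i in range(10)]
        slope, r2, p = P.check_size_bias(res, {f"G{i}": x[i] for i in range(10)})
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert slope == pytest.approx(beta[1], rel=1e-10)


class TestFilterTerms:
    def test_equal_sizes_all_retained(self):
        tm = TermMap({f"T{i}": {f"g{i}a", f"g{i}b"} for i in range(4)})
        out = P.filter_terms(tm, {g for s in tm.term_to_genes.values() for g in s})
        assert set(out.term_to_genes) == set(tm.term_to_genes)

    def test_median_rule_with_ties_kept(self):
        genes = {f"g{i}" for i in range(200)}
        sizes = {"T1": 1, "T2": 2, "T3": 3, "T4": 4, "T5": 100}
        tm = TermMap({t: {f"g{i}" for i in range(k)} for t, k in sizes.items()})
        out = P.filter_terms(tm, genes)
        assert set(out.term_to_genes) == {"T3", "T4", "T5"}

    def test_universe_intersection_applied_first(self):
        tm = TermMap({"T1": {"a", "zz"}, "T2": {"a", "b", "c"}})
        out = P.filter_terms(tm, {"a", "b", "c"})
        assert out.term_to_genes["T2"] == {"a", "b", "c"}
        assert "zz" not in out.term_to_genes.get("T1", set())


class TestPruneTerms:
    def test_identical_terms_collapse(self):
        tm = TermMap({"T2": {"a", "b"}, "T1": {"a", "b"}})
        out = P.prune_terms(tm, cut_height=0.5)
        assert set(out.term_to_genes) == {"T1"}  # tie -> lexicographically smallest

    def test_disjoint_terms_all_survive(self):
        tm = TermMap({"T1": {"a"}, "T2": {"b"}, "T3": {"c"}})
        out = P.prune_terms(tm, cut_height=0.5)
        assert set(out.term_to_genes) == {"T1", "T2", "T3"}

    def test_clusters_match_structure(self):
        groupA = {f"a{i}" for i in range(10)}
        tm = TermMap({
            "A1": set(groupA),
            "A2": set(list(groupA)[:9]) | {"extra"},   # Jaccard 9/11 with A1
            "B1": {"h1", "h2", "h3", "h4", "h5"},
            "B2": {"h1", "h2", "h3", "h4", "h5"},
            "C0": {f"x{i}" for i in range(20)},         # disjoint from all
        })
        out = P.prune_terms(tm, cut_height=0.5)
        assert set(out.term_to_genes) == {"A1", "B1", "C0"}  # larger/tied-smaller ids win

    def test_custom_distance_matrix(self):
        tm = TermMap({"T1": {"a"}, "T2": {"b"}})
        D = np.array([[0.0, 0.1], [0.1, 0.0]])  # force the disjoint pair together
        out = P.prune_terms(tm, cut_height=0.5, distance=D)
        assert set(out.term_to_genes) == {"T1"}


class TestProportionTest:
    def _results(self, n_sig, n_total, prefix):
        return [P.GeneIndexResult(f"{prefix}{i}", 0.0, 0.0, 1, i < n_sig) for i in range(n_total)]

    def test_equal_proportions_z_zero(self):
        res = self._results(2, 10, "t") + self._results(2, 10, "b")
        r = P.term_proportion_test({f"t{i}" for i in range(10)}, res)
        assert r.z == 0.0 and r.p == 0.5

    def test_extreme_contrast_closed_form(self):
        res = self._results(16, 16, "t") + self._results(0, 1000, "b")
        r = P.term_proportion_test({f"t{i}" for i in range(16)}, res)
        pooled = 16 / 1016
        z = (1.0 - 0.0) / np.sqrt(pooled * (1 - pooled) * (1 / 16 + 1 / 1000))
        assert r.z == pytest.approx(z, rel=1e-12)
        assert r.p == pytest.approx(stats.norm.sf(z), rel=1e-12)

    def test_hand_evaluated_fixture(self):
        res = self._results(5, 20, "t") + self._results(10, 1000, "b")
        r = P.term_proportion_test({f"t{i}" for i in range(20)}, res)
        pooled = 15 / 1020
        z = (5 / 20 - 10 / 1000) / np.sqrt(pooled * (1 - pooled) * (1 / 20 + 1 / 1000))
        assert r.z == pytest.approx(z, rel=1e-12)
        assert r.k_term == 5 and r.n_background == 1000

    def test_unscored_term_genes_rejected(self):
        with pytest.raises(ValidationError):
            P.term_proportion_test({"nope"}, self._results(1, 5, "t"))
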