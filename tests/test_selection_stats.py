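import numpy as np
import pytest

from adaptscan import selection_stats as S
from adaptscan.datatypes import PopulationPanel, ValidationError
from adaptscan.synthetic_data import SweepConfig, sweep_region_matrix

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def wc_fst_oracle(genos_a, genos_b):
    """Direct scalar transcription of the two-population Weir & Cockerham
    (1984) variance components from diploid genotype dosages (0/1/2)."""
    n1, n2 = len(genos_a), len(genos_b)
    p1 = sum(genos_a) / (2 * n1)
    p2 = sum(genos_b) / (2 * n2)
    h1 = sum(1 for g in genos_a if g == 1) / n1
    h2 = sum(1 for g in genos_b if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return None if a + b + c == 0 else a / (a + b + c)


def pbs_oracle(f_ab, f_ac, f_bc):
    def t(f):
        f = min(max(f, 0.0), 1.0 - 1e-6)
        return -np.log(1.0 - f)

    return (t(f_ab) + t(f_ac) - t(f_bc)) / 2.0


def nsl_oracle(H, focal, max_extend):
    """Exhaustive pairwise tract-length computation (ancestral allele = 0)."""

    def tract(h1, h2):
        L = 1
        j = focal - 1
        while j >= 0 and focal - j <= max_extend and h1[j] == h2[j]:
            L += 1
            j -= 1
        j = focal + 1
        while j < len(h1) and j - focal <= max_extend and h1[j] == h2[j]:
            L += 1
            j += 1
        return L

    def sl(rows):
        vals = [tract(H[a], H[b]) for i, a in enumerate(rows) for b in rows[i + 1:]]
        return sum(vals) / len(vals)

    anc = [i for i in range(H.shape[0]) if H[i, focal] == 0]
    der = [i for i in range(H.shape[0]) if H[i, focal] == 1]
    sl_a, sl_d = sl(anc), sl(der)
    return np.log(sl_a / sl_d), sl_a, sl_d


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequency:
    def test_all_reference_column(self, two_pop_matrix):
        gm, panel = two_pop_matrix
        gm.haplotypes[:, 0] = 0
        assert S.allele_frequency(gm, panel, "POPA", "alt")[0] == 0.0
        assert S.allele_frequency(gm, panel, "POPA", "ref")[0] == 1.0

    def test_matches_direct_tally(self, rng):
        haps = (rng.random((20, 5)) < 0.5).astype(np.int8)
        gm = make_matrix(haps)
        panel = PopulationPanel({f"S{i}": "P" for i in range(10)})
        freq = S.allele_frequency(gm, panel, "P", "alt")
        np.testing.assert_allclose(freq, haps.mean(axis=0))

    def test_a1_spec_resolves_per_variant(self, two_pop_matrix):
        gm, panel = two_pop_matrix
        alt = S.allele_frequency(gm, panel, "POPA", "alt")
        by_spec = S.allele_frequency(gm, panel, "POPA", np.array(["A"] * gm.n_variants, dtype=object))
        np.testing.assert_allclose(by_spec, 1.0 - alt)  # A is the REF base here

    def test_a1_mismatch_names_snp(self, two_pop_matrix):
        gm, panel = two_pop_matrix
        with pytest.raises(ValidationError, match="v0"):
            S.allele_frequency(gm, panel, "POPA", np.array(["T"] * gm.n_variants, dtype=object))

    def test_unknown_population(self, two_pop_matrix):
        gm, panel = two_pop_matrix
        with pytest.raises(ValidationError):
            S.allele_frequency(gm, panel, "NOPE")


# ---------------------------------------------------------------------------
# Fst / PBS
# ---------------------------------------------------------------------------

class TestFstWc:
    def _panel(self, n=10):
        return PopulationPanel({f"S{i}": ("PA" if i < n // 2 else "PB") for i in range(n)})

    def test_fixed_difference_gives_one(self):
        haps = np.vstack([np.ones((20, 1)), np.zeros((20, 1))]).astype(np.int8)
        gm = make_matrix(haps)
        panel = self._panel(20)
        res = S.fst_wc(gm, panel, "PA", "PB")
        assert res.theta[0] == pytest.approx(1.0)

    def test_all_heterozygote_nonpositive(self):
        haps = np.tile(np.array([[0], [1]], dtype=np.int8), (10, 1))
        gm = make_matrix(haps)
        res = S.fst_wc(gm, self._panel(10), "PA", "PB")
        assert res.theta[0] <= 0

    def test_monomorphic_absent_not_zero(self):
        haps = np.zeros((20, 1), dtype=np.int8)
        res = S.fst_wc(make_matrix(haps), self._panel(10), "PA", "PB")
        assert np.isnan(res.theta[0])

    def test_matches_direct_formula_oracle(self, rng):
        # 100 random small fixtures, 5+5 diploids
        for _ in range(100):
            haps = (rng.random((20, 1)) < rng.uniform(0.1, 0.9)).astype(np.int8)
            gm = make_matrix(haps)
            res = S.fst_wc(gm, self._panel(10), "PA", "PB")
            genos = haps[0::2, 0] + haps[1::2, 0]
            expected = wc_fst_oracle(list(genos[:5]), list(genos[5:]))
            if expected is None:
                assert np.isnan(res.theta[0])
            else:
                assert abs(res.theta[0] - expected) < 1e-12
                assert res.theta[0] == pytest.approx(
                    res.a[0] / (res.a[0] + res.b[0] + res.c[0]))


def _fst_like(ids, values, pops):
    values = np.asarray(values, dtype=float)
    return S.FstResult(np.asarray(ids, dtype=object), values,
                       values, np.zeros_like(values), np.zeros_like(values), pops)


class TestPbs:
    def test_all_zero(self):
        r = S.pbs(_fst_like(["v"], [0.0], ("A", "B")),
                  _fst_like(["v"], [0.0], ("A", "C")),
                  _fst_like(["v"], [0.0], ("B", "C")))
        assert r.pbs[0] == 0.0

    def test_symmetric_half_gives_log_two(self):
        r = S.pbs(_fst_like(["v"], [0.5], ("A", "B")),
                  _fst_like(["v"], [0.5], ("A", "C")),
                  _fst_like(["v"], [0.0], ("B", "C")))
        assert r.pbs[0] == pytest.approx(np.log(2.0))

    def test_matches_formula_on_random_triples(self, rng):
        f = rng.uniform(-0.1, 1.0, size=(3, 1000))
        r = S.pbs(_fst_like([f"v{i}" for i in range(1000)], f[0], ("A", "B")),
                  _fst_like([f"v{i}" for i in range(1000)], f[1], ("A", "C")),
                  _fst_like([f"v{i}" for i in range(1000)], f[2], ("B", "C")))
        expected = [pbs_oracle(*f[:, j]) for j in range(1000)]
        np.testing.assert_allclose(r.pbs, expected, atol=1e-12)

    def test_swapping_references_leaves_pbs_unchanged(self, rng):
        f = rng.uniform(0.0, 0.9, size=(3, 50))
        ids = [f"v{i}" for i in range(50)]
        r1 = S.pbs(_fst_like(ids, f[0], ("A", "B")), _fst_like(ids, f[1], ("A", "C")),
                   _fst_like(ids, f[2], ("B", "C")))
        r2 = S.pbs(_fst_like(ids, f[1], ("A", "C")), _fst_like(ids, f[0], ("A", "B")),
                   _fst_like(ids, f[2], ("C", "B")))
        np.testing.assert_allclose(r1.pbs, r2.pbs)

    def test_monotone_in_focal_divergence(self):
        ids = ["v"]
        vals = [S.pbs(_fst_like(ids, [x], ("A", "B")), _fst_like(ids, [0.3], ("A", "C")),
                      _fst_like(ids, [0.2], ("B", "C"))).pbs[0]
                for x in (0.1, 0.3, 0.5, 0.7)]
        assert np.all(np.diff(vals) > 0)

    def test_misaligned_variants_listed(self):
        with pytest.raises(ValidationError, match="v1"):
            S.pbs(_fst_like(["v0"], [0.1], ("A", "B")),
                  _fst_like(["v1"], [0.1], ("A", "C")),
                  _fst_like(["v0"], [0.1], ("B", "C")))


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

class TestNslRaw:
    def test_mirror_classes_give_zero(self):
        # derived carriers are exact mirror copies of the ancestral set
        block = np.array([[0, 1, 0, 1], [1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        focal_anc = np.zeros((3, 1), dtype=np.int8)
        focal_der = np.ones((3, 1), dtype=np.int8)
        H = np.vstack([
            np.hstack([block[:, :2], focal_anc, block[:, 2:]]),
            np.hstack([block[:, :2], focal_der, block[:, 2:]]),
        ])
        gm = make_matrix(H)
        pt = S.nsl_raw(gm, 2, maf_min=0.05)
        assert pt.raw == 0.0 and pt.sl_a == pt.sl_d

    def test_homogeneous_derived_class_negative(self):
        der = np.tile(np.array([1, 1, 1, 1, 1], dtype=np.int8), (3, 1))
        anc = np.array([[0, 1, 0, 0, 1], [1, 0, 0, 1, 0], [0, 0, 0, 0, 0]], dtype=np.int8)
        gm = make_matrix(np.vstack([anc, der]))
        pt = S.nsl_raw(gm, 2, maf_min=0.05)
        assert pt.raw < 0

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(100):
            n_hap = int(rng.integers(4, 10)) * 2
            n_sites = int(rng.integers(5, 12))
            H = (rng.random((n_hap, n_sites)) < 0.5).astype(np.int8)
            focal = n_sites // 2
            d = H[:, focal]
            if d.sum() < 2 or (1 - d).sum() < 2:
                continue
            gm = make_matrix(H)
            me = int(rng.integers(1, n_sites + 2))
            pt = S.nsl_raw(gm, focal, maf_min=0.01, max_extend=me)
            raw, sl_a, sl_d = nsl_oracle(H, focal, me)
            assert abs(pt.raw - raw) < 1e-12
            assert abs(pt.sl_a - sl_a) < 1e-12 and abs(pt.sl_d - sl_d) < 1e-12
            assert pt.sl_a >= 1 and pt.sl_d >= 1

    def test_skips_low_frequency_and_missing_annotation(self, rng):
        H = (rng.random((12, 9)) < 0.5).astype(np.int8)
        H[:, 4] = 0
        H[0, 4] = 1
        gm = make_matrix(H)
        assert S.nsl_raw(gm, 4) is None  # daf below maf_min
        gm2 = make_matrix(H, ancestral=None)
        assert S.nsl_raw(gm2, 2) is None  # no ancestral annotation

    def test_missing_calls_rejected(self):
        H = np.zeros((4, 3), dtype=np.int8)
        H[0, 0] = -1
        with pytest.raises(ValidationError, match="missing"):
            S.nsl_raw(make_matrix(H), 1)


class TestNslNormalize:
    def test_two_scores_one_bin(self):
        res = S.NslResult(np.array(["a", "b"], dtype=object), np.array([-1.0, 1.0]),
                          np.ones(2), np.ones(2), np.array([0.5, 0.51]))
        out = S.nsl_normalize(res, n_bins=1)
        np.testing.assert_allclose(out.zscore, [-1.0, 1.0])

    def test_bins_standardized(self, rng):
        res = S.NslResult(np.array([f"s{i}" for i in range(500)], dtype=object),
                          rng.normal(size=500), np.ones(500), np.ones(500),
                          rng.uniform(0.01, 0.99, 500))
        out = S.nsl_normalize(res, n_bins=20)
        for b in np.unique(out.bin_id):
            z = out.zscore[out.bin_id == b]
            if len(z) >= 2:
                assert abs(z.mean()) < 1e-9
                assert abs(z.std() - 1.0) < 1e-9

    def test_bin_assignment_floor(self):
        res = S.NslResult(np.array(["a", "b"], dtype=object), np.zeros(2),
                          np.ones(2), np.ones(2), np.array([0.049, 0.051]))
        out = S.nsl_normalize(res, n_bins=20)
        assert out.bin_id[0] == 0 and out.bin_id[1] == 1


def test_sweep_focal_zscore_outlier_versus_matched_neutral():
    """Mean focal |z| of swept regions exceeds the 95th percentile of
    focal |z| under frequency-matched neutral backgrounds."""
    results, labels = [], []
    rng = np.random.default_rng(77)
    n_sweep, n_neutral = 50, 100
    for i in range(n_sweep + n_neutral):
        is_sweep = i < n_sweep
        cfg = SweepConfig(n_haplotypes=200, core_freq=0.6, core_span=101 if is_sweep else 1,
                          seed=int(rng.integers(0, 2**31 - 1)))
        gm, focal, _ = sweep_region_matrix(cfg)
        if not is_sweep:
            col = np.zeros(gm.n_haplotypes, dtype=np.int8)
            on = rng.choice(gm.n_haplotypes, size=int(0.6 * gm.n_haplotypes), replace=False)
            col[on] = 1  # daf matched to the sweeps, no haplotype structure
            gm.haplotypes[:, focal] = col
        pt = S.nsl_raw(gm, focal, max_extend=100)
        results.append(S.NslResult(np.array([f"f{i}"], dtype=object), np.array([pt.raw]),
                                   np.array([pt.sl_a]), np.array([pt.sl_d]), np.array([pt.daf])))
        labels.append(is_sweep)
    out = S.nsl_normalize(S.combine_nsl(results), n_bins=1)
    labels = np.array(labels)
    z = np.abs(out.zscore)
    assert z[labels].mean() > np.quantile(z[~labels], 0.95)
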