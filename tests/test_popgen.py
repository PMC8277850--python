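import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoconcord import popgen

from conftest import small_config


def wc84_oracle(g1, g2):
    """Independent transcription of the Weir & Cockerham (1984) two-level
    variance components for two populations of diploid genotypes."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    n1, n2 = len(g1), len(g2)
    p1, p2 = g1.sum() / (2 * n1), g2.sum() / (2 * n2)
    h1, h2 = np.mean(g1 == 1), np.mean(g2 == 1)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def col(*genotypes):
    return np.asarray(genotypes, dtype=float)[:, None]


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        res = popgen.wc_fst_scan(col(*[0] * 10), col(*[2] * 10))
        assert res.per_site[0] == pytest.approx(1.0)

    def test_identical_pops_ratio_nonpositive(self):
        # identical frequencies and heterozygosity: s2 = 0, so
        # a = -(nbar/nc) * (pq - hbar/4)/(nbar - 1) = -(0.25 - 1/12)/5
        g = col(0, 0, 1, 1, 2, 2)
        res = popgen.wc_fst_scan(g, g.copy())
        assert res.a[0] == pytest.approx(-1 / 30)
        assert res.per_site[0] <= 0  # negative ratios retained as computed

    def test_toy_counts_match_component_oracle(self):
        g1, g2 = (0, 0, 1, 2), (2, 2, 1, 1)
        a, b, c = wc84_oracle(g1, g2)
        res = popgen.wc_fst_scan(col(*g1), col(*g2))
        assert res.a[0] == pytest.approx(a)
        assert res.b[0] == pytest.approx(b)
        assert res.c[0] == pytest.approx(c)
        assert res.per_site[0] == pytest.approx(a / (a + b + c))
        assert res.per_site[0] == pytest.approx(1 / 9)

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=12),
           st.lists(st.integers(0, 2), min_size=4, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_random_genotypes_match_oracle(self, g1, g2):
        res = popgen.wc_fst_scan(col(*g1), col(*g2))
        a, b, c = wc84_oracle(g1, g2)
        denom = a + b + c
        if denom == 0:
            assert np.isnan(res.per_site[0])
        else:
            assert res.per_site[0] == pytest.approx(a / denom)

    def test_pooled_identical_populations_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, size=1000)
        pop = rng.binomial(2, p, size=(200, 1000)).astype(float)
        res = popgen.wc_fst_scan(pop[:100], pop[100:])
        assert abs(res.weighted) < 0.01

    def test_monomorphic_everywhere_flagged_not_thrown(self):
        res = popgen.wc_fst_scan(np.zeros((5, 3)), np.zeros((5, 3)))
        assert np.isnan(res.per_site).all()
        assert np.isnan(res.weighted)

    def test_top_sites_recover_island_loci(self, sim_default, sim_filtered):
        gm, _ = sim_filtered
        g = sim_default.samples["group"].to_numpy()
        res = popgen.wc_fst_scan(gm.dosage[g == "parentA"], gm.dosage[g == "parentB"])
        pre = sim_default.genotypes
        idx = np.array(sim_default.truth.island_locus_idx)
        island_pos = set(zip(pre.chrom[idx], pre.pos[idx]))
        is_island = np.array([(c, p) in island_pos
                              for c, p in zip(gm.chrom, gm.pos)])
        n_island = int(is_island.sum())
        top = np.argsort(np.nan_to_num(res.per_site, nan=-1))[-n_island:]
        assert is_island[top].mean() >= 0.9


def pi_enumeration_oracle(dos):
    """O(n^2) enumeration of allele-pair differences/comparisons per site."""
    total_d = total_c = 0
    for j in range(dos.shape[1]):
        alleles = []
        for d in dos[:, j]:
            if np.isfinite(d):
                alleles += [1] * int(d) + [0] * (2 - int(d))
        if len(alleles) < 2:
            continue
        for x in range(len(alleles)):
            for y in range(x + 1, len(alleles)):
                total_c += 1
                total_d += alleles[x] != alleles[y]
    return total_d, total_c


class TestPiWindows:
    def _window(self, dos, pos=None):
        n_sites = dos.shape[1]
        pos = np.arange(1, n_sites + 1) if pos is None else pos
        return popgen.pi_windows(dos, np.array(["chr1"] * n_sites), pos)

    def test_monomorphic_window_zero(self):
        wins = self._window(np.zeros((4, 50)))
        assert wins[0].pi == 0.0

    def test_single_site_fully_genotyped(self):
        # 2 ref / 2 alt among 4 alleles: per-site pi = 2*2*2/(4*3) = 2/3;
        # with 999 fully genotyped invariant sites the window ratio of sums
        # is (2/3)/1000
        dos = np.zeros((2, 1000))
        dos[0, 0] = 2.0  # one hom-alt individual among two
        wins = self._window(dos)
        assert wins[0].pi == pytest.approx((2 / 3) / 1000)

    def test_masked_allele_changes_denominator(self):
        # 3 genotyped alleles (2 ref, 1 alt): pi = 2*2*1/(3*2) = 2/3
        diffs, comps = popgen.per_site_pi(np.array([[1.0], [np.nan]]))
        # one het individual: 2 alleles, 1 ref 1 alt -> 2*1*1/(2*1) = 1
        assert diffs[0] / comps[0] == pytest.approx(1.0)
        d2, c2 = popgen.per_site_pi(np.array([[0.0], [1.0]]))
        # 4 alleles, 3 ref 1 alt: 2*3*1/(4*3) = 1/2
        assert d2[0] / c2[0] == pytest.approx(0.5)

    @given(st.integers(2, 8), st.integers(2, 30), st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_matches_enumeration_oracle(self, n, L, seed):
        r = np.random.default_rng(seed)
        dos = r.integers(0, 3, size=(n, L)).astype(float)
        dos[r.random((n, L)) < 0.2] = np.nan
        wins = popgen.pi_windows(dos, np.array(["c"] * L),
                                 np.arange(1, L + 1), window=1000)
        d, c = pi_enumeration_oracle(dos)
        if c == 0:
            assert np.isnan(wins[0].pi)
        else:
            assert wins[0].pi == pytest.approx(d / c)

    def test_variant_only_input_rejected(self):
        with pytest.raises(ValueError, match="all-sites"):
            popgen.pi_windows(np.zeros((2, 3)), np.array(["c"] * 3),
                              np.arange(1, 4), is_all_sites=False)

    def test_window_coordinates_anchored_at_one(self):
        dos = np.zeros((2, 2))
        wins = self._window(dos, pos=np.array([1000, 1001]))
        assert [(w.start, w.end) for w in wins] == [(1, 1000), (1001, 2000)]


class TestLdR2:
    def _r2(self, x, y):
        dos = np.column_stack([x, y]).astype(float)
        df = popgen.ld_r2_matrix(dos, np.array(["c", "c"]), np.array([1, 2]))
        return df

    def test_duplicated_site_r2_one(self):
        df = self._r2([0, 1, 2, 1], [0, 1, 2, 1])
        assert df["r2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_dosages_r2_zero(self):
        df = self._r2([0, 0, 2, 2], [0, 2, 0, 2])
        assert df["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        df = self._r2([0, 1, 2, 2, 0], [0, 1, 1, 2, 0])
        x = np.array([0, 1, 2, 2, 0.])
        y = np.array([0, 1, 1, 2, 0.])
        r = np.corrcoef(x, y)[0, 1]
        assert df["r2"].iloc[0] == pytest.approx(r * r)
        assert df["r2"].iloc[0] == pytest.approx(0.8035714285714286)

    def test_allele_relabel_invariance(self, rng):
        x = rng.integers(0, 3, 30).astype(float)
        y = rng.integers(0, 3, 30).astype(float)
        assert self._r2(x, y)["r2"].iloc[0] == pytest.approx(
            self._r2(2 - x, y)["r2"].iloc[0])

    def test_monomorphic_pair_skipped(self):
        df = self._r2([1, 1, 1, 1], [0, 1, 2, 1])
        assert df.empty


class TestGenotypePCA:
    def test_separates_diverged_populations(self, rng):
        pa = rng.uniform(0.0, 0.2, 300)
        a = rng.binomial(2, pa, (50, 300)).astype(float)
        b = rng.binomial(2, 1 - pa, (50, 300)).astype(float)
        res = popgen.genotype_pca(np.vstack([a, b]))
        ev1 = res.eigenvectors[:, 0]
        gap = abs(ev1[:50].mean() - ev1[50:].mean())
        spread = max(ev1[:50].std(), ev1[50:].std())
        assert gap > 5 * spread

    def test_duplicate_individuals_identical_coordinates(self, rng):
        x = rng.integers(0, 3, (20, 100)).astype(float)
        x[1] = x[0]
        res = popgen.genotype_pca(x)
        np.testing.assert_allclose(res.eigenvectors[0], res.eigenvectors[1],
                                   atol=1e-10)

    def test_eigenvalue_identities(self, rng):
        x = rng.integers(0, 3, (15, 60)).astype(float)
        res = popgen.genotype_pca(x, k=15)
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)
        centered = x - x.mean(axis=0)
        total = np.trace(centered @ centered.T / x.shape[1])
        assert res.total_variance == pytest.approx(total)

    def test_orientation_flag(self, rng):
        pa = rng.uniform(0.0, 0.2, 200)
        a = rng.binomial(2, pa, (30, 200)).astype(float)
        b = rng.binomial(2, 1 - pa, (30, 200)).astype(float)
        ga = np.arange(60) < 30
        res = popgen.genotype_pca(np.vstack([a, b]), orient_groups=(ga, ~ga))
        assert res.eigenvectors[ga, 0].mean() < res.eigenvectors[~ga, 0].mean()
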