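import itertools

import numpy as np
import pytest

from sweepscan import sel_stats
from sweepscan.core import HaplotypeMatrix
from sweepscan.sel_stats import _ihh_side, _ihh_side_py


def _hm(alleles, pos=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if pos is None:
        pos = np.arange(1, alleles.shape[1] + 1) * 100
    return HaplotypeMatrix(alleles, pos, chrom)


def _single_window_grid(hap):
    return sel_stats.make_window_grid(hap.pos, int(hap.pos.max()),
                                      size=10_000_000, step=10_000_000)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def bf_pi_per_site(alleles):
    n, S = alleles.shape
    out = np.zeros(S)
    for s in range(S):
        diff = 0
        for i in range(n):
            for j in range(i + 1, n):
                diff += alleles[i, s] != alleles[j, s]
        out[s] = diff / (n * (n - 1) / 2)
    return out


def bf_tajimas_d(alleles):
    n, S_tot = alleles.shape
    seg = 0
    pi_total = 0.0
    npairs = n * (n - 1) / 2
    for s in range(S_tot):
        col = alleles[:, s]
        if 0 < col.sum() < n:
            seg += 1
        d = 0
        for i in range(n):
            for j in range(i + 1, n):
                d += col[i] != col[j]
        pi_total += d / npairs
    if seg == 0:
        return np.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_total - seg / a1) / np.sqrt(e1 * seg + e2 * seg * (seg - 1))


class TestTajima:
    def test_spec_worked_example(self):
        # 4 haplotypes, 3 singleton sites -> D ~ -0.755
        a = np.zeros((4, 3), dtype=np.uint8)
        a[0, 0] = a[1, 1] = a[2, 2] = 1
        hap = _hm(a)
        d = sel_stats.tajimas_d(hap, _single_window_grid(hap))
        assert d[0] == pytest.approx(-0.7544510776527732, abs=1e-6)

    def test_no_segregating_sites_nan(self):
        hap = _hm(np.zeros((6, 4)))
        d = sel_stats.tajimas_d(hap, _single_window_grid(hap))
        assert np.isnan(d[0])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = (rng.random((20, 30)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
            hap = _hm(a)
            d = sel_stats.tajimas_d(hap, _single_window_grid(hap))[0]
            want = bf_tajimas_d(a)
            assert d == pytest.approx(want, abs=1e-9)

    def test_too_few_haplotypes(self):
        hap = _hm(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            sel_stats.tajimas_d(hap, _single_window_grid(hap))


class TestPerSitePi:
    def test_monomorphic_zero(self):
        a = np.zeros((4, 2), dtype=np.uint8)
        a[:, 1] = 1
        assert np.all(sel_stats.per_site_pi(_hm(a)) == 0.0)

    def test_half_frequency(self):
        a = np.zeros((4, 1), dtype=np.uint8)
        a[:2, 0] = 1  # d=2, n=4 -> 4 differing pairs of 6
        assert sel_stats.per_site_pi(_hm(a))[0] == pytest.approx(2 / 3)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        a = (rng.random((12, 40)) < 0.3).astype(np.uint8)
        assert np.allclose(sel_stats.per_site_pi(_hm(a)),
                           bf_pi_per_site(a), atol=1e-12)

    def test_window_mean_consistent_with_tajima_pi(self):
        rng = np.random.default_rng(2)
        a = (rng.random((10, 50)) < 0.4).astype(np.uint8)
        hap = _hm(a)
        grid = _single_window_grid(hap)
        pi = sel_stats.per_site_pi(hap)
        win_mean = sel_stats.window_aggregate(pi, hap.pos, grid)
        assert win_mean[0] == pytest.approx(pi.mean())


class TestEhh:
    def test_core_value_is_one(self):
        rng = np.random.default_rng(3)
        a = (rng.random((12, 30)) < 0.5).astype(np.uint8)
        hap = _hm(a)
        curve = sel_stats.ehh(hap, 15, int(a[:, 15].max()))
        at_core = curve.values[curve.sites == 15]
        assert at_core[0] == 1.0

    def test_identical_carriers_stay_one(self):
        a = np.zeros((8, 20), dtype=np.uint8)
        a[:4, 10] = 1  # carriers of allele 1 are identical elsewhere
        hap = _hm(a)
        curve = sel_stats.ehh(hap, 10, 1)
        assert np.all(curve.values == 1.0)

    def test_two_two_split(self):
        # 4 carriers splitting 2/2 at the first flanking site -> EHH 1/3
        a = np.zeros((6, 3), dtype=np.uint8)
        a[:4, 1] = 1          # core carriers
        a[:2, 2] = 1          # split 2/2 at next site
        hap = _hm(a)
        curve = sel_stats.ehh(hap, 1, 1)
        val = curve.values[curve.sites == 2]
        assert val[0] == pytest.approx(1 / 3)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = (rng.random((14, 60)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            pos = np.sort(rng.choice(50_000, size=60, replace=False)) + 1
            hap = _hm(a, pos)
            core = int(rng.integers(5, 55))
            for allele in (0, 1):
                if (a[:, core] == allele).sum() < 2:
                    continue
                curve = sel_stats.ehh(hap, core, allele)
                k = int(np.flatnonzero(curve.sites == core)[0])
                left = curve.values[: k + 1]
                right = curve.values[k:]
                assert np.all(np.diff(left) >= -1e-12)   # increasing to core
                assert np.all(np.diff(right) <= 1e-12)   # decreasing outward
                assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_too_few_carriers(self):
        a = np.zeros((6, 3), dtype=np.uint8)
        a[0, 1] = 1
        with pytest.raises(ValueError):
            sel_stats.ehh(_hm(a), 1, 1)


class TestIhsNsl:
    def test_allele_swap_flips_sign(self, neutral_hap):
        sub = neutral_hap.take_sites(np.arange(900, 1100))
        df = sel_stats.ihs(sub)
        s = df[df["score"].notna()].index[len(df) // 4]
        flipped = sub.alleles.copy()
        flipped[:, s] ^= 1
        hap2 = HaplotypeMatrix(flipped, sub.pos, sub.chrom)
        df2 = sel_stats.ihs(hap2)
        assert df2.loc[s, "score"] == pytest.approx(-df.loc[s, "score"],
                                                    abs=1e-9)
        dfn = sel_stats.nsl(sub)
        dfn2 = sel_stats.nsl(hap2)
        assert dfn2.loc[s, "score"] == pytest.approx(-dfn.loc[s, "score"],
                                                     abs=1e-9)

    def test_symmetric_alleles_zero(self):
        # EHH curves identical for both alleles -> score 0
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        a = np.hstack([base, np.array([[0], [0], [1], [1]], dtype=np.uint8),
                       base])
        hap = _hm(a, pos=np.arange(1, 6) * 1000)
        df = sel_stats.nsl(hap, max_extend_sites=10)
        assert df.loc[2, "score"] == pytest.approx(0.0, abs=1e-12)

    def test_nsl_position_invariance(self, neutral_hap):
        sub = neutral_hap.take_sites(np.arange(500, 800))
        df1 = sel_stats.nsl(sub)
        warped = HaplotypeMatrix(sub.alleles,
                                 np.cumsum(np.arange(1, sub.n_sites + 1)),
                                 sub.chrom)
        df2 = sel_stats.nsl(warped)
        s1 = df1["score"].to_numpy()
        s2 = df2["score"].to_numpy()
        assert np.array_equal(np.isnan(s1), np.isnan(s2))
        assert np.allclose(s1[~np.isnan(s1)], s2[~np.isnan(s2)], atol=1e-12)

    def test_sweep_core_scores_extreme(self, neutral_hap, swept_hap):
        from conftest import maf_filter
        df = sel_stats.ihs(maf_filter(swept_hap))
        scored = df[df["score"].notna()]
        in_core = (scored["pos"] >= 850_000) & (scored["pos"] <= 1_150_000)
        dfn = sel_stats.nsl(maf_filter(swept_hap))
        scoredn = dfn[dfn["score"].notna()]
        # swept-derived haplotypes are long: core |scores| exceed background
        assert scored.loc[in_core, "score"].abs().mean() > \
            2 * scored.loc[~in_core, "score"].abs().mean() * 0.5
        # iHS and nSL measure the same footprint: correlated ranks
        merged = scored.merge(scoredn, on="site", suffixes=("_i", "_n"))
        rho = merged[["score_i", "score_n"]].rank().corr().iloc[0, 1]
        assert rho > 0.7

    def test_numba_kernel_matches_numpy_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            m = int(rng.integers(6, 14))
            S = int(rng.integers(5, 50))
            a = (rng.random((m, S)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            pos = np.sort(rng.choice(80_000, size=S, replace=False)) + 1
            core = int(rng.integers(0, S))
            carriers = np.flatnonzero(a[:, core] == 1)
            if carriers.size < 2:
                continue
            for direction in (-1, 1):
                for site_scale in (False, True):
                    kw = dict(site_scale=site_scale, cutoff=0.05,
                              maxgap_bp=None if site_scale else 20_000,
                              max_extend=200 if site_scale else 40_000)
                    got = _ihh_side(a, pos, core, carriers, direction, **kw)
                    want = _ihh_side_py(a, pos, core, carriers, direction, **kw)
                    assert got[1] == want[1]
                    assert got[0] == pytest.approx(want[0], abs=1e-9)


class TestStandardizeByFreq:
    def test_bin_moments(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=2000) + 3 * rng.random(2000)
        freqs = rng.random(2000)
        z = sel_stats.standardize_by_freq(scores, freqs, n_bins=20)
        edges = np.linspace(0, 1, 21)
        bins = np.clip(np.digitize(freqs, edges[1:-1]), 0, 19)
        for b in range(20):
            zb = z[bins == b]
            if zb.size >= 2:
                assert abs(zb.mean()) < 1e-9
                assert zb.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_equals_global_zscore(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=100)
        f = np.full(100, 0.3)
        z = sel_stats.standardize_by_freq(s, f, n_bins=1)
        assert np.allclose(z, (s - s.mean()) / s.std(ddof=0))

    def test_constant_bin_zero(self):
        z = sel_stats.standardize_by_freq(np.ones(10), np.full(10, 0.5))
        assert np.all(z == 0.0)

    def test_removes_frequency_trend(self, neutral_hap):
        df = sel_stats.ihs(neutral_hap)
        ok = df["score"].notna()
        z = sel_stats.standardize_by_freq(df["score"].to_numpy(),
                                          df["freq"].to_numpy())
        r = np.corrcoef(np.abs(z[ok]), df.loc[ok, "freq"])[0, 1]
        assert abs(r) < 0.1


class TestWindowAggregate:
    def test_mean_and_exclusion(self):
        rng = np.random.default_rng(8)
        a = (rng.random((10, 60)) < 0.4).astype(np.uint8)
        pos = np.sort(rng.choice(200_000, size=60, replace=False)) + 1
        hap = _hm(a, pos)
        table = sel_stats.build_window_table(hap, 200_000)
        for _, row in table.iterrows():
            sl = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
            assert row["n_snps"] == sl.sum()
            if row["n_snps"] < 10:
                assert not row["included"]
        pi = sel_stats.per_site_pi(hap)
        grid = sel_stats.make_window_grid(pos, 200_000)
        agg = sel_stats.window_aggregate(pi, pos, grid)
        w = 0
        sl = (pos - 1 >= grid.starts[w]) & (pos - 1 < grid.ends[w])
        if sl.any():
            assert agg[w] == pytest.approx(pi[sl].mean())

    def test_site_order_within_window_irrelevant(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        pos = np.array([10, 20, 30, 40])
        grid = sel_stats.make_window_grid(pos, 100, size=100, step=100)
        a = sel_stats.window_aggregate(vals, pos, grid)
        b = sel_stats.window_aggregate(vals[::-1], pos, grid)
        assert a[0] == b[0] == 2.5

    def test_standardized_columns_mean0_sd1(self, neutral_hap):
        table = sel_stats.standardize_windows(
            sel_stats.build_window_table(neutral_hap, 2_000_000))
        inc = table["included"]
        for col in ("pi_z", "ihs_z", "nsl_z"):
            v = table.loc[inc, col]
            assert abs(v.mean()) < 1e-9
            assert v.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
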