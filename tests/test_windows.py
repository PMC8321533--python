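"""Window statistics: per-site estimators, aggregation, ZF_ST, GC, correlation.

Brute-force oracles: π and d_XY by explicit enumeration of chromosome pairs,
Hudson F_ST by an independent transcription of the 1992 formulas.
"""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import divscan as ds
from divscan.variants import FilterReport, SiteCountsTable
from divscan.windows import window_stats, zfst


def pi_bruteforce(a, n):
    """Fraction of differing pairs among n chromosomes with a alt alleles."""
    alleles = [1] * a + [0] * (n - a)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(x != y for x, y in pairs) / len(pairs)


def dxy_bruteforce(a1, n1, a2, n2):
    """Fraction of differing cross-population chromosome pairs."""
    al1 = [1] * a1 + [0] * (n1 - a1)
    al2 = [1] * a2 + [0] * (n2 - a2)
    diffs = sum(x != y for x in al1 for y in al2)
    return diffs / (n1 * n2)


def hudson_fst_bruteforce(a1, n1, a2, n2):
    """Hudson (1992) estimator components, written out independently."""
    p1, p2 = a1 / n1, a2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestSiteEstimators:
    @pytest.mark.parametrize("a,n,expected", [
        (1, 2, 1.0),       # the single pair differs
        (0, 10, 0.0),      # monomorphic
        (3, 10, 0.4666666666666667),
    ])
    def test_site_pi_examples(self, a, n, expected):
        assert ds.site_pi(a, n) == pytest.approx(expected, abs=1e-12)
        assert ds.site_pi(a, n) == pytest.approx(pi_bruteforce(a, n))

    def test_site_pi_undefined_below_two_chromosomes(self):
        assert np.isnan(ds.site_pi(0, 1))
        assert np.isnan(ds.site_pi(0, 0))

    @pytest.mark.parametrize("p1,p2,expected", [
        (1.0, 0.0, 1.0),   # fixed difference
        (0.5, 0.5, 0.5),
    ])
    def test_site_dxy_examples(self, p1, p2, expected):
        assert ds.site_dxy(p1, p2) == expected

    def test_site_dxy_matches_pair_enumeration(self):
        a1, n1, a2, n2 = 2, 4, 1, 5
        got = ds.site_dxy(a1 / n1, a2 / n2)
        assert got == pytest.approx(dxy_bruteforce(a1, n1, a2, n2))
        assert got == pytest.approx(0.5)

    def test_fst_fixed_difference_is_one(self):
        num, den = ds.site_fst_components(10, 10, 0, 10)
        assert (num, den) == (1.0, 1.0)

    def test_fst_shared_monomorphic_has_zero_denominator(self):
        num, den = ds.site_fst_components(0, 10, 0, 8)
        assert num == 0.0 and den == 0.0

    def test_fst_example_against_oracle(self):
        num, den = ds.site_fst_components(5, 10, 1, 10)
        assert num == pytest.approx(0.122222222222, abs=1e-9)
        assert den == pytest.approx(0.5)
        onum, oden = hudson_fst_bruteforce(5, 10, 1, 10)
        assert num == pytest.approx(onum) and den == pytest.approx(oden)

    @given(st.integers(2, 30), st.integers(2, 30),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_estimators_match_oracles_everywhere(self, n1, n2, data):
        a1 = data.draw(st.integers(0, n1))
        a2 = data.draw(st.integers(0, n2))
        assert ds.site_pi(a1, n1) == pytest.approx(pi_bruteforce(a1, n1))
        assert ds.site_dxy(a1 / n1, a2 / n2) == pytest.approx(
            dxy_bruteforce(a1, n1, a2, n2))
        num, den = ds.site_fst_components(a1, n1, a2, n2)
        onum, oden = hudson_fst_bruteforce(a1, n1, a2, n2)
        assert num == pytest.approx(onum, abs=1e-12)
        assert den == pytest.approx(oden, abs=1e-12)

    def test_dxy_of_population_with_itself_approaches_pi(self):
        # d_XY lacks the n/(n-1) correction; they agree only as n grows
        a, n = 30, 100
        p = a / n
        assert ds.site_dxy(p, p) == pytest.approx(ds.site_pi(a, n),
                                                  abs=2.0 / n)


def _table(chrom, pos, alt, called, pops=("A", "B")):
    alt = np.asarray(alt); called = np.asarray(called)
    n = len(pos)
    return SiteCountsTable(
        chroms=np.asarray([chrom] * n, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n, dtype=object),
        alt_allele=np.asarray(["T"] * n, dtype=object),
        pops=list(pops), alt=alt, called=called, report=FilterReport())


class TestWindowStats:
    def test_single_fixed_difference_sets_dxy(self, window_grid):
        t = _table("chr1", [5000], [[4, 0]], [[4, 6]])
        out = window_stats(t, window_grid, min_snps=0)
        assert out.loc[0, "dxy_A_B"] == pytest.approx(1 / 20_000)
        assert out.loc[0, "fst_A_B"] == pytest.approx(1.0)

    def test_empty_window_degenerate_values(self, window_grid):
        t = _table("chr1", [5000], [[2, 1]], [[4, 6]])
        out = window_stats(t, window_grid, min_snps=0, add_zfst=False)
        assert out.loc[1, "pi_A"] == 0.0
        assert out.loc[1, "dxy_A_B"] == 0.0
        assert np.isnan(out.loc[1, "fst_A_B"])

    def test_min_snps_masks_sparse_windows(self, window_grid):
        t = _table("chr1", [5000, 6000], [[2, 1], [1, 0]],
                   [[4, 6], [4, 6]])
        out = window_stats(t, window_grid, min_snps=3, add_zfst=False)
        assert out.loc[0, "n_snps"] == 2
        assert np.isnan(out.loc[0, "pi_A"])

    def test_window_sums_match_per_site_loop(self, window_grid):
        """Aggregation equals an explicit per-site python loop to 1e-12."""
        rng = np.random.default_rng(11)
        n_sites = 80
        pos = np.sort(rng.choice(200_000, n_sites, replace=False)) + 1
        called = rng.integers(2, 9, size=(n_sites, 2)) * 0 + [[8, 6]]
        alt = np.stack([rng.integers(0, 9, n_sites) % 9,
                        rng.integers(0, 7, n_sites) % 7], axis=1)
        alt = np.minimum(alt, called)
        t = _table("chr1", pos, alt, called)
        out = window_stats(t, window_grid, min_snps=0, add_zfst=False)
        for w in range(10):
            lo, hi = w * 20_000, (w + 1) * 20_000
            in_w = (pos - 1 >= lo) & (pos - 1 < hi)
            pi_sum = sum(pi_bruteforce(int(a), 8) for a in alt[in_w, 0])
            dxy_sum = sum(dxy_bruteforce(int(a), 8, int(b), 6)
                          for a, b in alt[in_w])
            nums = dens = 0.0
            for a, b in alt[in_w]:
                nu, de = hudson_fst_bruteforce(int(a), 8, int(b), 6)
                if de > 0:
                    nums += nu; dens += de
            assert out.loc[w, "pi_A"] == pytest.approx(pi_sum / 20_000,
                                                       abs=1e-12)
            assert out.loc[w, "dxy_A_B"] == pytest.approx(dxy_sum / 20_000,
                                                          abs=1e-12)
            if dens > 0:
                assert out.loc[w, "fst_A_B"] == pytest.approx(nums / dens,
                                                              abs=1e-12)

    def test_sites_denominator_mode(self, window_grid):
        t = _table("chr1", [5000, 6000], [[2, 0], [4, 6]],
                   [[4, 6], [4, 6]])
        out = window_stats(t, window_grid, min_snps=0, denominator="sites",
                           add_zfst=False)
        expected = (ds.site_pi(2, 4) + ds.site_pi(4, 4)) / 2
        assert out.loc[0, "pi_A"] == pytest.approx(float(expected))


class TestZfst:
    def test_small_vector(self):
        np.testing.assert_allclose(zfst(np.array([0.0, 0.5, 1.0])),
                                   [-1.0, 0.0, 1.0])

    def test_matches_direct_formula_and_centers_median(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 0.8, 100)
        f[::7] = np.nan
        z = zfst(f)
        ok = np.isfinite(f)
        expected = (f[ok] - np.median(f[ok])) / np.std(f[ok], ddof=1)
        np.testing.assert_allclose(z[ok], expected, atol=1e-12)
        assert np.median(z[ok]) == 0.0
        assert np.isnan(z[~ok]).all()

    def test_degenerate_landscape_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            zfst(np.array([0.3, 0.3, 0.3]))


class TestGcAndCorrelation:
    def test_gc_content_windows(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\n" + "GCGC" * 5 + "ATAT" * 5 + "ACGTN" * 4 + "\n")
        w = pd.DataFrame({"chrom": ["chr1"] * 3,
                          "start": [0, 20, 40], "end": [20, 40, 60]})
        gc = ds.gc_content(fa, w)
        np.testing.assert_allclose(gc, [1.0, 0.0, 0.5])

    def test_all_n_window_is_nan(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\nNNNNNNNNNN\n")
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        assert np.isnan(ds.gc_content(fa, w)[0])

    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert ds.correlate(x, x, "pearson")[0] == pytest.approx(1.0)
        assert ds.correlate(x, -x, "spearman")[0] == pytest.approx(-1.0)

    def test_spearman_matches_hand_rank_computation(self):
        # ranks of x: 1..5; ranks of y: 2,1,4,3,5 → rho = 1 - 6*4/(5*24) = 0.8
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.2, 0.1, 0.8, 0.5, 0.9]
        assert ds.correlate(x, y, "spearman")[0] == pytest.approx(0.8)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = ds.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)
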