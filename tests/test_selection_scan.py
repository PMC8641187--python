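import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepkit.genotype_io import MISSING, PopulationScheme
from sweepkit.selection_scan import (
    FstComponents,
    GenomicWindow,
    WindowStatistic,
    delta_pi_scan,
    empirical_outliers,
    locus_fst,
    locus_fst_components,
    make_windows,
    site_pi,
    windowed_fst,
    windowed_pi,
)
from conftest import make_matrix, random_matrix
from _oracles import brute_site_pi, brute_windowed_fst


class TestLocusComponents:
    def test_hand_worked_two_populations(self):
        c = locus_fst_components([(20, 0.8), (30, 0.3)])
        assert c.p_bar == pytest.approx(0.5, abs=1e-12)
        assert c.msp == pytest.approx(3.0, abs=1e-9)
        assert c.msg == pytest.approx(9.5 / 49, abs=1e-12)
        assert c.n_c == pytest.approx(25.0)

    def test_equal_frequencies_zero_msp(self):
        c = locus_fst_components([(10, 0.42), (55, 0.42), (7, 0.42)])
        assert c.msp == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference(self):
        n = 12
        c = locus_fst_components([(n, 1.0), (n, 0.0)])
        assert c.msg == 0.0
        assert c.msp == pytest.approx(n / 2.0)

    def test_akey_msg_denominator(self):
        c = locus_fst_components([(20, 0.8), (30, 0.3)], msg_denom="akey")
        assert c.msg == pytest.approx(9.5 / 48)

    def test_wc_nc(self):
        c = locus_fst_components([(20, 0.8), (30, 0.3)], nc_mode="wc")
        assert c.n_c == pytest.approx(50 - (400 + 900) / 50)  # (n_tot - sum n^2/n_tot)/(s-1)

    def test_needs_two_subpopulations(self):
        with pytest.raises(ValueError):
            locus_fst_components([(10, 0.5)])


class TestLocusFst:
    def test_hand_worked_value(self):
        c = locus_fst_components([(20, 0.8), (30, 0.3)])
        assert locus_fst(c) == pytest.approx(2.80612 / 7.65306, abs=1e-5)
        assert locus_fst(c) == pytest.approx(0.36666666666, abs=1e-9)

    def test_fixed_difference_is_one(self):
        c = locus_fst_components([(8, 1.0), (8, 0.0)])
        assert locus_fst(c) == pytest.approx(1.0)

    def test_identical_frequencies_negative_floor(self):
        c = locus_fst_components([(10, 0.4), (10, 0.4)])
        assert c.n_c == 10
        assert locus_fst(c) == pytest.approx(-1.0 / 9.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        c = FstComponents(msp=0.0, msg=0.0, n_c=10.0, s=2, p_bar=0.0)
        assert np.isnan(locus_fst(c))

    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        n1=st.integers(2, 100),
        n2=st.integers(2, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_allele_label_swap_invariance(self, p1, p2, n1, n2):
        a = locus_fst(locus_fst_components([(n1, p1), (n2, p2)]))
        b = locus_fst(locus_fst_components([(n1, 1 - p1), (n2, 1 - p2)]))
        assert a == pytest.approx(b, abs=1e-9)

    @given(p1=st.floats(0.01, 0.99), p2=st.floats(0.01, 0.99), n=st.integers(2, 100))
    @settings(max_examples=100, deadline=None)
    def test_population_exchange_symmetry(self, p1, p2, n):
        a = locus_fst(locus_fst_components([(n, p1), (n, p2)]))
        b = locus_fst(locus_fst_components([(n, p2), (n, p1)]))
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_frequency_gap(self):
        # fix p_bar-ish center, widen the gap symmetrically
        n = 30
        gaps = np.linspace(0.0, 0.9, 40)
        vals = [
            locus_fst(locus_fst_components([(n, 0.5 - g / 2), (n, 0.5 + g / 2)]))
            for g in gaps
        ]
        assert np.all(np.diff(vals) >= -1e-12)


class TestMakeWindows:
    def test_arithmetic_tiling(self):
        w = make_windows({"chr1": 250_000}, 100_000, 50_000)
        assert [x.start_bp for x in w] == [1, 50_001, 100_001, 150_001, 200_001]

    def test_non_overlapping_each_locus_once(self):
        wins = make_windows({"chr1": 99_999}, 10_000, 10_000)
        for pos in (1, 9_999, 10_000, 55_000, 99_999):
            assert sum(w.contains(pos) for w in wins) == 1

    def test_half_step_each_interior_locus_twice(self):
        wins = make_windows({"chr1": 200_000}, 20_000, 10_000)
        for pos in (30_000, 100_005, 150_000):
            assert sum(w.contains(pos) for w in wins) == 2


class TestWindowedFst:
    def test_singleton_window_equals_locus_fst(self, two_group_scheme):
        dosage = np.array([[0], [0], [2], [2], [1], [2]], dtype=np.int8)
        pops = ["p1", "p2"] * 3
        g = make_matrix(dosage, positions=[500], populations=pops)
        for mode in ("weighted", "mean"):
            stats = windowed_fst(g, two_group_scheme, ("grp1", "grp2"), 1000, 1000, mode=mode)
            assert len(stats) == 1
            # p1 = rows 0,2,4 -> freq 3/6; p2 = rows 1,3,5 -> freq 4/6
            expect = locus_fst(locus_fst_components([(3, 0.5), (3, 2 / 3)]))
            assert stats[0].value == pytest.approx(expect, abs=1e-12)

    def test_identical_components_weighted_equals_mean(self, two_group_scheme):
        col = np.array([0, 2, 0, 2, 1, 1], dtype=np.int8)
        dosage = np.stack([col, col, col], axis=1)
        g = make_matrix(dosage, positions=[10, 20, 30], populations=["p1", "p2"] * 3)
        w1 = windowed_fst(g, two_group_scheme, ("grp1", "grp2"), 1000, 1000, mode="weighted")
        w2 = windowed_fst(g, two_group_scheme, ("grp1", "grp2"), 1000, 1000, mode="mean")
        assert w1[0].value == pytest.approx(w2[0].value, abs=1e-12)

    def test_two_locus_hand_ratio_of_sums(self, two_group_scheme):
        # group sizes 3/3; locus A: p=(1/6, 5/6); locus B: p=(0, 1/2)
        a = np.array([0, 2, 0, 2, 1, 1], dtype=np.int8)
        b = np.array([0, 2, 0, 0, 0, 1], dtype=np.int8)
        g = make_matrix(np.stack([a, b], axis=1), positions=[10, 20],
                        populations=["p1", "p2"] * 3)
        stats = windowed_fst(g, two_group_scheme, ("grp1", "grp2"), 1000, 1000)
        num = den = 0.0
        for col in (a, b):
            p1 = col[::2].sum() / 6.0
            p2 = col[1::2].sum() / 6.0
            pb = (p1 + p2) / 2
            msp = 3 * (p1 - pb) ** 2 + 3 * (p2 - pb) ** 2
            msg = (3 * p1 * (1 - p1) + 3 * p2 * (1 - p2)) / 5.0
            num += msp - msg
            den += msp + 2.0 * msg  # n_c = 3
        assert stats[0].value == pytest.approx(num / den, abs=1e-12)

    def test_identical_groups_rejected(self):
        scheme = PopulationScheme(groups={"a": {"p1"}, "b": {"p2"}})
        rng = np.random.default_rng(0)
        g = random_matrix(rng)
        with pytest.raises(ValueError):
            windowed_fst(g, scheme, ("a", "a"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, two_group_scheme):
        rng = np.random.default_rng(seed)
        g = random_matrix(rng, n_samples=16, n_loci=60, chrom_count=2, missing_rate=0.08)
        window_bp, step_bp = 100_000, 50_000
        stats = windowed_fst(g, two_group_scheme, ("grp1", "grp2"), window_bp, step_bp)
        rows_a = [i for i, s in enumerate(g.samples) if g.populations[s] == "p1"]
        rows_b = [i for i, s in enumerate(g.samples) if g.populations[s] == "p2"]
        expect = brute_windowed_fst(
            g.dosage, g.chromosomes(), g.positions(), rows_a, rows_b,
            g.chrom_extents(), window_bp, step_bp,
        )
        got = {s.window.key: s.value for s in stats}
        assert set(got) == set(expect)
        for k in expect:
            assert got[k] == pytest.approx(expect[k], abs=1e-9)


class TestSitePi:
    def test_counting_pairs(self):
        assert site_pi(20, 8) == pytest.approx(96 / 190)
        assert site_pi(20, 8) == pytest.approx(brute_site_pi([1] * 8 + [0] * 12))

    def test_monomorphic_zero(self):
        assert site_pi(10, 0) == 0.0
        assert site_pi(10, 10) == 0.0

    def test_single_pair(self):
        assert site_pi(2, 1) == 1.0

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            site_pi(1, 0)

    @pytest.mark.parametrize("n,alt", [(5, 2), (7, 3), (12, 6), (9, 1)])
    def test_matches_pair_enumeration(self, n, alt):
        assert site_pi(n, alt) == pytest.approx(brute_site_pi([1] * alt + [0] * (n - alt)))


class TestWindowedPi:
    def test_no_variants_zero(self):
        g = make_matrix(np.zeros((4, 2), dtype=np.int8), positions=[100, 200])
        stats = windowed_pi(g, {"pop1"}, 50_000, 25_000)
        assert all(s.value == 0.0 for s in stats)

    def test_single_site_division(self):
        col = np.array([0, 0, 1, 1], dtype=np.int8)  # n_chr=8, alt=2 -> pi=12/28
        g = make_matrix(col[:, None], positions=[100])
        stats = windowed_pi(g, {"pop1"}, 50_000, 50_000)
        assert stats[0].value == pytest.approx(site_pi(8, 2) / 50_000)

    def test_three_site_hand_sum(self):
        dosage = np.array(
            [[0, 1, 2], [1, 1, 2], [0, 0, 2], [2, 1, 2]], dtype=np.int8
        )
        g = make_matrix(dosage, positions=[10, 20, 30])
        stats = windowed_pi(g, {"pop1"}, 50_000, 50_000)
        expect = (site_pi(8, 3) + site_pi(8, 3) + site_pi(8, 8)) / 50_000
        assert stats[0].value == pytest.approx(expect, abs=1e-15)

    def test_missing_reduces_n_chr(self):
        col = np.array([0, 1, MISSING, MISSING], dtype=np.int8)
        g = make_matrix(col[:, None], positions=[100])
        stats = windowed_pi(g, {"pop1"}, 1000, 1000)
        assert stats[0].value == pytest.approx(site_pi(4, 1) / 1000)


class TestDeltaPiScan:
    def make_stats(self, values, chrom="chr1"):
        return [
            WindowStatistic(GenomicWindow(chrom, 1 + 1000 * i, 1001 + 1000 * i), v)
            for i, v in enumerate(values)
        ]

    def test_top_one_percent_of_hundred(self):
        rng = np.random.default_rng(0)
        other = self.make_stats(rng.uniform(0.5, 1.0, 100))
        focal = self.make_stats(np.zeros(100))
        out = delta_pi_scan(other, focal, 0.01)
        assert len(out) == 1
        best = max(o.value - f.value for o, f in zip(other, focal))
        assert out[0].value == pytest.approx(best)

    def test_all_equal_tie_returns_everything(self):
        other = self.make_stats(np.full(20, 0.3))
        focal = self.make_stats(np.full(20, 0.3))
        with pytest.warns(UserWarning):
            out = delta_pi_scan(other, focal, 0.05)
        assert len(out) == 20
        assert all(o.value == 0.0 for o in out)

    def test_inflated_window_found(self):
        other = self.make_stats([0.1] * 10)
        focal_vals = [0.1] * 10
        focal_vals[6] = 0.0  # diversity loss in focal window 6
        focal = self.make_stats(focal_vals)
        out = delta_pi_scan(other, focal, 0.1)
        assert len(out) == 1
        assert out[0].window.start_bp == 1 + 6000

    def test_disjoint_tilings_error(self):
        a = self.make_stats([1.0, 2.0], chrom="chr1")
        b = self.make_stats([1.0, 2.0], chrom="chr2")
        with pytest.raises(ValueError):
            delta_pi_scan(a, b, 0.05)


class TestEmpiricalOutliers:
    def make_stats(self, values):
        return [
            WindowStatistic(GenomicWindow("chr1", 1 + 100 * i, 101 + 100 * i), float(v))
            for i, v in enumerate(values)
        ]

    def test_top5_of_200_distinct(self):
        out = empirical_outliers(self.make_stats(np.arange(200)), 0.05)
        assert len(out) == 10
        assert min(o.value for o in out) == 190

    def test_top1_of_100(self):
        out = empirical_outliers(self.make_stats(np.arange(1, 101)), 0.01)
        assert [o.value for o in out] == [100]

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            out = empirical_outliers(self.make_stats(np.ones(50)), 0.05)
        assert len(out) == 50

    def test_percentile_ranks_filled(self):
        stats = self.make_stats(np.arange(10))
        empirical_outliers(stats, 0.5)
        assert all(s.percentile_rank is not None for s in stats)
        assert max(s.percentile_rank for s in stats) == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            empirical_outliers([], 0.05)
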