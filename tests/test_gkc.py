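import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pbscreen as pb
from pbscreen.genome import TTAAIndex
from pbscreen.gkc import GkcParams, find_peaks, sample_null
from pbscreen.kernel_oracle import brute_force_density
from conftest import make_sites


class TestKernelDensity:
    def test_single_insertion_at_its_own_position(self):
        assert pb.kernel_density([7], 5, [7])[0] == pytest.approx(1.0)

    def test_closed_form_two_insertions(self):
        # f(5000) = 2 exp(-5000^2 / (2*10000^2)) = 2 exp(-1/8)
        h = pb.kernel_density([0, 10_000], 10_000, [5_000])
        assert h[0] == pytest.approx(2 * np.exp(-0.125), rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10**6), min_size=1, max_size=20),
           st.integers(-10**6, 10**6))
    def test_translation_invariance(self, positions, shift):
        pos = np.sort(np.array(positions))
        ev = pos[:5] + 137
        a = pb.kernel_density(pos, 1000.0, np.sort(ev))
        b = pb.kernel_density(pos + shift, 1000.0, np.sort(ev) + shift)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n, m = int(rng.integers(1, 40)), int(rng.integers(2, 20))
            h = float(rng.uniform(100, 20_000))
            pos = np.sort(rng.uniform(0, 5 * h, n))
            ev = np.sort(rng.uniform(-h, 6 * h, m))
            np.testing.assert_allclose(pb.kernel_density(pos, h, ev),
                                       brute_force_density(pos, h, ev),
                                       rtol=1e-9)

    def test_truncation_bound(self, rng):
        # windowed engine differs from the exact sum by at most n*exp(-18)
        pos = np.sort(rng.uniform(0, 1e6, 500))
        ev = np.sort(rng.uniform(0, 1e6, 200))
        exact = pb.kernel_density(pos, 5000.0, ev)
        trunc = pb.kernel_density(pos, 5000.0, ev, trunc_radius=6.0)
        assert np.max(np.abs(exact - trunc)) <= 500 * np.exp(-18.0) + 1e-12

    def test_monotone_in_added_insertion(self):
        pos = np.array([1000.0, 2000.0, 3000.0])
        ev = np.array([2000.0])
        with_extra = pb.kernel_density(np.sort(np.append(pos, 2100.0)), 500.0, ev)
        assert with_extra[0] > pb.kernel_density(pos, 500.0, ev)[0]

    def test_unsorted_inputs_rejected(self):
        with pytest.raises(pb.InputError):
            pb.kernel_density([5, 1], 10.0, [1])
        with pytest.raises(pb.InputError):
            pb.kernel_density([1, 5], 10.0, [3, 1])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(pb.ParameterError):
            pb.kernel_density([1], 0.0, [1])


class TestFindPeaks:
    def test_unimodal_profile_single_peak(self):
        grid = np.arange(0, 10_000, 500)
        pos = np.array([5_000] * 3)
        heights = pb.kernel_density(pos, 1000.0, grid)
        peaks = find_peaks(grid, heights, pos, 1000, min_tumors=1)
        assert len(peaks) == 1
        assert peaks["apex_pos"].iloc[0] == grid[np.argmax(heights)]

    def test_two_distant_clusters_stay_separate(self):
        # clusters 5h apart: each peak's members are its own cluster only
        h = 1000
        pos = np.sort(np.array([0, 10, 20, 5000, 5010, 5030]))
        grid = np.unique(np.concatenate([np.arange(-200, 5400, 200), pos]))
        heights = pb.kernel_density(pos, float(h), grid)
        peaks = find_peaks(grid, heights, pos, h, min_tumors=1)
        assert len(peaks) == 2
        assert peaks["n_insertions"].tolist() == [3, 3]

    def test_single_tumor_support_filtered(self):
        pos = np.array([1000, 1010, 1020])
        grid = np.arange(0, 2000, 100)
        heights = pb.kernel_density(pos, 500.0, grid)
        peaks = find_peaks(grid, heights, pos, 500, tumor_codes=np.zeros(3),
                           min_tumors=2)
        assert len(peaks) == 0

    def test_empty_profile(self):
        assert len(find_peaks(np.array([]), np.array([]), np.array([]), 100)) == 0


class TestPeakPvalue:
    def _null(self, heights):
        return pb.NullDistribution(10_000, np.sort(np.asarray(heights, float)),
                                   np.array([]), 0.0, 100, 0)

    def test_add_one_bound(self):
        null = self._null(np.linspace(0, 1, 10_000))
        raw, adj = pb.peak_pvalue(5.0, null, 1)
        assert raw == pytest.approx(1 / 10_001)

    def test_bonferroni_arithmetic(self):
        null = self._null(np.linspace(0, 1, 1999))
        raw, adj = pb.peak_pvalue(2.0, null, 2)
        assert raw == pytest.approx(0.0005)
        assert adj == pytest.approx(0.001)

    def test_height_below_all_nulls(self):
        null = self._null([1.0, 2.0, 3.0])
        raw, adj = pb.peak_pvalue(0.5, null, 10)
        assert raw == 1.0 and adj == 1.0

    def test_empty_null_is_an_error(self):
        with pytest.raises(pb.StatisticsError):
            pb.peak_pvalue(1.0, self._null([]), 1)


class TestSampleNull:
    def _ttaa(self):
        return TTAAIndex({"c": np.arange(1, 2001) * 40}, {"c": 90_000})

    def test_seed_reproducibility(self):
        params = GkcParams(n_perm=100, scales=(1000,), min_scales_significant=1)
        a = sample_null({"c": 20}, self._ttaa(), 1000, params, seed=5)
        b = sample_null({"c": 20}, self._ttaa(), 1000, params, seed=5)
        c = sample_null({"c": 20}, self._ttaa(), 1000, params, seed=6)
        np.testing.assert_array_equal(a.heights, b.heights)
        assert not np.array_equal(a.heights, c.heights)

    def test_zero_insertions_empty_null(self):
        params = GkcParams(n_perm=100, scales=(1000,), min_scales_significant=1)
        null = sample_null({"c": 0}, self._ttaa(), 1000, params, seed=1)
        assert null.heights.size == 0

    def test_chromosome_without_ttaa_is_config_error(self):
        params = GkcParams(n_perm=100, scales=(1000,), min_scales_significant=1)
        ttaa = TTAAIndex({"c": []}, {"c": 100})
        with pytest.raises(pb.ConfigurationError):
            sample_null({"c": 5}, ttaa, 1000, params, seed=1)


class TestGkcParams:
    def test_default_scale_ladder_is_10_to_100_kb(self):
        assert GkcParams().scales == tuple(range(10_000, 100_001, 10_000))

    @pytest.mark.parametrize("kwargs", [
        {"scales": ()}, {"scales": (1000, 500)}, {"alpha": 0.0},
        {"alpha": 1.5}, {"n_perm": 10}, {"min_scales_significant": 0},
        {"min_scales_significant": 99}, {"null_mode": "bogus"},
        {"bonferroni": "bogus"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(pb.ParameterError):
            GkcParams(**kwargs)


class TestModel:
    def test_empty_input_yields_no_cis(self):
        ttaa = TTAAIndex({"c": [100]}, {"c": 1000})
        res = pb.call_cis(make_sites([]), ttaa,
                          params=GkcParams(n_perm=100, scales=(1000,),
                                           min_scales_significant=1))
        assert res.n_cis == 0

    def test_unknown_chromosome_is_config_error(self):
        ttaa = TTAAIndex({"c": [100]}, {"c": 1000})
        df = make_sites([("S1", "cX", 10, "+", "merged", 1)])
        with pytest.raises(pb.ConfigurationError):
            pb.CommonInsertionSiteModel(df, ttaa)

    def test_byte_identical_given_seed(self, small_screen):
        conf, ttaa, genes, screen = small_screen
        pooled = pb.pool_nonredundant(pb.collapse_reads(screen.insertions))
        params = GkcParams(n_perm=100, alpha=0.05, scales=(10_000, 20_000))
        a = pb.CommonInsertionSiteModel(pooled, ttaa, params=params).fit(seed=9)
        b = pb.CommonInsertionSiteModel(pooled, ttaa, params=params).fit(seed=9)
        assert a.cis.to_csv() == b.cis.to_csv()
        assert a.membership.to_csv() == b.membership.to_csv()

    def test_recovers_strong_drivers_end_to_end(self, small_screen):
        conf, ttaa, genes, screen = small_screen
        pooled = pb.pool_nonredundant(pb.collapse_reads(screen.insertions))
        params = GkcParams(n_perm=200, alpha=0.05,
                           scales=(10_000, 20_000, 30_000))
        res = pb.call_cis(pooled, ttaa, genes=genes, params=params, seed=3)
        assert res.n_cis >= 2
        called = set(",".join(res.cis["genes"]).split(","))
        assert {d.gene for d in conf.drivers} <= called
        # reported CIS respect their own invariants
        assert (res.cis["adjusted_p"] >= res.cis["raw_p"] - 1e-15).all()
        assert (res.cis["start"] <= res.cis["apex_pos"]).all()
        assert (res.cis["apex_pos"] <= res.cis["end"]).all()
        assert (res.cis["n_tumors"] <= res.cis["n_insertions"]).all()
        assert (res.cis["n_scales_significant"]
                >= params.min_scales_significant).all()

    def test_summary_mentions_cis_count(self, small_screen):
        conf, ttaa, genes, screen = small_screen
        pooled = pb.pool_nonredundant(pb.collapse_reads(screen.insertions))
        params = GkcParams(n_perm=100, alpha=0.05, scales=(10_000, 20_000))
        res = pb.CommonInsertionSiteModel(pooled, ttaa, params=params).fit(seed=1)
        assert f"Significant CIS: {res.n_cis}" in res.summary()
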