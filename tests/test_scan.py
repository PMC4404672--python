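import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sweepkit as sk
from sweepkit.exceptions import (EstimationError, UndefinedPairError,
                                 UndefinedSiteError)
from sweepkit.io import MISSING

from conftest import make_gm, random_gm


class TestExpectedHet:
    @pytest.mark.parametrize("p, expected", [(0.5, 0.5), (0.0, 0.0), (0.1, 0.18)])
    def test_known_values(self, p, expected):
        assert sk.expected_het(p) == pytest.approx(expected)

    def test_undefined_without_calls(self):
        with pytest.raises(UndefinedSiteError):
            sk.expected_het(sk.SiteFrequency(p_alt=0.5, n_called=0))

    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, p):
        h = sk.expected_het(p)
        assert h == pytest.approx(sk.expected_het(1.0 - p))
        assert 0.0 <= h <= sk.expected_het(0.5) + 1e-12


class TestHetRatioScan:
    def test_identical_groups_give_unit_ratio(self, rng):
        dosage = rng.integers(0, 3, size=(10, 60)).astype(np.int8)
        # wild and cultivated are byte-identical sample sets
        both = np.vstack([dosage, dosage])
        gm = make_gm(both, populations={"wild": 10, "cult": 10})
        ws = sk.het_ratio_scan(gm, "wild", ["cult"], window_sites=20)
        assert np.allclose(ws.windows["ratio"], 1.0)

    def test_window_tiling_and_means_match_brute_force(self, rng):
        gm = random_gm(rng, n_samples=30, n_sites=1500, missing_rate=0.05,
                       pops={"wild": 10, "cult": 20})
        ws = sk.het_ratio_scan(gm, "wild", ["cult"], window_sites=500)
        assert ws.n_windows == 3  # 1500 sites, window 500, one chromosome
        wild = gm.sample_indices("wild")
        cult = gm.sample_indices("cult")
        for w in range(3):
            lo, hi = 500 * w, 500 * (w + 1)
            for rows, col in ((wild, "Hw_mean"), (cult, "Hc_mean")):
                hets = []
                for j in range(lo, hi):
                    c = gm.dosage[rows, j]
                    c = c[c != MISSING]
                    if len(c):
                        p = c.sum() / (2 * len(c))
                        hets.append(2 * p * (1 - p))
                assert ws.windows[col][w] == pytest.approx(np.mean(hets))

    def test_trailing_remainder_dropped(self, rng):
        gm = random_gm(rng, n_samples=10, n_sites=130,
                       pops={"wild": 5, "cult": 5})
        ws = sk.het_ratio_scan(gm, "wild", ["cult"], window_sites=50)
        assert ws.n_windows == 2

    def test_empty_scan_error(self, rng):
        gm = random_gm(rng, n_samples=8, n_sites=30, pops={"wild": 4, "cult": 4})
        with pytest.raises(EstimationError, match="empty"):
            sk.het_ratio_scan(gm, "wild", ["cult"], window_sites=100)

    def test_planted_sweep_windows_are_maximal(self):
        cfg = sk.SimConfig(
            n_chromosomes=1, sites_per_chromosome=1000,
            chrom_length_bp=10_000_000, chrom_length_cM=50,
            populations=(sk.PopulationSpec("wild", 25, 0.02),
                         sk.PopulationSpec("cult", 60, 0.2)),
            sweeps=(sk.SweepSpec(("cult",), "Chr01", 2_000_000, 4_200_000, 0.1),),
            seed=11)
        gm, _, truth = sk.simulate(cfg)
        ws = sk.het_ratio_scan(gm, "wild", ["cult"], window_sites=200)
        reg = truth.sweep_regions[0]
        sweep_windows = [w for w in range(ws.n_windows)
                         if ws.windows["first_site_index"][w] >= reg["site_start"] - 200
                         and ws.windows["first_site_index"][w] < reg["site_stop"]]
        ranks = ws.windows["ratio"].rank(ascending=False)
        # the fully swept windows occupy the top ranks of the chromosome
        fully = [w for w in sweep_windows
                 if ws.windows["first_site_index"][w] >= reg["site_start"]
                 and ws.windows["first_site_index"][w] + 200 <= reg["site_stop"]]
        assert fully and all(ranks[w] <= len(sweep_windows) for w in fully)


class TestTopPercentile:
    def test_all_equal_keeps_everything(self):
        scan = sk.WindowScan(windows=_fake_windows([2.0] * 10), window_sites=5)
        cutoff, regions = sk.top_percentile_regions(scan, 0.05)
        assert cutoff == 2.0
        total = sum(int(r.end - r.start) // 1000 for r in regions)
        assert total == 10  # every window qualifies (ties kept)

    def test_order_statistics(self):
        scan = sk.WindowScan(windows=_fake_windows([float(i) for i in range(1, 101)]),
                             window_sites=5)
        cutoff, regions = sk.top_percentile_regions(scan, 0.05)
        assert cutoff == 96.0
        assert len(regions) == 1  # windows 96..100 are adjacent -> merged
        assert regions[0].score == 100.0

    def test_infinite_windows_rank_highest(self):
        ratios = [1.0, 2.0, np.inf, 3.0, np.inf] + [1.0] * 15
        scan = sk.WindowScan(windows=_fake_windows(ratios), window_sites=5)
        cutoff, _ = sk.top_percentile_regions(scan, 0.05)
        assert np.isinf(cutoff)

    @given(st.lists(st.floats(0.1, 100, allow_nan=False), min_size=3, max_size=60),
           st.sampled_from([0.01, 0.05, 0.2, 0.5]))
    @settings(max_examples=60, deadline=None)
    def test_quantile_count_bracket(self, ratios, frac):
        scan = sk.WindowScan(windows=_fake_windows(ratios), window_sites=5)
        cutoff, _ = sk.top_percentile_regions(scan, frac)
        arr = np.asarray(ratios)
        assert (arr > cutoff).sum() <= frac * len(arr) or frac * len(arr) < 1
        assert (arr >= cutoff).sum() >= min(frac * len(arr), 1)
        assert frac * len(arr) <= (arr >= cutoff).sum()


def _fake_windows(ratios):
    import pandas as pd
    n = len(ratios)
    return pd.DataFrame({
        "chrom": ["1"] * n,
        "start_bp": np.arange(n) * 1000,
        "end_bp": np.arange(1, n + 1) * 1000,
        "first_site_index": np.arange(n) * 5,
        "n_sites": [5] * n,
        "Hw_mean": [0.3] * n,
        "Hc_mean": [0.3] * n,
        "ratio": ratios,
    })


class TestFst:
    def test_same_population_near_zero(self, rng):
        # two independent samples drawn from one frequency vector: the
        # estimator's expectation is zero (sampling-noise terms cancel)
        p = rng.uniform(0.1, 0.9, size=2000)
        dosage = rng.binomial(2, p[None, :], size=(200, 2000)).astype(np.int8)
        gm = make_gm(dosage, populations={"a": 100, "b": 100})
        assert sk.fst(gm, "a", "b") == pytest.approx(0.0, abs=0.01)

    def test_duplicated_samples_give_known_negative_bias(self, rng):
        # literally identical samples violate the between-sample independence
        # the estimator assumes; the closed form is exactly -1/(n-1)
        dosage = rng.integers(0, 3, size=(20, 200)).astype(np.int8)
        both = np.vstack([dosage, dosage])
        gm = make_gm(both, populations={"a": 20, "b": 20})
        assert sk.fst(gm, "a", "b") == pytest.approx(-1 / 39, rel=1e-9)

    def test_fixed_differences_give_one(self):
        dosage = np.vstack([np.zeros((5, 30)), np.full((5, 30), 2)]).astype(np.int8)
        gm = make_gm(dosage, populations={"a": 5, "b": 5})
        assert sk.fst(gm, "a", "b") == pytest.approx(1.0)

    def test_symmetric_in_population_order(self, rng):
        gm = random_gm(rng, n_samples=30, n_sites=300, pops={"a": 15, "b": 15})
        assert sk.fst(gm, "a", "b") == pytest.approx(sk.fst(gm, "b", "a"))

    def test_hudson_and_wc_agree_on_balanced_panel(self):
        cfg = sk.SimConfig(n_chromosomes=1, sites_per_chromosome=2000,
                           chrom_length_bp=10_000_000,
                           populations=(sk.PopulationSpec("a", 60, 0.2),
                                        sk.PopulationSpec("b", 60, 0.2)),
                           n_founders=None, seed=4)
        gm, _, _ = sk.simulate(cfg)
        h = sk.fst(gm, "a", "b")
        w = sk.fst(gm, "a", "b", estimator="wc")
        assert h == pytest.approx(w, abs=0.02)

    def test_matrix_shape_and_symmetry(self, rng):
        gm = random_gm(rng, n_samples=30, n_sites=100,
                       pops={"a": 10, "b": 10, "c": 10})
        mat = sk.fst_matrix(gm)
        assert mat.shape == (3, 3)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)


class TestLd:
    def test_identical_vectors(self):
        gm = make_gm(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        assert sk.ld_r2(gm, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        gm = make_gm(np.array([[0, 2], [0, 2], [2, 0], [2, 0]]))
        assert sk.ld_r2(gm, 0, 1) == pytest.approx(1.0)

    def test_matches_pearson_oracle(self, rng):
        # 6-sample worked table with one missing pair
        dosage = np.array([[0, 1], [1, 0], [2, 2], [0, 0], [2, 1], [MISSING, 2]])
        gm = make_gm(dosage)
        x = dosage[:5, 0].astype(float)
        y = dosage[:5, 1].astype(float)
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert sk.ld_r2(gm, 0, 1) == pytest.approx(expected)

    def test_allele_relabel_invariance(self, rng):
        gm = random_gm(rng, n_samples=30, n_sites=4, missing_rate=0.1)
        flipped = gm.dosage.copy()
        ok = flipped[:, 1] != MISSING
        flipped[ok, 1] = 2 - flipped[ok, 1]
        gm2 = make_gm(flipped)
        r1, r2 = sk.ld_r2(gm, 0, 1), sk.ld_r2(gm2, 0, 1)
        if not (np.isnan(r1) or np.isnan(r2)):
            assert r1 == pytest.approx(r2)

    def test_too_few_complete_pairs(self):
        gm = make_gm(np.array([[0, MISSING], [MISSING, 1], [1, 1]]))
        with pytest.raises(UndefinedPairError):
            sk.ld_r2(gm, 0, 1)

    def test_monomorphic_flagged_nan(self):
        gm = make_gm(np.array([[0, 1], [0, 0], [0, 2]]))
        assert np.isnan(sk.ld_r2(gm, 0, 1))

    def test_ld_matrix_cross_chromosome_distance(self, rng):
        gm = make_gm(rng.integers(0, 3, size=(10, 3)),
                     chrom=["1", "1", "2"], pos=[100, 900, 100])
        res = sk.ld_matrix(gm, [0, 1, 2])
        assert len(res.pairs) == 3
        assert res.pairs["distance_bp"][0] == 800
        assert np.isnan(res.pairs["distance_bp"][2])

    def test_no_decay_returns_horizon_flag(self):
        # one haplotype repeated: r2 = 1 at all distances
        hap = np.array([0, 2, 2, 0, 2, 0, 0, 2, 2, 0])
        dosage = np.tile(hap, (12, 1)).T  # sites x samples -> transpose below
        gm = make_gm(dosage.T, pos=np.arange(1, 11) * 10_000)
        res = sk.ld_decay_extent(gm, bin_bp=20_000, max_distance_bp=100_000)
        assert not res.reached_background
        assert res.extent_bp == 100_000

    def test_unlinked_sites_decay_immediately(self):
        cfg = sk.SimConfig(n_chromosomes=1, sites_per_chromosome=800,
                           chrom_length_bp=20_000_000,
                           populations=(sk.PopulationSpec("a", 200, 0.2,
                                                          selfing_rate=0.0),),
                           n_founders=None, seed=6)
        gm, _, _ = sk.simulate(cfg)
        res = sk.ld_decay_extent(gm, bin_bp=50_000, max_distance_bp=500_000)
        assert res.reached_background and res.extent_bp == 0.0
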