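from collections import Counter

import numpy as np
import pytest

import sweepkit as sk
from sweepkit.exceptions import EstimationError
from sweepkit.io import MISSING

from conftest import make_gm, random_gm


def brute_force_profile(gm, sites, population):
    """Independent enumeration over individuals and consecutive pairs."""
    rows = gm.sample_indices(population)
    counters = []
    for k in range(len(sites) - 1):
        c = Counter()
        for i in rows:
            d1 = gm.dosage[i, sites[k]]
            d2 = gm.dosage[i, sites[k + 1]]
            if d1 in (0, 2) and d2 in (0, 2):
                c[(d1 // 2, d2 // 2)] += 1
        counters.append(c)
    return counters


def brute_force_ratio(gm, sites, pop_a, pop_b):
    ca = brute_force_profile(gm, sites, pop_a)
    cb = brute_force_profile(gm, sites, pop_b)
    shared = sum(len(set(x) & set(y)) for x, y in zip(ca, cb))
    union = sum(len(set(x) | set(y)) for x, y in zip(ca, cb))
    return shared, union


class TestSelectLinkedSnps:
    def test_singleton_region(self, rng):
        gm = random_gm(rng, n_samples=10, n_sites=5, missing_rate=0.0)
        region = sk.Interval("1", gm.pos_bp[2] - 1, gm.pos_bp[2], unit="bp")
        assert sk.select_linked_snps(gm, 2, region) == [2]

    def test_exact_copies_selected(self, rng):
        peak = rng.integers(0, 3, size=12).astype(np.int8)
        cols = [peak, rng.integers(0, 3, 12), peak,
                rng.integers(0, 3, 12), peak]
        gm = make_gm(np.stack(cols, axis=1))
        region = sk.Interval("1", 0, 10_000, unit="bp")
        selected = sk.select_linked_snps(gm, 0, region, r2_min=0.999)
        assert set(selected) >= {0, 2, 4}

    def test_matches_brute_force_r2_filter(self):
        cfg = sk.SimConfig(n_chromosomes=1, sites_per_chromosome=200,
                           chrom_length_bp=2_000_000, chrom_length_cM=10,
                           populations=(sk.PopulationSpec("a", 50, 0.2),),
                           block_length_bp=200_000, n_founders=4, seed=9)
        gm, _, _ = sk.simulate(cfg)
        region = sk.Interval("Chr01", 0, 800_000, unit="bp")
        candidates = gm.sites_in("Chr01", 0, 800_000)
        peak = int(candidates[len(candidates) // 2])
        selected = sk.select_linked_snps(gm, peak, region, r2_min=0.6)
        expected = {peak}
        for j in candidates:
            if int(j) == peak:
                continue
            r2 = sk.ld_r2(gm, peak, int(j))
            if not np.isnan(r2) and r2 >= 0.6:
                expected.add(int(j))
        assert set(selected) == expected

    def test_monomorphic_peak_rejected(self):
        gm = make_gm(np.zeros((6, 4)))
        region = sk.Interval("1", 0, 10_000, unit="bp")
        with pytest.raises(EstimationError, match="monomorphic"):
            sk.select_linked_snps(gm, 1, region)

    def test_region_count_selector(self, rng):
        gm = random_gm(rng, n_samples=5, n_sites=50, missing_rate=0.0)
        region = sk.Interval("1", 0, 100_000, unit="bp")
        sites = sk.select_region_snps(gm, region, n_snps=10)
        assert sites == list(range(10))


class TestBuildProfile:
    def test_single_homozygous_individual(self):
        gm = make_gm(np.array([[0, 0, 0]]))
        prof = sk.build_profile(gm, [0, 1, 2], "pop")
        assert prof.pair_haplotypes == [Counter({(0, 0): 1}), Counter({(0, 0): 1})]

    def test_heterozygote_skipped_per_pair(self):
        gm = make_gm(np.array([[0, 1, 2]]))
        with pytest.warns(UserWarning):
            prof = sk.build_profile(gm, [0, 1, 2], "pop")
        assert prof.pair_haplotypes == [Counter(), Counter()]

    def test_missing_skipped_per_pair(self):
        gm = make_gm(np.array([[0, MISSING, 2], [2, 2, 2]]))
        prof = sk.build_profile(gm, [0, 1, 2], "pop")
        assert prof.pair_haplotypes[0] == Counter({(1, 1): 1})
        assert prof.pair_haplotypes[1] == Counter({(1, 1): 1})

    def test_matches_enumeration_oracle(self, rng):
        gm = random_gm(rng, n_samples=20, n_sites=12, missing_rate=0.15)
        sites = list(range(12))
        prof = sk.build_profile(gm, sites, "pop")
        assert prof.pair_haplotypes == brute_force_profile(gm, sites, "pop")


class TestCommonHaplotypeRatio:
    def test_identical_populations(self, rng):
        dosage = (rng.integers(0, 2, size=(10, 8)) * 2).astype(np.int8)
        both = np.vstack([dosage, dosage])
        gm = make_gm(both, populations={"a": 10, "b": 10})
        sites = list(range(8))
        res = sk.common_haplotype_ratio(sk.build_profile(gm, sites, "a"),
                                        sk.build_profile(gm, sites, "b"))
        assert res.ratio == 1.0

    def test_disjoint_fixed_haplotypes(self):
        a = np.tile([0, 0, 0, 0], (5, 1))
        b = np.tile([2, 2, 2, 2], (5, 1))
        gm = make_gm(np.vstack([a, b]).astype(np.int8),
                     populations={"a": 5, "b": 5})
        sites = [0, 1, 2, 3]
        res = sk.common_haplotype_ratio(sk.build_profile(gm, sites, "a"),
                                        sk.build_profile(gm, sites, "b"))
        assert res.ratio == 0.0

    def test_worked_three_site_example(self):
        # pair 1: A has {RR, AA}, B has {RR}; pair 2: A has {RA}, B has {RA, AA}
        a = sk.HaplotypeProfile("A", [0, 1, 2],
                                [Counter({(0, 0): 3, (1, 1): 2}),
                                 Counter({(0, 1): 4})])
        b = sk.HaplotypeProfile("B", [0, 1, 2],
                                [Counter({(0, 0): 5}),
                                 Counter({(0, 1): 1, (1, 1): 2})])
        res = sk.common_haplotype_ratio(a, b)
        assert (res.shared_count, res.union_count) == (2, 4)
        assert res.ratio == 0.5

    def test_requires_same_site_list(self):
        a = sk.HaplotypeProfile("A", [0, 1], [Counter({(0, 0): 1})])
        b = sk.HaplotypeProfile("B", [0, 2], [Counter({(0, 0): 1})])
        with pytest.raises(ValueError, match="same site list"):
            sk.common_haplotype_ratio(a, b)

    def test_frequency_invariance(self, rng):
        """Adding an individual whose haplotypes already occur in both
        populations leaves the (type-based) ratio unchanged."""
        base = (rng.integers(0, 2, size=(8, 6)) * 2).astype(np.int8)
        gm1 = make_gm(np.vstack([base, base]), populations={"a": 8, "b": 8})
        extra = base[0:1]  # duplicate of an existing individual
        gm2 = make_gm(np.vstack([base, extra, base, extra]),
                      populations={"a": 9, "b": 9})
        sites = list(range(6))
        r1 = sk.common_haplotype_ratio(sk.build_profile(gm1, sites, "a"),
                                       sk.build_profile(gm1, sites, "b"))
        r2 = sk.common_haplotype_ratio(sk.build_profile(gm2, sites, "a"),
                                       sk.build_profile(gm2, sites, "b"))
        assert r1.ratio == r2.ratio


class TestSharingMatrix:
    def test_pair_count(self, rng):
        gm = random_gm(rng, n_samples=20, n_sites=10, missing_rate=0.0,
                       pops={"a": 5, "b": 5, "c": 5, "d": 5})
        res = sk.sharing_matrix(gm, list(range(10)), ["a", "b", "c", "d"])
        assert len(res) == 6  # k(k-1)/2 for k = 4

    def test_symmetry(self, rng):
        gm = random_gm(rng, n_samples=12, n_sites=8, missing_rate=0.0,
                       pops={"a": 6, "b": 6})
        sites = list(range(8))
        ab = sk.common_haplotype_ratio(sk.build_profile(gm, sites, "a"),
                                       sk.build_profile(gm, sites, "b"))
        ba = sk.common_haplotype_ratio(sk.build_profile(gm, sites, "b"),
                                       sk.build_profile(gm, sites, "a"))
        assert ab.ratio == ba.ratio

    def test_shared_sweep_pair_scores_highest(self):
        region = (1_000_000, 1_200_000)
        sweeps = (sk.SweepSpec(("A", "B"), "Chr01", *region, 0.05, haplotype_id=0),
                  sk.SweepSpec(("C",), "Chr01", *region, 0.05, haplotype_id=1))
        cfg = sk.SimConfig(n_chromosomes=1, sites_per_chromosome=2000,
                           chrom_length_bp=4_000_000, chrom_length_cM=50,
                           populations=(sk.PopulationSpec("A", 40, 0.2),
                                        sk.PopulationSpec("B", 40, 0.25),
                                        sk.PopulationSpec("C", 40, 0.3)),
                           sweeps=sweeps, seed=3)
        gm, _, _ = sk.simulate(cfg)
        iv = sk.Interval("Chr01", region[0], region[1], unit="bp")
        sites = sk.select_region_snps(gm, iv, n_snps=100)
        res = {r.pop_pair: r.ratio for r in sk.sharing_matrix(gm, sites,
                                                              ["A", "B", "C"])}
        assert res[("A", "B")] > res[("A", "C")]
        assert res[("A", "B")] > res[("B", "C")]
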