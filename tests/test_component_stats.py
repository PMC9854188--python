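import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from csscan.component_stats import (
    EHHProfile,
    compute_components,
    delta_saf,
    ehh,
    fst_per_snp,
    ihh,
    xpehh_raw,
    xpehh_scan,
    xpehh_standardize,
)
from csscan.errors import ContractError, DegenerateDistributionError
from csscan.genotype_io import allele_frequencies
from csscan.synthetic_cohort import SimConfig, simulate_cohort
from csscan.genotype_io import split_cohorts

from conftest import make_haps, make_map, random_panel


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def wc_theta_oracle(count1, n1, count2, n2):
    """Scalar Weir-Cockerham two-population theta from allele counts,
    coded long-hand from the haploid ANOVA decomposition."""
    p1, p2 = count1 / n1, count2 / n2
    N = n1 + n2
    pbar = (count1 + count2) / N
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2)
    nc = N - (n1 * n1 + n2 * n2) / N
    denom = msp + (nc - 1) * msg
    if denom == 0:
        return float("nan")
    return (msp - msg) / denom


def ehh_oracle(alleles, pos, core, d_index):
    """EHH at marker offset d_index from core via exhaustive haplotype
    class enumeration (tuples + Counter)."""
    lo, hi = min(core, d_index), max(core, d_index)
    segs = [tuple(row[lo: hi + 1]) for row in alleles]
    n = len(segs)
    return sum(c * (c - 1) for c in Counter(segs).values()) / (n * (n - 1))


def trapezoid_oracle(xs, ys):
    area = 0.0
    for i in range(1, len(xs)):
        area += (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2
    return area


def ihh_oracle(profile):
    d = profile.distances
    e = profile.ehh_values
    left = [(abs(int(x)), float(y)) for x, y in zip(d, e) if x <= 0]
    right = [(int(x), float(y)) for x, y in zip(d, e) if x >= 0]
    left.sort()
    right.sort()
    return trapezoid_oracle(*zip(*left)) + trapezoid_oracle(*zip(*right))


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

class TestFst:
    def test_identical_counts_non_positive(self):
        a = np.array([[0], [1], [0], [1]], dtype=np.int8)
        sel = make_haps(np.tile(a, (5, 1)))
        ref = make_haps(np.tile(a, (5, 1)), prefix="R")
        assert fst_per_snp(sel, ref)[0] <= 0

    def test_fixed_difference_matches_oracle(self):
        sel = make_haps(np.ones((20, 1), dtype=np.int8))
        ref = make_haps(np.zeros((80, 1), dtype=np.int8), prefix="R")
        got = fst_per_snp(sel, ref)[0]
        expect = wc_theta_oracle(20, 20, 0, 80)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_both_unavailable(self):
        sel = make_haps(np.ones((4, 1), dtype=np.int8))
        ref = make_haps(np.ones((4, 1), dtype=np.int8), prefix="R")
        assert np.isnan(fst_per_snp(sel, ref)[0])

    def test_matches_oracle_on_200_random_fixtures(self, rng):
        for _ in range(200):
            n1 = 2 * int(rng.integers(2, 15))
            n2 = 2 * int(rng.integers(2, 15))
            c1 = int(rng.integers(0, n1 + 1))
            c2 = int(rng.integers(0, n2 + 1))
            sel = make_haps(
                np.concatenate([np.ones(c1), np.zeros(n1 - c1)])
                .astype(np.int8)
                .reshape(-1, 1)
            )
            ref = make_haps(
                np.concatenate([np.ones(c2), np.zeros(n2 - c2)])
                .astype(np.int8)
                .reshape(-1, 1),
                prefix="R",
            )
            got = fst_per_snp(sel, ref)[0]
            expect = wc_theta_oracle(c1, n1, c2, n2)
            if math.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        sel, _ = random_panel(rng, 3, 5)
        ref, _ = random_panel(rng, 3, 6)
        with pytest.raises(ContractError):
            fst_per_snp(sel, ref)


# ---------------------------------------------------------------------------
# deltaSAF
# ---------------------------------------------------------------------------

class TestDeltaSaf:
    def test_arithmetic(self):
        sel = make_haps(
            np.array([[1]] * 8 + [[0]] * 2, dtype=np.int8)
        )  # p = 0.8
        ref = make_haps(
            np.array([[1]] * 3 + [[0]] * 7, dtype=np.int8), prefix="R"
        )  # p = 0.3
        assert delta_saf(sel, ref)[0] == pytest.approx(0.5)

    def test_equal_frequencies_zero(self):
        a = np.array([[0], [1], [0], [1]], dtype=np.int8)
        assert delta_saf(make_haps(a), make_haps(a, prefix="R"))[0] == 0.0

    def test_antisymmetry_exact(self, rng):
        sel, _ = random_panel(rng, 5, 20)
        ref, _ = random_panel(rng, 8, 20)
        np.testing.assert_array_equal(
            delta_saf(sel, ref), -delta_saf(ref, sel)
        )

    def test_composition_with_allele_frequencies(self, rng):
        sel, _ = random_panel(rng, 5, 30)
        ref, _ = random_panel(rng, 7, 30)
        np.testing.assert_allclose(
            delta_saf(sel, ref),
            allele_frequencies(sel) - allele_frequencies(ref),
            atol=1e-15,
        )


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

class TestEhh:
    def test_identical_haplotypes_ehh_one(self):
        hs = make_haps(np.tile([0, 1, 0, 1, 1], (4, 1)).astype(np.int8))
        mm = make_map([1000, 2000, 3000, 4000, 5000])
        prof = ehh(hs, mm, 2)
        np.testing.assert_allclose(prof.ehh_values, 1.0)
        assert prof.distances[0] == -2000 and prof.distances[-1] == 2000

    def test_two_pairs_one_third(self):
        alleles = np.array(
            [[0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 0]], dtype=np.int8
        )
        hs = make_haps(alleles)
        mm = make_map([1000, 2000, 3000])
        prof = ehh(hs, mm, 0)
        # at +1000 (marker 2): classes {(0,0)x2, (0,1)x2} -> 2/C(4,2)
        val = prof.ehh_values[list(prof.distances).index(1000)]
        assert val == pytest.approx(1 / 3)

    def test_all_distinct_truncates(self):
        alleles = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8
        )
        hs = make_haps(alleles)
        mm = make_map([1000, 2000])
        prof = ehh(hs, mm, 0)
        # EHH one marker out = C(1,2)-free = 0 < floor -> dropped
        assert list(prof.distances) == [0]
        assert ihh(prof) == 0.0

    def test_core_value_is_one(self, rng):
        hs, mm = random_panel(rng, 6, 10)
        prof = ehh(hs, mm, 4)
        assert prof.ehh_values[list(prof.distances).index(0)] == 1.0

    def test_gap_stops_extension(self):
        hs = make_haps(np.tile([0, 1, 0], (4, 1)).astype(np.int8))
        mm = make_map([1000, 2000, 500_000])
        prof = ehh(hs, mm, 0, max_gap=200_000)
        assert prof.distances.max() == 1000

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(60):
            hs, mm = random_panel(rng, int(rng.integers(2, 7)), 12, spacing=500)
            core = int(rng.integers(0, 12))
            prof = ehh(hs, mm, core, truncation=0.0)
            pos_to_idx = {int(p): j for j, p in enumerate(mm.pos)}
            for d, e in zip(prof.distances, prof.ehh_values):
                if d == 0:
                    assert e == 1.0
                    continue
                j = pos_to_idx[int(mm.pos[core]) + int(d)]
                assert e == pytest.approx(
                    ehh_oracle(hs.alleles, mm.pos, core, j), abs=1e-10
                )

    def test_monotone_non_increasing(self, rng):
        for _ in range(40):
            hs, mm = random_panel(rng, int(rng.integers(2, 8)), 15)
            prof = ehh(hs, mm, 7, truncation=0.0)
            d, e = prof.distances, prof.ehh_values
            right = e[d >= 0]
            left = e[d <= 0][::-1]
            assert np.all(np.diff(right) <= 1e-12)
            assert np.all(np.diff(left) <= 1e-12)

    def test_out_of_range_core(self, rng):
        hs, mm = random_panel(rng, 3, 5)
        with pytest.raises(IndexError):
            ehh(hs, mm, 5)


class TestIhh:
    def test_rectangle(self):
        prof = EHHProfile(0, [0, 5000, 10000], [1.0, 1.0, 1.0])
        assert ihh(prof) == pytest.approx(10_000)

    def test_core_only_zero(self):
        assert ihh(EHHProfile(0, [0], [1.0])) == 0.0

    def test_piecewise_toy_vs_hand_trapezoid(self):
        d = [-3000, -1000, 0, 2000, 2500, 4000]
        e = [0.2, 0.6, 1.0, 0.7, 0.5, 0.1]
        prof = EHHProfile(0, d, e)
        assert ihh(prof) == pytest.approx(ihh_oracle(prof), abs=1e-10)

    def test_matches_oracle_on_random_profiles(self, rng):
        for _ in range(60):
            nl, nr = int(rng.integers(0, 6)), int(rng.integers(0, 6))
            dl = -np.sort(rng.integers(1, 10_000, nl))[::-1] if nl else []
            dr = np.sort(rng.integers(1, 10_000, nr)) if nr else []
            d = list(dl) + [0] + list(dr)
            e = [float(x) for x in rng.uniform(0, 1, len(d))]
            e[len(list(dl))] = 1.0
            prof = EHHProfile(0, d, e)
            assert ihh(prof) == pytest.approx(ihh_oracle(prof), abs=1e-10)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

class TestXpehh:
    def test_identical_cohorts_zero(self, rng):
        hs, mm = random_panel(rng, 4, 9)
        assert xpehh_raw(hs, hs, mm, 4) == pytest.approx(0.0)

    def test_constructed_ratio_e(self):
        # sel identical out to +-27183, ref identical only to +-10000:
        # iHH_sel / iHH_ref = 27183/10000 ~ e  ->  xpehh ~ 1
        core = 100_000
        pos = [core - 27_183, core - 10_000, core, core + 10_000, core + 27_183]
        mm = make_map(pos)
        sel = make_haps(np.tile([0, 1, 0, 1, 0], (4, 1)).astype(np.int8))
        ref_alleles = np.array(
            [
                [0, 1, 0, 1, 0],
                [0, 1, 0, 1, 1],
                [1, 1, 0, 1, 0],
                [1, 1, 0, 1, 1],
            ],
            dtype=np.int8,
        )
        ref = make_haps(ref_alleles, prefix="R")
        # 4 binary haplotypes cannot drop below EHH = 1/3 in one step, so a
        # 0.4 floor discards the outer ref points
        got = xpehh_raw(sel, ref, mm, 2, truncation=0.4, max_gap=30_000)
        assert got == pytest.approx(math.log(27_183 / 10_000), abs=1e-12)
        assert got == pytest.approx(1.0, abs=1e-4)

    def test_heterogeneous_reference_unavailable(self):
        mm = make_map([1000, 2000, 3000])
        sel = make_haps(np.tile([0, 1, 0], (4, 1)).astype(np.int8))
        ref = make_haps(
            np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8),
            prefix="R",
        )
        assert np.isnan(xpehh_raw(sel, ref, mm, 1))

    def test_antisymmetry_exact(self, rng):
        sel, mm = random_panel(rng, 5, 12)
        ref, _ = random_panel(rng, 6, 12)
        ref = make_haps(ref.alleles, prefix="R")
        for core in range(12):
            a = xpehh_raw(sel, ref, mm, core)
            b = xpehh_raw(ref, sel, mm, core)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == -b

    def test_scan_matches_single_core_calls(self, rng):
        sel, mm = random_panel(rng, 4, 10)
        ref, _ = random_panel(rng, 5, 10)
        scan = xpehh_scan(sel, ref, mm)
        for core in range(10):
            single = xpehh_raw(sel, ref, mm, core)
            if np.isnan(single):
                assert np.isnan(scan[core])
            else:
                assert scan[core] == pytest.approx(single, abs=1e-12)


class TestXpehhStandardize:
    def test_mean_zero_sd_one(self, rng):
        raw = rng.normal(2.0, 3.0, 500)
        z = xpehh_standardize(raw)
        assert abs(z.mean()) < 1e-6
        assert abs(z.std(ddof=0) - 1) < 1e-6

    def test_unavailable_preserved(self):
        raw = np.array([1.0, np.nan, 3.0, 5.0])
        z = xpehh_standardize(raw)
        assert np.isnan(z[1])
        avail = z[~np.isnan(z)]
        assert abs(avail.mean()) < 1e-12

    def test_rank_order_preserved(self, rng):
        raw = rng.normal(size=100)
        z = xpehh_standardize(raw)
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(z))

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDistributionError):
            xpehh_standardize(np.array([2.0, 2.0, 2.0]))


# ---------------------------------------------------------------------------
# neutral null behaviour of all components
# ---------------------------------------------------------------------------

class TestNeutralNull:
    def test_no_component_elevated_at_null_position(self):
        """At a fixed position of a neutral panel, each component should sit
        within the genome-wide background (50 seeded replicates, alpha=0.01)."""
        diffs = {"fst": [], "dsaf": [], "xpehh": []}
        for seed in range(50):
            cfg = SimConfig(
                seed=seed, sweep=False, n_sel=10, n_ref=10,
                n_snps=120, n_chrom=1, background_fst=0.0,
            )
            hs, mm, contrast, _ = simulate_cohort(cfg)
            sel, ref = split_cohorts(hs, contrast)
            sc = compute_components(sel, ref, mm)
            j = len(mm) // 2  # the would-be sweep site
            for name, vec in (("fst", sc.fst), ("dsaf", sc.dsaf), ("xpehh", sc.xpehh)):
                bg = np.delete(vec, j)
                bg = bg[~np.isnan(bg)]
                if np.isnan(vec[j]) or len(bg) < 10:
                    continue
                diffs[name].append(vec[j] - bg.mean())
        for name, d in diffs.items():
            t = stats.ttest_1samp(d, 0.0)
            assert t.pvalue > 0.01, f"{name} systematically shifted: {t}"
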