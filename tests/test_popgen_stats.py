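import itertools
import math

import numpy as np
import pytest

from nivgeno.popgen_stats import (
    aggregate_diversity,
    allele_frequencies_from_genotypes,
    fis_locus,
    fis_overall,
    heterozygosities_from_genotypes,
    hwe_permutation_test_genotypes,
    null_allele_ml,
    pi_sibs_locus,
    pi_sibs_panel,
    pi_sibs_subsets,
    sex_ratio_test_counts,
)


def hwe_genotypes(freqs, n, rng):
    alleles = np.array(list(freqs.keys()))
    probs = np.array(list(freqs.values()))
    draws = rng.choice(alleles, size=(n, 2), p=probs)
    return [tuple(sorted(pair)) for pair in draws.tolist()]


class TestFrequencies:
    def test_counting_example(self):
        freqs = allele_frequencies_from_genotypes([(120, 120), (120, 124)])
        assert freqs == {120: 0.75, 124: 0.25}

    def test_monomorphic(self):
        assert allele_frequencies_from_genotypes([(120, 120)] * 3) == {120: 1.0}

    def test_sum_to_one(self):
        rng = np.random.default_rng(0)
        genos = hwe_genotypes({1: 0.2, 2: 0.3, 3: 0.5}, 57, rng)
        assert sum(allele_frequencies_from_genotypes(genos).values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies_from_genotypes([])


class TestHeterozygosities:
    def test_all_heterozygous(self):
        ho, _ = heterozygosities_from_genotypes([(120, 124), (120, 124)])
        assert ho == 1.0

    def test_monomorphic_zero(self):
        ho, he = heterozygosities_from_genotypes([(120, 120)] * 10)
        assert ho == 0.0 and he == 0.0

    def test_unbiased_correction_vanishes_at_large_n(self):
        rng = np.random.default_rng(1)
        genos = hwe_genotypes({1: 0.5, 2: 0.5}, 100_000, rng)
        _, he = heterozygosities_from_genotypes(genos)
        freqs = allele_frequencies_from_genotypes(genos)
        plain = 1.0 - sum(p * p for p in freqs.values())
        assert he == pytest.approx(plain, abs=1e-4)
        assert he == pytest.approx(0.5, abs=0.01)


class TestFis:
    def test_equilibrium_is_zero(self):
        assert fis_locus(0.5, 0.5) == 0.0

    def test_no_heterozygotes_is_one(self):
        assert fis_locus(0.0, 0.4) == 1.0

    def test_monomorphic_undefined(self):
        assert fis_locus(0.0, 0.0) is None

    def test_hwe_simulation_near_zero(self):
        rng = np.random.default_rng(2)
        ho_vals, he_vals = [], []
        for _ in range(22):
            probs = rng.dirichlet([1.0] * 5)
            genos = hwe_genotypes(dict(zip(range(5), probs)), 1000, rng)
            ho, he = heterozygosities_from_genotypes(genos)
            ho_vals.append(ho)
            he_vals.append(he)
        fis, (lo, hi) = fis_overall(ho_vals, he_vals, seed=3)
        assert abs(fis) < 0.02
        assert lo <= fis <= hi


class TestHWEPermutation:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        genos = hwe_genotypes({1: 0.6, 2: 0.4}, 100, rng)
        p1 = hwe_permutation_test_genotypes(genos, seed=7)
        p2 = hwe_permutation_test_genotypes(genos, seed=7)
        assert p1 == p2

    def test_monomorphic_p_one(self):
        assert hwe_permutation_test_genotypes([(1, 1)] * 50) == 1.0

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            hwe_permutation_test_genotypes([(1, 2)] * 4)

    def test_heterozygote_deficit_detected(self):
        rng = np.random.default_rng(5)
        genos = hwe_genotypes({1: 0.5, 2: 0.5}, 1000, rng)
        hets = [g for g in genos if g[0] != g[1]]
        homs = [g for g in genos if g[0] == g[1]]
        depleted = (homs + hets[: len(hets) // 2])[:500]
        p = hwe_permutation_test_genotypes(depleted, seed=8)
        assert p < 0.05


class TestPiSibs:
    def test_monomorphic_is_one(self):
        assert pi_sibs_locus({120: 1.0}) == pytest.approx(1.0)

    def test_two_even_alleles(self):
        # 0.25 + 0.5*0.5 + 0.5*0.25 - 0.25*0.125 = 19/32
        assert pi_sibs_locus({120: 0.5, 124: 0.5}) == pytest.approx(19 / 32)

    def test_panel_value_is_product(self):
        vals = [0.5, 0.4, 0.9]
        assert pi_sibs_panel(vals) == pytest.approx(0.5 * 0.4 * 0.9)

    def test_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            probs = rng.dirichlet([0.5] * 8)
            v = pi_sibs_locus(dict(zip(range(8), probs)))
            assert 0.0 < v <= 1.0

    def test_unnormalised_frequencies_rejected(self):
        with pytest.raises(ValueError):
            pi_sibs_locus({1: 0.5, 2: 0.4})


class TestPiSibsSubsets:
    def test_symmetric_values(self):
        r = pi_sibs_subsets([0.5, 0.5, 0.5], 2)
        assert r.min == r.max == r.mean == pytest.approx(0.25)

    def test_matches_enumeration_n6(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.1, 0.9, size=6).tolist()
        for k in range(1, 7):
            r = pi_sibs_subsets(vals, k)
            products = [math.prod(c) for c in itertools.combinations(vals, k)]
            assert r.min == pytest.approx(min(products))
            assert r.max == pytest.approx(max(products))
            assert r.mean == pytest.approx(sum(products) / len(products))

    def test_mean_weakly_decreasing_in_k(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.05, 1.0, size=10).tolist()
        means = [pi_sibs_subsets(vals, k).mean for k in range(1, 11)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_full_panel_single_subset(self):
        vals = [0.3, 0.6, 0.8, 0.2]
        r = pi_sibs_subsets(vals, 4)
        assert r.min == r.max == r.mean == pytest.approx(pi_sibs_panel(vals))

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            pi_sibs_subsets([0.5], 2)


def null_allele_genotypes(visible_freqs, r, n, rng):
    """Called genotypes under HWE with a null allele of frequency r."""
    alleles = list(visible_freqs.keys()) + ["null"]
    probs = [p * (1 - r) / sum(visible_freqs.values()) for p in visible_freqs.values()] + [r]
    probs = np.array(probs) / sum(probs)
    out = []
    while len(out) < n:
        a, b = rng.choice(len(alleles), size=2, p=probs)
        ga, gb = alleles[a], alleles[b]
        if ga == "null" and gb == "null":
            continue  # amplification blank, not called
        if ga == "null":
            out.append((gb, gb))
        elif gb == "null":
            out.append((ga, ga))
        else:
            out.append(tuple(sorted((ga, gb))))
    return out


class TestNullAlleleML:
    def test_all_heterozygotes_estimate_zero(self):
        est = null_allele_ml([(1, 2)] * 40)
        assert est.frequency < 1e-3

    def test_no_null_small_estimate(self):
        rng = np.random.default_rng(9)
        genos = hwe_genotypes({1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}, 1000, rng)
        est = null_allele_ml(genos)
        assert est.converged
        assert est.frequency < 0.02

    def test_recovers_null_frequency(self):
        rng = np.random.default_rng(10)
        genos = null_allele_genotypes({1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}, r=0.2, n=1000, rng=rng)
        est = null_allele_ml(genos)
        assert est.converged
        assert est.frequency == pytest.approx(0.2, abs=0.05)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            null_allele_ml([(1, 1), (1, 2)] * 5)


class TestSexRatio:
    def test_balanced(self):
        prop, z, p = sex_ratio_test_counts(50, 100)
        assert (prop, z, p) == (0.5, 0.0, 1.0)

    def test_standard_formula(self):
        _, z, _ = sex_ratio_test_counts(55, 100)
        assert z == pytest.approx(1.0)
        _, z, _ = sex_ratio_test_counts(220, 400)
        assert z == pytest.approx(2.0)

    def test_monitoring_scale_bias(self):
        # a 55% male share among ~1735 animals: clearly significant, with a
        # z-score near 4.2 under the standard one-proportion formula
        prop, z, p = sex_ratio_test_counts(954, 1735)
        assert z == pytest.approx(4.15, abs=0.05)
        assert p < 1e-4

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        n, males = 200, 120
        _, _, p = sex_ratio_test_counts(males, n)
        sims = rng.binomial(n, 0.5, size=20_000)
        p_mc = np.mean(np.abs(sims - n / 2) >= abs(males - n / 2))
        assert p == pytest.approx(p_mc, abs=0.01)

    def test_zero_sexed_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sex_ratio_test_counts(0, 0)


class TestAggregation:
    def test_total_row_from_per_locus_table(self):
        import pandas as pd

        table = pd.DataFrame({
            "Na": [4, 6, 8],
            "Ho": [0.2, 0.5, 0.8],
            "He": [0.25, 0.5, 0.75],
            "pi_sibs": [0.9, 0.5, 0.4],
        })
        totals = aggregate_diversity(table)
        assert totals["Na"] == 18
        assert totals["Ho"] == pytest.approx(0.5)
        assert totals["He"] == pytest.approx(0.5)
        assert totals["FIS"] == pytest.approx(0.0)
        assert totals["pi_sibs"] == pytest.approx(0.18)

    def test_single_locus_total_equals_locus(self):
        import pandas as pd

        table = pd.DataFrame({"Na": [5], "Ho": [0.4], "He": [0.5]})
        totals = aggregate_diversity(table)
        assert totals["Na"] == 5 and totals["Ho"] == 0.4 and totals["He"] == 0.5
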