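import itertools
import random

import pytest
from scipy import stats

from nivgeno import (
    GenotypeCall,
    MatchRule,
    assign_sex,
    audit_individuals,
    cluster_individuals,
    mismatch_probability,
    mismatch_range_probability,
    pairwise_compare,
    threshold_sensitivity,
)

from conftest import make_sample

C = GenotypeCall.called


# --- binomial mismatch model -------------------------------------------------

class TestMismatchModel:
    def test_at_least_one_error_matches_field_value(self):
        # 1 - (1 - 0.071)^12, the probability that two samples of one
        # individual disagree somewhere across 12 compared loci
        assert round(mismatch_probability(12, 0.071), 3) == 0.587

    def test_zero_rate_gives_zero(self):
        assert mismatch_probability(25, 0.0) == 0.0

    def test_matches_full_pmf_summation(self):
        # brute-force oracle: 1 - pmf(0) summed from the binomial pmf
        for n, p in [(12, 0.071), (22, 0.2), (5, 0.9)]:
            oracle = 1.0 - stats.binom.pmf(0, n, p)
            assert mismatch_probability(n, p) == pytest.approx(oracle, abs=1e-12)

    def test_mismatches_concentrate_below_four(self):
        # virtually all same-individual comparisons show at most three
        # mismatches; conditioned on disagreeing at all, 99% (to printed
        # precision) fall in the 1-3 range
        assert mismatch_range_probability(12, 0.071, 0, 3) >= 0.99
        cond = mismatch_range_probability(12, 0.071, 1, 3, conditional_on_at_least_one=True)
        assert round(cond, 2) == 0.99

    def test_full_range_is_one(self):
        assert mismatch_range_probability(9, 0.3, 0, 9) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,p,lo,hi", [(6, 0.2, 1, 3), (8, 0.45, 0, 2), (10, 0.07, 2, 10)])
    def test_matches_exhaustive_enumeration(self, n, p, lo, hi):
        # enumerate all 2^n per-locus error vectors
        total = 0.0
        for pattern in itertools.product([0, 1], repeat=n):
            k = sum(pattern)
            if lo <= k <= hi:
                total += (p ** k) * ((1 - p) ** (n - k))
        assert mismatch_range_probability(n, p, lo, hi) == pytest.approx(total, abs=1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            mismatch_range_probability(5, 0.1, 3, 2)


# --- pairwise comparison -----------------------------------------------------

def full_genotype(panel, pair=(120, 124)):
    return {name: pair for name in panel.autosomal_names}


class TestPairwiseCompare:
    def test_identical_full_genotypes(self, panel, sample_factory):
        a = sample_factory("a", panel, full_genotype(panel))
        b = sample_factory("b", panel, full_genotype(panel))
        assert pairwise_compare(a, b, panel) == (22, 0)

    def test_one_het_vs_hom_difference(self, panel, sample_factory):
        names = panel.autosomal_names
        ga = {n: (120, 124) for n in names[:12]}
        gb = dict(ga)
        gb[names[0]] = (120, 120)
        a = sample_factory("a", panel, ga)
        b = sample_factory("b", panel, gb)
        assert pairwise_compare(a, b, panel) == (12, 1)


# --- clustering ---------------------------------------------------------------

class TestClustering:
    def test_identical_genotypes_merge(self, panel, sample_factory):
        a = sample_factory("a", panel, full_genotype(panel))
        b = sample_factory("b", panel, full_genotype(panel))
        inds = cluster_individuals([a, b], panel)
        assert len(inds) == 1 and sorted(inds[0].sample_ids) == ["a", "b"]

    def test_four_mismatches_split(self, panel, sample_factory):
        names = panel.autosomal_names
        ga = {n: (120, 124) for n in names[:12]}
        gb = dict(ga)
        for n in names[:4]:
            gb[n] = (120, 120)  # 4 single-allele differences
        a = sample_factory("a", panel, ga)
        b = sample_factory("b", panel, gb)
        assert len(cluster_individuals([a, b], panel)) == 2

    def test_three_mismatches_merge(self, panel, sample_factory):
        names = panel.autosomal_names
        ga = {n: (120, 124) for n in names[:12]}
        gb = dict(ga)
        for n in names[:3]:
            gb[n] = (120, 120)
        a = sample_factory("a", panel, ga)
        b = sample_factory("b", panel, gb)
        assert len(cluster_individuals([a, b], panel)) == 1

    def test_eleven_shared_loci_insufficient(self, panel, sample_factory):
        names = panel.autosomal_names
        a = sample_factory("a", panel, {n: (120, 124) for n in names[:11]})
        b = sample_factory("b", panel, {n: (120, 124) for n in names})
        assert len(cluster_individuals([a, b], panel)) == 2

    def test_contaminated_input_rejected(self, panel, sample_factory):
        s = sample_factory("a", panel, full_genotype(panel))
        s.contaminated = True
        with pytest.raises(ValueError):
            cluster_individuals([s], panel)

    def test_input_order_invariance(self, panel, sample_factory):
        rnd = random.Random(42)
        names = panel.autosomal_names
        samples = []
        for i in range(20):
            base = 100 + 2 * rnd.randrange(3)
            geno = {n: (base, base + 2 * rnd.randrange(2)) for n in names}
            samples.append(sample_factory(f"s{i:02d}", panel, geno, mean_qi=rnd.random()))
        ref = {
            frozenset(ind.sample_ids) for ind in cluster_individuals(samples, panel)
        }
        for _ in range(3):
            rnd.shuffle(samples)
            got = {frozenset(i.sample_ids) for i in cluster_individuals(samples, panel)}
            assert got == ref

    def test_members_satisfy_rule_post_hoc(self, panel, sample_factory):
        rnd = random.Random(1)
        names = panel.autosomal_names
        samples = []
        for i in range(30):
            geno = {n: (120, 124 if rnd.random() < 0.5 else 120) for n in names}
            samples.append(sample_factory(f"s{i:02d}", panel, geno, mean_qi=rnd.random()))
        inds = cluster_individuals(samples, panel)
        assert audit_individuals(inds, panel) == []


class TestThresholdSensitivity:
    def test_monotone_in_min_shared(self, panel, sample_factory):
        rnd = random.Random(3)
        names = panel.autosomal_names
        samples = []
        for i in range(25):
            geno = {
                n: ((120, 124) if rnd.random() < 0.8 else None) for n in names
            }
            samples.append(sample_factory(f"s{i:02d}", panel, geno, mean_qi=0.9))
        rules = [MatchRule(12, 3), MatchRule(16, 3), MatchRule(20, 3)]
        counts = [r["n_individuals"] for r in threshold_sensitivity(samples, panel, rules)]
        assert counts == sorted(counts)

    def test_single_rule_zero_change(self, panel, sample_factory):
        s = sample_factory("a", panel, full_genotype(panel))
        out = threshold_sensitivity([s], panel, [MatchRule()])
        assert len(out) == 1 and out[0]["pct_change"] == 0.0

    def test_no_rules_rejected(self, panel):
        with pytest.raises(ValueError):
            threshold_sensitivity([], panel, [])

    def test_mismatch_tolerance_irrelevant_without_errors(self, panel, sample_factory):
        a = sample_factory("a", panel, full_genotype(panel))
        b = sample_factory("b", panel, full_genotype(panel))
        strict = cluster_individuals([a, b], panel, MatchRule(12, 0))
        loose = cluster_individuals([a, b], panel, MatchRule(12, 3))
        assert len(strict) == len(loose) == 1


class TestAssignSex:
    def test_heterozygote_is_male(self, panel, sample_factory):
        geno = full_genotype(panel)
        geno["Amelogenin"] = (194, 200)
        s = sample_factory("a", panel, geno)
        assert assign_sex(s.calls, panel) == "male"

    def test_homozygote_is_female(self, panel, sample_factory):
        geno = full_genotype(panel)
        geno["Amelogenin"] = (194, 194)
        s = sample_factory("a", panel, geno)
        assert assign_sex(s.calls, panel) == "female"

    def test_missing_is_unknown(self, panel, sample_factory):
        s = sample_factory("a", panel, full_genotype(panel))
        assert assign_sex(s.calls, panel) == "unknown"
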