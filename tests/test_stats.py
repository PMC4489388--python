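"""Exact tests, rates, quantiles and the placement null vs independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from hbsyntax import (ContingencyTable2x2, GenomicInterval, HypergeomSpec, RegionSet,
                      fisher_exact, fold_vs_background, hypergeom_enrichment,
                      mann_whitney_u, placement_null, quantile, rate_per_mb,
                      zscore_normal_p)
from hbsyntax.stats import count_pairs_vectorised


# -- exact rational-arithmetic oracles --------------------------------------

def hypergeom_tail_oracle(N, K, n, x):
    """P(X >= x) by direct summation of binomial-coefficient ratios."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for k in range(x, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return total


def fisher_oracle(a, b, c, d, alternative):
    """Enumerate every table with the observed margins."""
    r1, c1 = a + b, a + c
    N = a + b + c + d
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    probs = {aa: Fraction(math.comb(c1, aa) * math.comb(N - c1, r1 - aa),
                          math.comb(N, r1)) for aa in range(lo, hi + 1)}
    if alternative == "greater":
        return float(sum(p for aa, p in probs.items() if aa >= a))
    # two-sided: all tables at most as probable as the observed one
    obs = probs[a]
    cutoff = obs * (1 + Fraction(1, 10**7))  # guard against fp-style ties
    return float(sum(p for p in probs.values() if p <= cutoff))


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("alternative", ["two_sided", "greater"])
    def test_matches_exhaustive_enumeration(self, rng, alternative):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4))
            if 0 in ContingencyTable2x2(a, b, c, d).margins():
                continue
            got = fisher_exact(ContingencyTable2x2(a, b, c, d), alternative)
            assert got == pytest.approx(fisher_oracle(a, b, c, d, alternative),
                                        rel=1e-6)

    def test_agrees_with_hypergeometric_tail(self, rng):
        """One-sided Fisher 'greater' IS the hypergeometric upper tail."""
        for _ in range(20):
            N = int(rng.integers(10, 40))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            x = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            table = ContingencyTable2x2(x, n - x, K - x, N - n - K + x)
            if 0 in table.margins():
                continue
            p_fisher = fisher_exact(table, "greater")
            p_hyper = hypergeom_enrichment(HypergeomSpec(N, K, n, x)).p_value
            assert p_fisher == pytest.approx(p_hyper, rel=1e-9)


class TestHypergeomEnrichment:
    def test_zero_successes_gives_p_one(self):
        res = hypergeom_enrichment(HypergeomSpec(100, 10, 20, 0))
        assert res.p_value == pytest.approx(1.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HypergeomSpec(100, 10, 20, 15)  # x > min(K, n)

    def test_matches_rational_oracle_small_populations(self, rng):
        for _ in range(25):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(K, n) + 1))
            res = hypergeom_enrichment(HypergeomSpec(N, K, n, x))
            assert res.p_value == pytest.approx(
                float(hypergeom_tail_oracle(N, K, n, x)), rel=1e-9)
            assert res.expected == pytest.approx(n * K / N)

    def test_tail_monotone_in_observed(self):
        ps = [hypergeom_enrichment(HypergeomSpec(1000, 50, 100, x)).p_value
              for x in range(0, 20)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestRatesAndFolds:
    def test_zero_count_rate(self):
        assert rate_per_mb(0, 1_000_000) == 0.0

    def test_identical_rates_fold_one(self):
        assert fold_vs_background(10, 1_000_000, 100, 10_000_000) == pytest.approx(1.0)

    def test_fold_equals_expected_count_form(self):
        obs, obs_bp, bg, bg_bp = 394, 10_455_007, 3122, 210_786_169
        expected = bg * obs_bp / bg_bp
        assert fold_vs_background(obs, obs_bp, bg, bg_bp) == pytest.approx(obs / expected)


class TestZscoreNormal:
    def test_observed_equals_mean(self):
        z, p = zscore_normal_p(7.0, 7.0, 2.0)
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_tail_agrees_with_erfc(self):
        """Upper normal tail equals erfc(z/sqrt(2))/2 from the C library."""
        for z0 in (-2.0, 0.5, 3.0, 8.0, 10.25):
            _, p = zscore_normal_p(z0, 0.0, 1.0)
            assert p == pytest.approx(0.5 * math.erfc(z0 / math.sqrt(2)), rel=1e-12)


class TestMannWhitney:
    def test_identical_samples(self):
        p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.1)

    def test_small_sample_exact_enumeration(self):
        """p for {1,2,3} vs {10,20,30}, 'less', equals 1/C(6,3) by enumeration."""
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        # enumerate all C(6,3)=20 assignments of ranks to group a
        pooled = sorted(a + b)
        u_obs = sum(1 for x in a for y in b if x < y)  # U of b over a... a below b
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            aa = [pooled[i] for i in combo]
            bb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in aa for y in bb if x < y)
            total += 1
            if u >= u_obs:  # as or more extreme towards 'a less than b'
                count += 1
        assert mann_whitney_u(a, b, "less") == pytest.approx(count / total)

    def test_shifted_normals_strongly_significant(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        assert mann_whitney_u(a, b, "less") < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestQuantile:
    def test_linear_interpolation_convention(self):
        assert quantile(range(1, 11), 0.1) == pytest.approx(1.9)

    def test_extremes(self, rng):
        v = rng.normal(size=50)
        assert quantile(v, 0.0) == v.min()
        assert quantile(v, 1.0) == v.max()

    def test_matches_sort_and_index_oracle(self, rng):
        v = rng.normal(size=37)
        s = np.sort(v)
        for q in (0.1, 0.25, 0.5, 0.9):
            h = q * (len(v) - 1)
            lo, frac = int(math.floor(h)), h - math.floor(h)
            expected = s[lo] + frac * (s[min(lo + 1, len(v) - 1)] - s[lo])
            assert quantile(v, q) == pytest.approx(expected)


class TestPlacementNull:
    def toy_regions(self):
        return RegionSet([GenomicInterval("chr1", 0, 20)])

    def test_pair_counting_matches_bruteforce(self, rng):
        for _ in range(20):
            a = rng.integers(0, 500, size=30)
            b = rng.integers(0, 500, size=40)
            brute = 0
            for x in a:
                for y in b:
                    if y >= x + 10 and y - (x + 10) <= 40:
                        brute += 1
                    elif x >= y + 6 and x - (y + 6) <= 40:
                        brute += 1
            assert count_pairs_vectorised(a, 10, b, 6, 40) == brute

    def test_toy_universe_mean_matches_exact_enumeration(self):
        """One 6-mer + one 10-mer in a 20 bp region: exact pair probability
        by enumeration over all (20-10+1)*(20-6+1) placements."""
        pair = 0
        total = 0
        for a in range(20 - 10 + 1):          # 10-mer start
            for b in range(20 - 6 + 1):       # 6-mer start
                total += 1
                if (b >= a + 10 and b - (a + 10) <= 40) or \
                   (a >= b + 6 and a - (b + 6) <= 40):
                    pair += 1
        exact = pair / total
        n_sims = 4000
        null = placement_null(self.toy_regions(), 1, 10, 1, 6,
                              max_gap=40, n_sims=n_sims, seed=11)
        se = math.sqrt(exact * (1 - exact) / n_sims)
        assert abs(null.mean - exact) < 3 * se

    def test_reproducible_from_seed(self):
        regions = RegionSet([GenomicInterval("chr1", 0, 500),
                             GenomicInterval("chr1", 900, 1400)])
        n1 = placement_null(regions, 5, 10, 8, 6, n_sims=50, seed=42)
        n2 = placement_null(regions, 5, 10, 8, 6, n_sims=50, seed=42)
        assert n1.counts == n2.counts

    def test_self_consistency_z_small_under_null(self):
        regions = RegionSet([GenomicInterval("chr1", i * 3000, i * 3000 + 2000)
                             for i in range(10)])
        null = placement_null(regions, 30, 10, 60, 6, n_sims=400, seed=3)
        # draw an observed value from the same null
        obs_null = placement_null(regions, 30, 10, 60, 6, n_sims=2, seed=99)
        z, _ = zscore_normal_p(obs_null.counts[0], null.mean, null.sd)
        assert abs(z) < 4

    def test_z_grows_with_inflated_observation(self):
        regions = RegionSet([GenomicInterval("chr1", i * 3000, i * 3000 + 2000)
                             for i in range(10)])
        null = placement_null(regions, 30, 10, 60, 6, n_sims=300, seed=3)
        zs = [zscore_normal_p(null.mean * f, null.mean, null.sd)[0]
              for f in (1.2, 1.5, 2.0)]
        assert zs[0] > 0 and zs == sorted(zs)

    def test_region_shorter_than_site_excluded(self):
        regions = RegionSet([GenomicInterval("chr1", 0, 4),
                             GenomicInterval("chr1", 100, 400)])
        null = placement_null(regions, 2, 10, 2, 6, n_sims=20, seed=0)
        assert null.n_sims == 20  # 4 bp region hosts neither site length

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError):
            placement_null(self.toy_regions(), 1, 10, 1, 6, n_sims=1, seed=0)

    def test_empirical_p_definition(self):
        regions = self.toy_regions()
        null = placement_null(regions, 1, 10, 1, 6, n_sims=100, seed=7, observed=0)
        assert null.p_empirical == (1 + sum(c >= 0 for c in null.counts)) / 101
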