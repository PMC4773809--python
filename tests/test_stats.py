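"""Differentiation statistics, HWE exact test, bootstrap, rank tests.

The independent oracles here are deliberately naive re-derivations
(explicit loops, exact rational arithmetic, brute-force enumeration) kept
separate from the library's vectorized implementations.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import ptc_popgen as pp
from ptc_popgen.polarize import PopAlleleCounts
from ptc_popgen.stats import multilocus_theta, theta_statistic


# -- independent oracles ---------------------------------------------------

def naive_theta(ns, ps, hs):
    """Scalar Weir-Cockerham components, written longhand from the
    moment-estimator definitions."""
    r = len(ns)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c, a / (a + b + c)


def hwe_enumeration_pvalue(nAA, nAa, naa):
    """Exact HWE p-value by full enumeration of genotype tables with the
    observed allele counts, in exact rational arithmetic."""
    n = nAA + nAa + naa
    na = 2 * naa + nAa
    probs = {}
    for het in range(na % 2, min(na, 2 * n - na) + 1, 2):
        hom_a = (na - het) // 2
        hom_A = n - het - hom_a
        if hom_A < 0:
            continue
        w = (Fraction(math.factorial(n),
                      math.factorial(hom_A) * math.factorial(het) * math.factorial(hom_a))
             * Fraction(2) ** het)
        probs[het] = w
    total = sum(probs.values())
    p_obs = probs[nAa] / total
    return float(sum(v for v in probs.values() if Fraction(v, total) <= p_obs) / total)


def wilcoxon_enumeration_pvalue(diffs):
    """Two-sided signed-rank p-value by enumerating all sign assignments."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = min(ranks[np.array(d) > 0].sum(), ranks[np.array(d) < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        count += w <= w_obs
    return count / 2 ** n


# -- genotype spectra ------------------------------------------------------

class TestSpectrum:
    def _panel(self):
        return pp.PanelMap({"a": "P1", "b": "P1", "c": "P2", "d": "P2"},
                           {"P1": "G", "P2": "G"})

    def test_dosage_tabulation(self):
        per, pooled = pp.genotype_spectrum(np.array([0, 0, 1, 2], dtype=np.int8),
                                           ["a", "b", "c", "d"], self._panel())
        assert per["P1"] == (2, 0, 0) and per["P2"] == (0, 1, 1)
        assert pooled == (2, 1, 1)

    def test_all_missing_gives_zero_counts(self):
        per, pooled = pp.genotype_spectrum(np.array([-1] * 4, dtype=np.int8),
                                           ["a", "b", "c", "d"], self._panel())
        assert pooled == (0, 0, 0)

    def test_pooled_is_sum_of_populations(self, rng):
        d = rng.integers(-1, 3, size=4).astype(np.int8)
        per, pooled = pp.genotype_spectrum(d, ["a", "b", "c", "d"], self._panel())
        for i in range(3):
            assert pooled[i] == sum(c[i] for c in per.values())


class TestHwe:
    def test_expected_frequencies_closed_form(self):
        # q = 0.2 -> expected genotype frequencies (0.64, 0.32, 0.04)
        res = pp.hwe_test(64, 32, 4)
        assert res.q == pytest.approx(0.2)
        assert res.expected == pytest.approx((0.64, 0.32, 0.04))

    def test_perfect_hwe_counts_give_p_one(self):
        assert pp.hwe_test(25, 50, 25).p_value == pytest.approx(1.0)

    def test_monomorphic_p_one(self):
        assert pp.hwe_test(30, 0, 0).p_value == 1.0

    @pytest.mark.parametrize("counts", [(20, 10, 20), (45, 2, 3), (10, 30, 10),
                                        (0, 10, 40), (17, 23, 9)])
    def test_matches_full_enumeration(self, counts):
        assert pp.hwe_test(*counts).p_value == pytest.approx(
            hwe_enumeration_pvalue(*counts), rel=1e-10)

    def test_random_fixtures_match_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 51))
            nAa = int(rng.integers(0, n + 1))
            naa = int(rng.integers(0, n - nAa + 1))
            counts = (n - nAa - naa, nAa, naa)
            assert pp.hwe_test(*counts).p_value == pytest.approx(
                hwe_enumeration_pvalue(*counts), rel=1e-10)

    def test_zero_genotypes_error(self):
        with pytest.raises(ValueError):
            pp.hwe_test(0, 0, 0)


class TestHeterozygosity:
    def test_monomorphic_population(self):
        per, pooled = pp.heterozygosity({"P1": PopAlleleCounts(10, 0, 0),
                                         "P2": PopAlleleCounts(5, 4, 1)})
        assert per["P1"] == (0.0, 0.0)

    def test_single_heterozygote_small_sample_correction(self):
        per, _ = pp.heterozygosity({"P1": PopAlleleCounts(0, 1, 0),
                                    "P2": PopAlleleCounts(1, 0, 0)})
        assert per["P1"] == (1.0, pytest.approx(1.0))

    def test_direct_probability_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 100))
            nAa = int(rng.integers(0, n + 1))
            naa = int(rng.integers(0, n - nAa + 1))
            c = PopAlleleCounts(n - nAa - naa, nAa, naa)
            per, _ = pp.heterozygosity({"P1": c, "P2": PopAlleleCounts(2, 1, 1)})
            q = c.n_a / (2 * n)
            expected = (2 * n / (2 * n - 1)) * (1 - q ** 2 - (1 - q) ** 2)
            assert per["P1"][1] == pytest.approx(expected)


class TestWeirCockerham:
    def test_fixed_populations_give_theta_one(self):
        for n in (2, 5, 40):
            counts = {"P1": PopAlleleCounts(0, 0, n), "P2": PopAlleleCounts(n, 0, 0)}
            res = pp.differentiation(counts)
            assert res.theta == pytest.approx(1.0)

    def test_identical_large_populations_near_zero(self):
        # same frequency, HWE genotype counts in both pops
        counts = {"P1": PopAlleleCounts(640, 320, 40),
                  "P2": PopAlleleCounts(640, 320, 40)}
        res = pp.differentiation(counts)
        assert abs(res.theta) < 0.002

    def test_matches_naive_oracle_exactly(self, rng):
        for _ in range(50):
            ns = rng.integers(2, 80, size=3).astype(float)
            ps = rng.uniform(0.01, 0.99, size=3)
            hs = np.minimum(rng.uniform(0, 1, size=3), 2 * ps * (1 - ps) * 1.5)
            a, b, c, th = pp.weir_cockerham_theta(ns, ps, hs)
            oa, ob, oc, oth = naive_theta(ns.tolist(), ps.tolist(), hs.tolist())
            assert th == pytest.approx(oth, abs=1e-12)
            assert (a, b, c) == pytest.approx((oa, ob, oc), abs=1e-12)

    def test_globally_monomorphic_undefined(self):
        counts = {"P1": PopAlleleCounts(10, 0, 0), "P2": PopAlleleCounts(10, 0, 0)}
        assert np.isnan(pp.differentiation(counts).theta)

    def test_invariant_to_population_ordering(self, rng):
        ns = rng.integers(5, 50, size=4).astype(float)
        ps = rng.uniform(0.05, 0.95, size=4)
        hs = 2 * ps * (1 - ps)
        _, _, _, t1 = pp.weir_cockerham_theta(ns, ps, hs)
        perm = rng.permutation(4)
        _, _, _, t2 = pp.weir_cockerham_theta(ns[perm], ps[perm], hs[perm])
        assert t1 == pytest.approx(t2)

    def test_multilocus_recovery_beats_per_locus_mean(self):
        cfg = pp.SimulationConfig(n_populations=4, samples_per_population=100,
                                  n_loci=500, differentiation_F=0.3, seed=21)
        ds = pp.simulate_populations(cfg)
        n, p, h = pp.pop_allele_stats(ds.derived_dosages(), ds.pop_indices())
        ml = multilocus_theta(n, p, h)
        assert abs(ml - 0.3) < abs(np.nanmean(pp.weir_cockerham_theta(n, p, h)[3]) - 0.3)


class TestGstFamily:
    def test_fixed_populations_all_one(self):
        counts = {"P1": PopAlleleCounts(0, 0, 30), "P2": PopAlleleCounts(30, 0, 0)}
        r = pp.differentiation(counts)
        assert (r.H_S, r.H_T) == (0.0, pytest.approx(0.5))
        assert (r.G_ST, r.G_prime_ST, r.D) == pytest.approx((1.0, 1.0, 1.0))

    def test_identical_populations_all_zero(self):
        counts = {"P1": PopAlleleCounts(25, 50, 25), "P2": PopAlleleCounts(25, 50, 25)}
        r = pp.differentiation(counts)
        assert (r.G_ST, r.G_prime_ST, r.D) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_three_populations_closed_form(self):
        # p = (0.2, 0.5, 0.8), n = 50 each: evaluate the three closed forms
        n = np.array([50.0, 50.0, 50.0])
        p = np.array([0.2, 0.5, 0.8])
        H_S, H_T, G, Gp, D = pp.gst_family(n, p)
        hs = np.mean(2 * p * (1 - p))
        ht = 2 * 0.5 * 0.5
        assert H_S == pytest.approx(hs) and H_T == pytest.approx(ht)
        assert G == pytest.approx((ht - hs) / ht)
        assert Gp == pytest.approx(G * (2 + hs) / (2 * (1 - hs)))
        assert D == pytest.approx(1.5 * (ht - hs) / (1 - hs))

    def test_ordering_on_differentiated_loci(self, rng):
        # D and G'_ST dominate G_ST when within-population diversity > 0
        for _ in range(20):
            n = rng.integers(20, 60, size=3).astype(float)
            p = rng.uniform(0.2, 0.8, size=3)
            if p.std() < 0.15:
                continue
            _, _, G, Gp, D = pp.gst_family(n, p)
            assert Gp >= G - 1e-12 and D >= G - 1e-12


class TestBootstrap:
    def _pops(self, rng, p1=0.3, p2=0.6, n=50):
        return {"P1": rng.binomial(2, p1, n).astype(np.int8),
                "P2": rng.binomial(2, p2, n).astype(np.int8)}

    def test_degenerate_data_zero_width(self):
        pops = {"P1": np.ones(20, dtype=np.int8), "P2": np.ones(20, dtype=np.int8)}
        ci = pp.bootstrap_ci(lambda g: float(np.mean([x.mean() for x in g.values()])),
                             pops, B=100, seed=1)
        assert ci == (1.0, 1.0)

    def test_same_seed_identical(self, rng):
        pops = self._pops(rng)
        a = pp.bootstrap_ci(theta_statistic, pops, B=200, seed=5)
        b = pp.bootstrap_ci(theta_statistic, pops, B=200, seed=5)
        assert a == b

    def test_interval_contains_point_estimate(self, rng):
        pops = self._pops(rng, n=80)
        point = theta_statistic(pops)
        ci = pp.bootstrap_ci(theta_statistic, pops, B=500, seed=9)
        assert ci[0] <= point <= ci[1]

    def test_mostly_undefined_reports_missing(self):
        pops = {"P1": np.zeros(10, dtype=np.int8), "P2": np.zeros(10, dtype=np.int8)}
        with pytest.warns(UserWarning):
            assert pp.bootstrap_ci(theta_statistic, pops, B=50, seed=2) is None


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning):
            assert pp.compare_cohort_daf([1, 2, 3], [1, 2, 3]) == 1.0

    def test_six_unit_shifts_exact(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 3, 4, 5, 6, 7]
        assert pp.compare_cohort_daf(x, y) == pytest.approx(0.03125)

    def test_matches_enumeration_small_n(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 11))
            x = rng.uniform(0, 10, n)
            y = x + rng.normal(0, 1, n)
            assert pp.compare_cohort_daf(x, y) == pytest.approx(
                wilcoxon_enumeration_pvalue(x - y), abs=1e-9)
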