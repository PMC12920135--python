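"""Weir-Cockerham Fst: oracle equivalence, boundary cases, asFst contrast."""

import numpy as np
import pytest

from admixfreq.fst import (asfst_per_variant, compare_asfst, pairwise_state_fst,
                           wc_fst)
from admixfreq.frequencies import allele_frequency
from admixfreq.masking import mask

from conftest import random_haps_and_calls
from test_masking import toy_haps


# ---------------------------------------------------------------------------
# independent oracles: literal nested-ANOVA sums of squares over observations
# ---------------------------------------------------------------------------

def anova_haploid_oracle(alleles_by_pop):
    """theta from a per-observation two-level ANOVA on 0/1 allele indicators."""
    r = len(alleles_by_pop)
    n = np.array([len(a) for a in alleles_by_pop], float)
    N = n.sum()
    p = np.array([np.mean(a) for a in alleles_by_pop])
    pbar = sum(a.sum() for a in alleles_by_pop) / N
    ssa = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p))
    ssw = sum(((a - pi) ** 2).sum() for a, pi in zip(alleles_by_pop, p))
    msa = ssa / (r - 1)
    msw = ssw / (N - r)
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    a = (msa - msw) / nc
    b = msw
    return a, b, a / (a + b)


def anova_diploid_oracle(genotypes_by_pop):
    """a, b, c from a three-level ANOVA (populations / individuals / gametes).

    ``genotypes_by_pop``: list of (n_i, 2) 0/1 arrays.  Mean squares follow
    the classic decomposition; components are the moment estimators
    a=(MSP-MSI)/(2 nc), b=(MSI-MSG)/2, c=MSG.
    """
    r = len(genotypes_by_pop)
    n = np.array([len(g) for g in genotypes_by_pop], float)
    N = n.sum()
    pbar = sum(g.sum() for g in genotypes_by_pop) / (2 * N)
    p = np.array([g.mean() for g in genotypes_by_pop])
    ssp = sum(2 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p))
    ssi = sum(((g.mean(axis=1) - pi) ** 2).sum() * 2
              for g, pi in zip(genotypes_by_pop, p))
    ssg = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum()
              for g in genotypes_by_pop)
    msp = ssp / (r - 1)
    msi = ssi / (N - r)
    msg = ssg / N
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    a = (msp - msi) / (2 * nc)
    b = (msi - msg) / 2
    c = msg
    return a, b, c


class TestWcFstHaploid:
    def test_fixed_difference_gives_theta_one(self):
        res = wc_fst(np.array([[0, 10]]), np.array([[10, 10]]))
        assert res.per_site["theta"].item() == pytest.approx(1.0)

    def test_null_limit_near_zero(self):
        rng = np.random.default_rng(6)
        alt = rng.binomial(2000, 0.3, size=(200, 2))
        called = np.full((200, 2), 2000)
        res = wc_fst(alt, called)
        assert abs(res.weighted) < 0.002

    @pytest.mark.parametrize("r", [2, 3])
    def test_matches_anova_oracle_on_random_instances(self, r):
        rng = np.random.default_rng(42 + r)
        for _ in range(500):
            pops = [rng.integers(0, 2, size=rng.integers(2, 30)).astype(float)
                    for _ in range(r)]
            alt = np.array([[p.sum() for p in pops]])
            called = np.array([[len(p) for p in pops]])
            res = wc_fst(alt, called)
            a, b, theta = anova_haploid_oracle(pops)
            if np.isnan(res.per_site["theta"].item()):
                assert a + b == pytest.approx(0, abs=1e-12)
                continue
            assert res.per_site["a"].item() == pytest.approx(a, abs=1e-12)
            assert res.per_site["b"].item() == pytest.approx(b, abs=1e-12)
            assert res.per_site["theta"].item() == pytest.approx(theta, abs=1e-12)

    def test_population_with_no_data_rejected(self):
        with pytest.raises(ValueError):
            wc_fst(np.array([[1, 0]]), np.array([[10, 0]]))

    def test_negative_theta_retained(self):
        # slightly under-dispersed configuration yields a negative estimate
        alt = np.array([[5, 5]])
        called = np.array([[10, 10]])
        res = wc_fst(alt, called)
        assert res.per_site["theta"].item() < 0


class TestWcFstDiploid:
    def test_matches_three_level_anova_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            pops = [rng.integers(0, 2, size=(rng.integers(2, 20), 2)).astype(float)
                    for _ in range(2)]
            alt = np.array([[g.sum() for g in pops]])
            called = np.array([[2 * len(g) for g in pops]])
            het = np.array([[np.mean(g[:, 0] != g[:, 1]) for g in pops]])
            n_ind = np.array([[len(g) for g in pops]])
            res = wc_fst(alt, called, het_by_pop=het, n_ind_by_pop=n_ind)
            a, b, c = anova_diploid_oracle(pops)
            if np.isnan(res.per_site["theta"].item()):
                assert a + b + c == pytest.approx(0, abs=1e-12)
                continue
            assert res.per_site["a"].item() == pytest.approx(a, abs=1e-12)
            assert res.per_site["b"].item() == pytest.approx(b, abs=1e-12)
            assert res.per_site["c"].item() == pytest.approx(c, abs=1e-12)

    def test_worked_example_p02_vs_p06(self):
        # 5 diploids at p=0.2 (2 hets) vs 5 at p=0.6 (2 hom alt + 2 hets)
        g1 = np.array([[0, 1], [0, 1], [0, 0], [0, 0], [0, 0]], float)
        g2 = np.array([[1, 1], [1, 1], [0, 1], [0, 1], [0, 0]], float)
        res = wc_fst(np.array([[g1.sum(), g2.sum()]]),
                     np.array([[10, 10]]),
                     het_by_pop=np.array([[0.4, 0.4]]),
                     n_ind_by_pop=np.array([[5, 5]]))
        a, b, c = anova_diploid_oracle([g1, g2])
        assert res.per_site["theta"].item() == pytest.approx(a / (a + b + c),
                                                             abs=1e-12)


class TestPairwiseAndMaskedConsistency:
    def test_matrix_symmetric_with_zero_diagonal(self):
        haps, calls = random_haps_and_calls(2, n_samples=12)
        strata = {s: f"g{i % 3}" for i, s in enumerate(haps.samples)}
        W, M = pairwise_state_fst(haps, strata)
        assert np.allclose(W.to_numpy(), W.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(W.to_numpy()), 0)

    def test_duplicated_strata_give_nonpositive_theta(self):
        gt = np.array([[0, 1, 1], [1, 0, 0]] * 8, dtype=np.int8)
        haps = toy_haps(gt)
        strata = {s: ("a" if i < 4 else "b") for i, s in enumerate(haps.samples)}
        W, _ = pairwise_state_fst(haps, strata, mode="haploid")
        assert W.loc["a", "b"] <= 0

    def test_single_sample_stratum_skipped(self):
        haps, _ = random_haps_and_calls(5, n_samples=5)
        strata = {s: ("solo" if i == 0 else "rest")
                  for i, s in enumerate(haps.samples)}
        W, _ = pairwise_state_fst(haps, strata)
        assert np.isnan(W.loc["solo", "rest"])

    def test_masked_route_equals_count_route(self):
        """asFst from masked haplotypes == wc_fst on the per-ancestry counts."""
        haps, calls = random_haps_and_calls(8, n_samples=20, missing_rate=0.0)
        masked = mask(haps, calls, "IND")
        strata = {s: ("n" if i % 2 else "s") for i, s in enumerate(haps.samples)}
        tab = allele_frequency(masked, strata)
        piv_alt = tab.pivot(index="variant", columns="stratum", values="alt_count")
        piv_called = tab.pivot(index="variant", columns="stratum",
                               values="called_count")
        order = masked.variant_ids()
        alt = piv_alt.loc[order, ["n", "s"]].to_numpy()
        called = piv_called.loc[order, ["n", "s"]].to_numpy()
        direct = wc_fst(alt, called)
        via_matrix = pairwise_state_fst(masked, strata, mode="haploid")[0]
        assert via_matrix.loc["n", "s"] == pytest.approx(direct.weighted, abs=1e-12)


class TestCompareAsfst:
    def test_identical_vectors(self):
        x = np.array([0.1, 0.2, 0.3, 0.1, 0.2])
        out = compare_asfst(x, x.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_textbook_welch_on_toy_pair(self):
        ind = [0.01, 0.02, 0.03, 0.02, 0.02]
        eur = [0.02, 0.04, 0.03, 0.05, 0.03]
        out = compare_asfst(ind, eur)
        # hand computation: t = 2.3333, df = 6.6804 (Welch-Satterthwaite)
        assert out["t"] == pytest.approx(2.3333333, abs=1e-6)
        assert out["p"] == pytest.approx(0.0540738, abs=1e-6)
        assert out["ci_low"] == pytest.approx(-0.000326504, abs=1e-8)
        assert out["ci_high"] == pytest.approx(0.028326504, abs=1e-8)

    def test_detects_shifted_distributions(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            ind = r.normal(0.03, 0.05, 1000)
            eur = r.normal(0.02, 0.05, 1000)
            if compare_asfst(ind, eur)["p"] < 0.05:
                hits += 1
        assert hits > 16  # > 80% power at delta=0.01, sd=0.05, n=1000

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compare_asfst([0.1], [0.2, 0.3])


def test_asfst_per_variant_applies_maf_filter():
    haps, calls = random_haps_and_calls(12, n_samples=30, missing_rate=0.0)
    strata = {s: ("n" if i % 2 else "s") for i, s in enumerate(haps.samples)}
    masked = mask(haps, calls, "IND")
    out = asfst_per_variant(masked, strata, min_maf=0.05)
    maf = np.minimum(out["pooled_freq"], 1 - out["pooled_freq"])
    assert (maf > 0.05).all()
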