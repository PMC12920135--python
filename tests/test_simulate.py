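"""Tract simulation, allele assignment and confusion-matrix corruption."""

import numpy as np
import pandas as pd
import pytest

from admixfreq.ancestry import ConfusionMatrix
from admixfreq.haplotypes import read_vcf
from admixfreq.simulate import (BP_PER_MORGAN, ConfigError, SimulationConfig,
                                assign_alleles, corrupt_ancestry,
                                simulate_cohort, simulate_full_cohort,
                                simulate_tracts)

PAPER_PROPS = (0.04, 0.30, 0.01, 0.65)  # AFR, EUR, EAS, IND


def small_config(**kw):
    defaults = dict(n_individuals=50, n_sites=10, seed=3,
                    proportions_by_stratum=np.array([PAPER_PROPS]))
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateTracts:
    def test_degenerate_proportions_give_single_tract(self):
        cfg = small_config(proportions_by_stratum=np.array([[1.0, 0, 0, 0]]))
        tr = simulate_tracts(cfg, n_haplotypes=20).merged()
        for h in range(20):
            assert len(tr.breaks[0][h]) == 0
            assert tr.codes[0][h].tolist() == [0]

    def test_mean_indigenous_fraction_matches_proportions(self):
        cfg = small_config(chrom_lengths_morgans=(3.0,), generations=16)
        tr = simulate_tracts(cfg, n_haplotypes=1000,
                             rng=np.random.default_rng(11))
        frac = tr.genome_fractions()[:, 3]
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.65) < 3 * se

    def test_breakpoint_count_matches_poisson_oracle(self):
        g, L, n = 16, 1.0, 4000
        cfg = small_config(generations=g, chrom_lengths_morgans=(L,))
        tr = simulate_tracts(cfg, n_haplotypes=n, rng=np.random.default_rng(5))
        counts = np.array([len(tr.breaks[0][h]) for h in range(n)])
        # brute-force oracle: raw Poisson(g*L) draws
        oracle = np.random.default_rng(99).poisson(g * L, size=200_000)
        se = np.sqrt(counts.var(ddof=1) / n + oracle.var(ddof=1) / len(oracle))
        assert abs(counts.mean() - oracle.mean()) < 3 * se

    def test_tract_tiling_is_exact(self):
        cfg = small_config(chrom_lengths_morgans=(0.7, 1.3))
        tr = simulate_tracts(cfg, n_haplotypes=30)
        for ci, L in enumerate(tr.chrom_lengths):
            for h in range(30):
                edges = np.concatenate(([0.0], tr.breaks[0 + ci][h], [L]))
                assert np.isclose(np.diff(edges).sum(), L, atol=1e-12)
                assert (np.diff(edges) >= 0).all()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigError):
            small_config(proportions_by_stratum=np.array([[0.5, 0.2, 0.1, 0.1]]))
        with pytest.raises(ConfigError):
            small_config(proportions_by_stratum=np.array([[1.2, -0.2, 0, 0]]))

    def test_determinism_under_fixed_seed(self):
        cfg = small_config(seed=42)
        a = simulate_tracts(cfg, n_haplotypes=10)
        b = simulate_tracts(cfg, n_haplotypes=10)
        for h in range(10):
            assert np.array_equal(a.breaks[0][h], b.breaks[0][h])
            assert np.array_equal(a.codes[0][h], b.codes[0][h])


class TestAssignAlleles:
    @pytest.mark.parametrize("f,expected", [(0.0, 0), (1.0, 1)])
    def test_extreme_frequencies(self, f, expected):
        cfg = small_config(per_ancestry_freqs=np.full((10, 4), f))
        tr = simulate_tracts(cfg, n_haplotypes=40)
        haps = assign_alleles(tr, cfg)
        assert (haps.alleles == expected).all()

    def test_single_ancestry_frequency_in_binomial_interval(self):
        n_hap = 6000
        cfg = small_config(
            proportions_by_stratum=np.array([[0, 0, 0, 1.0]]),
            per_ancestry_freqs=np.full((10, 4), 0.1), n_sites=10)
        tr = simulate_tracts(cfg, n_haplotypes=n_hap)
        haps = assign_alleles(tr, cfg, rng=np.random.default_rng(8))
        f_hat = haps.alleles.mean()   # pooled over 10 iid sites
        n_draws = n_hap * 10
        half = 2.58 * np.sqrt(0.1 * 0.9 / n_draws)
        assert abs(f_hat - 0.1) < half

    def test_allele_depends_on_covering_tract_ancestry(self):
        freqs = np.zeros((10, 4))
        freqs[:, 3] = 1.0  # only Indigenous tracts carry the alternate allele
        cfg = small_config(per_ancestry_freqs=freqs)
        tr = simulate_tracts(cfg, n_haplotypes=50)
        haps = assign_alleles(tr, cfg)
        codes = tr.ancestry_at(0, cfg.site_table()["gpos"].to_numpy())
        assert np.array_equal(haps.alleles == 1, codes == 3)


class TestCorruptAncestry:
    def test_identity_matrix_preserves_tracts(self):
        cfg = small_config()
        tr = simulate_tracts(cfg, n_haplotypes=20)
        out = corrupt_ancestry(tr, ConfusionMatrix.identity(), rng=1)
        gpos = np.linspace(0, 1, 501)[:-1]
        assert np.array_equal(tr.ancestry_at(0, gpos), out.ancestry_at(0, gpos))

    def test_deterministic_row_relabels_everything(self):
        m = np.eye(4)
        m[0] = [0, 1, 0, 0]  # true AFR always called EUR
        cfg = small_config(proportions_by_stratum=np.array([[1.0, 0, 0, 0]]))
        tr = simulate_tracts(cfg, n_haplotypes=10)
        out = corrupt_ancestry(tr, ConfusionMatrix(m), rng=2)
        gpos = np.linspace(0, 1, 100, endpoint=False)
        assert (out.ancestry_at(0, gpos) == 1).all()

    def test_assignment_marginals_match_confusion_rows(self):
        m = np.full((4, 4), 0.05)
        np.fill_diagonal(m, 0.85)
        cm = ConfusionMatrix(m)
        cfg = small_config(proportions_by_stratum=np.array([[1.0, 0, 0, 0]]),
                           chrom_lengths_morgans=(2.0,))
        tr = simulate_tracts(cfg, n_haplotypes=100)
        out = corrupt_ancestry(tr, cm, window_cm=0.2, rng=3)
        mids = np.arange(0.001, 2.0, 0.002)
        assigned = out.ancestry_at(0, mids)
        n = assigned.size
        for k in range(4):
            rate = (assigned == k).mean()
            se = np.sqrt(m[0, k] * (1 - m[0, k]) / n)
            assert abs(rate - m[0, k]) < 4 * se

    def test_bad_window_rejected(self):
        cfg = small_config()
        tr = simulate_tracts(cfg, n_haplotypes=2)
        with pytest.raises(ValueError):
            corrupt_ancestry(tr, ConfusionMatrix.identity(), window_cm=0.0)


class TestSimulateCohort:
    def test_structural_counts(self, tmp_path):
        cfg = small_config(n_individuals=2, n_sites=5)
        paths = simulate_cohort(cfg, str(tmp_path))
        vcf_header = [l for l in open(paths["vcf"]) if l.startswith("#CHROM")][0]
        assert len(vcf_header.split("\t")) == 9 + 2
        msp_header = open(paths["msp"]).readlines()[1]
        assert len(msp_header.rstrip("\n").split("\t")) == 6 + 4

    def test_cline_monotone_in_latitude(self):
        cfg = SimulationConfig.cline(
            n_individuals=300, n_strata=3,
            north_proportions=(0.04, 0.66, 0.01, 0.29),
            south_proportions=(0.04, 0.11, 0.01, 0.84),
            n_sites=5, seed=9)
        haps, tracts, meta = simulate_full_cohort(cfg)
        frac_ind = tracts.genome_fractions()[:, 3]
        per_ind = (frac_ind[0::2] + frac_ind[1::2]) / 2
        means = pd.Series(per_ind, index=meta["latitude"]).groupby(level=0).mean()
        assert means.sort_index(ascending=True).is_monotonic_decreasing

    def test_seeded_outputs_byte_identical(self, tmp_path):
        cfg = small_config(n_individuals=5, n_sites=8, seed=13)
        p1 = simulate_cohort(cfg, str(tmp_path / "a"))
        p2 = simulate_cohort(cfg, str(tmp_path / "b"))
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_vcf_and_msp_are_cross_consistent(self, tmp_path):
        cfg = small_config(n_individuals=6, n_sites=8, seed=21)
        paths = simulate_cohort(cfg, str(tmp_path))
        haps = read_vcf(paths["vcf"])
        from admixfreq.ancestry import read_msp
        calls = read_msp(paths["msp"])
        assert haps.samples == calls.samples
        codes = calls.ancestry_at("1", haps.variants["pos"].to_numpy())
        assert (codes >= 0).all()  # every genotyped site covered by a tract
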