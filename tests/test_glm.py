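"""Per-variant GLM scan: calibration, recovery, classification, contrasts."""

import numpy as np
import pandas as pd
import pytest

from admixfreq.glm import (TERMS, build_predictors, effect_direction_contrast,
                           glm_scan, standardize, upset_categories)

from test_masking import toy_haps


def make_preds(n, seed=0):
    """Realistic predictor table: correlated ancestry fractions + geography."""
    rng = np.random.default_rng(seed)
    ind = np.clip(rng.beta(6, 3, n), 0.01, 0.99)
    afr = np.clip(rng.beta(2, 30, n), 0.001, 0.2)
    eas = np.full(n, 0.01)
    eur = np.clip(1 - ind - afr - eas, 0.0, 1.0)
    tot = ind + afr + eas + eur
    fr = pd.DataFrame({"AFR": afr / tot, "EUR": eur / tot, "EAS": eas / tot,
                       "IND": ind / tot},
                      index=[f"S{i:05d}" for i in range(n)])
    meta = pd.DataFrame({
        "sample_id": fr.index,
        "latitude": 15 + 17 * (1 - fr["IND"].to_numpy()) + rng.normal(0, 2, n),
        "longitude": rng.uniform(-115, -88, n),
    })
    return build_predictors(fr, meta), fr


def haps_from_dosage(dose, seed=1):
    """Phased HaplotypeSet whose per-individual alt counts equal ``dose``."""
    rng = np.random.default_rng(seed)
    n, m = dose.shape
    a0 = np.zeros((n, m), np.int8)
    a1 = np.zeros((n, m), np.int8)
    a0[dose == 2] = 1
    a1[dose == 2] = 1
    het = dose == 1
    which = rng.random((n, m)) < 0.5
    a0[het & which] = 1
    a1[het & ~which] = 1
    gt = np.empty((2 * n, m), np.int8)
    gt[0::2] = a0
    gt[1::2] = a1
    return toy_haps(gt, samples=[f"S{i:05d}" for i in range(n)])


class TestBuildPredictors:
    def test_single_ancestry_individual_has_fraction_one(self):
        fr = pd.DataFrame({"AFR": [0.0], "EUR": [0.0], "EAS": [0.0], "IND": [1.0]},
                          index=["S0"])
        meta = pd.DataFrame({"sample_id": ["S0", "S1"], "latitude": [1, 2.0],
                             "longitude": [3, 4.0]})
        with pytest.raises(ValueError):  # constant predictors cannot be z-scored
            build_predictors(fr, meta)

    def test_fractions_match_tract_length_sums(self):
        from admixfreq.simulate import SimulationConfig, simulate_tracts
        cfg = SimulationConfig(n_individuals=10, n_sites=5, seed=2)
        tr = simulate_tracts(cfg, n_haplotypes=20)
        samples = [f"S{i}" for i in range(10)]
        calls = tr.to_ancestry_calls(samples)
        got = calls.genome_fractions()
        # brute-force oracle: sum tract lengths per ancestry over each
        # individual's two haplotypes
        L = cfg.chrom_lengths_morgans[0]
        for i in range(10):
            for k, lab in enumerate(("AFR", "EUR", "EAS", "IND")):
                expect = sum(
                    np.diff(np.concatenate(([0.0], tr.breaks[0][j], [L])))[
                        tr.codes[0][j] == k].sum()
                    for j in (2 * i, 2 * i + 1)) / (2 * L)
                assert got.iloc[i][lab] == pytest.approx(expect, abs=1e-9)

    def test_standardization_is_exact(self):
        preds, _ = make_preds(200, seed=3)
        for col in ("z_ind", "z_afr", "z_lat", "z_lon"):
            assert abs(preds[col].mean()) < 1e-10
            assert abs(preds[col].std(ddof=0) - 1) < 1e-10

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.ones(10))


class TestGlmScan:
    def test_null_calibration_quick(self):
        """Type-I rate per term near alpha on null variants (small version)."""
        n, m = 300, 400
        preds, _ = make_preds(n, seed=5)
        rng = np.random.default_rng(6)
        dose = rng.binomial(2, 0.3, size=(n, m))
        haps = haps_from_dosage(dose)
        results, skipped = glm_scan(haps, preds)
        assert len(results) > 0.95 * m
        for t in TERMS:
            rate = (results[f"p_{t}"] < 0.05).mean()
            assert 0.02 < rate < 0.09  # wide band at m=400; tight check at scale

    def test_ancestry_effect_detected_and_recovered(self):
        n, m = 1000, 60
        preds, fr = make_preds(n, seed=7)
        b = 0.8
        eta = -0.5 + b * preds["z_ind"].to_numpy()
        p = 1 / (1 + np.exp(-eta))
        rng = np.random.default_rng(8)
        dose = rng.binomial(2, p[:, None], size=(n, m))
        haps = haps_from_dosage(dose)
        results, _ = glm_scan(haps, preds)
        assert (results["p_IND"] < 0.05).mean() > 0.95
        bias = results["beta_IND"].mean() - b
        se = results["beta_IND"].std(ddof=1) / np.sqrt(len(results))
        assert abs(bias) < 4 * se + 0.02

    def test_monomorphic_variants_skipped_with_reason(self):
        preds, _ = make_preds(50, seed=9)
        dose = np.zeros((50, 2), int)
        dose[:, 1] = np.random.default_rng(1).binomial(2, 0.5, 50)
        haps = haps_from_dosage(dose)
        results, skipped = glm_scan(haps, preds)
        assert skipped["reason"].str.contains("monomorphic").any()
        assert len(results) == 1

    def test_standardization_invariance_of_p_values(self):
        """Affine rescaling of predictors leaves Wald p-values unchanged."""
        n, m = 300, 10
        preds, _ = make_preds(n, seed=10)
        rng = np.random.default_rng(11)
        dose = rng.binomial(2, 0.4, size=(n, m))
        haps = haps_from_dosage(dose)
        r1, _ = glm_scan(haps, preds)
        raw = preds.copy()
        raw["z_ind"] = preds["ind_fraction"]
        raw["z_afr"] = preds["afr_fraction"]
        raw["z_lat"] = preds["latitude"]
        raw["z_lon"] = preds["longitude"]
        r2, _ = glm_scan(haps, raw)
        for t in TERMS:
            assert np.allclose(r1[f"p_{t}"], r2[f"p_{t}"], atol=1e-8)


class TestCategoriesAndContrasts:
    def fake_results(self, cats, betas=None):
        df = pd.DataFrame({"variant": [f"v{i}" for i in range(len(cats))],
                           "category": cats})
        for t in TERMS:
            df[f"beta_{t}"] = betas[t] if betas else 0.0
            df[f"p_{t}"] = 0.5
        return df

    def test_counts_sum_to_input_size(self):
        cats = ["IND", "IND+AFR", "unexplained", "IND", "LAT"]
        counts = upset_categories(self.fake_results(cats))
        assert counts.sum() == 5
        assert counts["IND"] == 2

    def test_category_matches_brute_force_tally(self):
        rng = np.random.default_rng(12)
        n, m = 400, 120
        preds, _ = make_preds(n, seed=13)
        dose = rng.binomial(2, 0.3, size=(n, m))
        haps = haps_from_dosage(dose)
        results, _ = glm_scan(haps, preds, alpha=0.05)
        counts = upset_categories(results)
        brute = {}
        for _, row in results.iterrows():
            key = "+".join(t for t in TERMS if row[f"p_{t}"] < 0.05) or "unexplained"
            brute[key] = brute.get(key, 0) + 1
        assert dict(counts) == brute

    def test_effect_direction_contrast_detects_heavier_negative_tail(self):
        rng = np.random.default_rng(14)
        beta = np.where(rng.random(1000) < 0.5, rng.normal(0.2, 0.05, 1000),
                        -np.abs(rng.normal(0.5, 0.1, 1000)))
        res = self.fake_results(["IND"] * 1000, betas={t: beta for t in TERMS})
        out = effect_direction_contrast(res, "IND")
        assert out["mean_abs_neg"] > out["mean_abs_pos"]
        assert out["p"] < 0.05

    def test_identical_magnitudes_give_t_zero(self):
        beta = np.array([0.3, -0.3, 0.3, -0.3, 0.3, -0.3])
        res = self.fake_results(["AFR"] * 6, betas={t: beta for t in TERMS})
        out = effect_direction_contrast(res, "AFR")
        assert out["t"] == pytest.approx(0.0)

    def test_empty_sign_group_reported_not_raised(self):
        res = self.fake_results(["LAT"] * 4,
                                betas={t: np.array([0.1, 0.2, 0.3, 0.4])
                                       for t in TERMS})
        out = effect_direction_contrast(res, "LAT")
        assert np.isnan(out["t"]) and "message" in out
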