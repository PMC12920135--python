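"""Per-variant GLM scan: ancestry vs geography as drivers of allele frequency.

Each variant's per-individual alternate-allele count (0/1/2) is modelled as
a binomial response with 2 trials on four standardized predictors — the
individual's Indigenous-American and African genome-wide ancestry fractions
and the latitude/longitude of their stratum — with a logit link, fit by
iteratively reweighted least squares (statsmodels).  European ancestry is
excluded: with four components summing to one and East Asian near zero, it
is close to a mirror of the Indigenous component.

A variant's "category" is the exact subset of terms with Wald p below
alpha (UpSet-style classification); the empty subset is reported as
``unexplained``.  No multiple-testing correction is applied by default; a
Benjamini–Hochberg mode is available.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .haplotypes import HaplotypeSet

logger = logging.getLogger(__name__)

TERMS = ("IND", "AFR", "LAT", "LON")
_TERM_COLUMNS = {"IND": "z_ind", "AFR": "z_afr", "LAT": "z_lat", "LON": "z_lon"}


def standardize(x: np.ndarray) -> np.ndarray:
    """Exact z-scoring; a constant column is a hard error (zero variance)."""
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant predictor")
    return (x - x.mean()) / sd


def build_predictors(ancestry_fractions: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-individual predictor table.

    Parameters
    ----------
    ancestry_fractions
        Per-sample genome fractions indexed by sample id with ancestry-label
        columns (from ``AncestryCalls.genome_fractions()`` or the
        simulator's truth tracts); rows must sum to 1.
    meta
        Table with ``sample_id``, ``latitude``, ``longitude``.

    Returns the merged table with standardized columns
    ``z_ind, z_afr, z_lat, z_lon``.
    """
    fr = ancestry_fractions
    if not np.allclose(fr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ancestry fractions must sum to 1 per individual")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = fr.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    out = pd.DataFrame(index=fr.index)
    out["ind_fraction"] = fr["IND"]
    out["afr_fraction"] = fr["AFR"]
    out["latitude"] = meta.loc[fr.index, "latitude"].astype(float)
    out["longitude"] = meta.loc[fr.index, "longitude"].astype(float)
    out["z_ind"] = standardize(out["ind_fraction"])
    out["z_afr"] = standardize(out["afr_fraction"])
    out["z_lat"] = standardize(out["latitude"])
    out["z_lon"] = standardize(out["longitude"])
    return out


def _design(preds: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([preds[_TERM_COLUMNS[t]].to_numpy() for t in TERMS])
    return sm.add_constant(X, prepend=True)


def glm_scan(
    haps: HaplotypeSet,
    preds: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "binomial",
    correction: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the per-variant GLM and classify each variant's significant terms.

    Parameters
    ----------
    haps
        Unmasked phased genotypes; individuals with missing alleles at a
        site are dropped for that site (trials < 2 excluded).
    preds
        Output of :func:`build_predictors`, indexed like ``haps.samples``.
    family
        ``"binomial"`` (default; logit on allele counts out of 2) or
        ``"gaussian"`` (identity link on the 0/1/2 dosage).
    correction
        ``None`` (raw p < alpha, the headline convention) or ``"bh"`` for
        per-term Benjamini–Hochberg at level alpha.

    Returns
    -------
    (results, skipped): per-variant coefficients/p-values/category, and a
    table of variants not fit (monomorphic, too few individuals, failed or
    separated fits) with reasons.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError("family must be 'binomial' or 'gaussian'")
    preds = preds.loc[haps.samples]
    X_full = _design(preds)
    dose = haps.dosage()  # (N, S) with NaN at partially-missing calls
    ids = haps.variant_ids().to_numpy()
    rows, skipped = [], []
    for s in range(haps.n_sites):
        y = dose[:, s]
        keep = ~np.isnan(y)
        n = int(keep.sum())
        if n < 5:
            skipped.append((ids[s], "fewer than 5 called individuals"))
            continue
        yk = y[keep]
        if yk.min() == yk.max():
            skipped.append((ids[s], "monomorphic"))
            continue
        X = X_full[keep]
        try:
            # saturating fits raise benign overflow/separation warnings; real
            # separation is caught below via the standard-error check
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if family == "binomial":
                    endog = np.column_stack([yk, 2 - yk])
                    fit = sm.GLM(endog, X,
                                 family=sm.families.Binomial()).fit(maxiter=50)
                else:
                    fit = sm.OLS(yk, X).fit()
            converged = bool(getattr(fit, "converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            skipped.append((ids[s], f"fit failed: {type(exc).__name__}"))
            continue
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        if not converged or not np.isfinite(pvals[1:]).all() or (bse[1:] > 1e3).any():
            skipped.append((ids[s], "non-converged or separated fit"))
            continue
        row = {"variant": ids[s], "n": n, "intercept": params[0]}
        for j, t in enumerate(TERMS, start=1):
            row[f"beta_{t}"] = params[j]
            row[f"se_{t}"] = bse[j]
            row[f"p_{t}"] = pvals[j]
        rows.append(row)
    results = pd.DataFrame(rows)
    skipped_df = pd.DataFrame(skipped, columns=["variant", "reason"])
    if len(results):
        sig = {}
        for t in TERMS:
            p = results[f"p_{t}"].to_numpy()
            if correction == "bh":
                sig[t] = multipletests(p, alpha=alpha, method="fdr_bh")[0]
            else:
                sig[t] = p < alpha
        results["category"] = [
            "+".join([t for t in TERMS if sig[t][i]]) or "unexplained"
            for i in range(len(results))
        ]
    if len(skipped_df):
        logger.info("glm_scan skipped %d variant(s)", len(skipped_df))
    return results, skipped_df


def upset_categories(results: pd.DataFrame) -> pd.Series:
    """Counts per exact significant-term combination (plus ``unexplained``).

    Categories are mutually exclusive, so the counts sum to the number of
    scanned (converged) variants.
    """
    if results.empty:
        raise ValueError("no scan results to categorize")
    return results["category"].value_counts()


def effect_direction_contrast(results: pd.DataFrame, term: str) -> dict:
    """Compare |beta| between positive- and negative-effect variants for a term.

    Welch two-sided t test over variants where the term is significant;
    zero-effect variants (exact ties) fall in neither group.
    """
    if term not in TERMS:
        raise KeyError(f"term must be one of {TERMS}")
    sub = results[results["category"].str.contains(term, regex=False)]
    beta = sub[f"beta_{term}"].to_numpy()
    pos, neg = np.abs(beta[beta > 0]), np.abs(beta[beta < 0])
    if len(pos) < 2 or len(neg) < 2:
        return {"term": term, "n_pos": len(pos), "n_neg": len(neg),
                "mean_abs_pos": float(np.mean(pos)) if len(pos) else np.nan,
                "mean_abs_neg": float(np.mean(neg)) if len(neg) else np.nan,
                "t": np.nan, "p": np.nan,
                "message": "a sign group has fewer than 2 members"}
    if pos.std(ddof=1) == 0 and neg.std(ddof=1) == 0 and pos.mean() == neg.mean():
        # degenerate equal-magnitude groups: no difference by construction
        res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
    else:
        res = stats.ttest_ind(pos, neg, equal_var=False)
    return {"term": term, "n_pos": len(pos), "n_neg": len(neg),
            "mean_abs_pos": float(np.mean(pos)), "mean_abs_neg": float(np.mean(neg)),
            "t": float(res.statistic), "p": float(res.pvalue)}
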