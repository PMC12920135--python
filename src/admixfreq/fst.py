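"""Weir–Cockerham Fst between geographic strata, on masked or unmasked data.

Ancestry-specific Fst (asFst) is the Weir & Cockerham (1984) estimator
computed on an ancestry-masked haplotype matrix: only alleles lying on
segments of one ancestry enter the counts, so per-site sample sizes vary
across sites and strata.

Two computational paths are exposed:

* ``haploid`` — masked data: masking breaks the pairing of an individual's
  two alleles, so alleles are treated as haploid observations and the
  within-individual component ``c`` is zero.  Components come from the
  two-level nested ANOVA moment estimators:

      a = (MSA - MSW) / n_c,   b = MSW,   theta = a / (a + b)

* ``diploid`` — unmasked genotypes: the full three-component estimator with
  the heterozygosity term ``c`` (equations as implemented by the classic
  --weir-fst-pop tools).

Negative per-site estimates are retained, not clipped.  Multi-site
summaries report both the "weighted" ratio-of-sums (headline) and the
mean-of-ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Per-site variance components and the two multi-site summaries.

    ``per_site`` columns: a, b, c, theta (NaN where a+b+c == 0), and the
    per-population called sample sizes.  ``weighted`` is
    ``sum(a) / sum(a+b+c)`` over usable sites; ``mean`` averages the
    per-site ratios.  ``n_excluded`` counts sites dropped for insufficient
    data (fewer than 2 called alleles in some population).
    """

    per_site: pd.DataFrame
    weighted: float
    mean: float
    n_excluded: int


def _wc_haploid_components(alt: np.ndarray, called: np.ndarray):
    """Two-level ANOVA components from per-site allele counts.

    ``alt``/``called``: (S, r) integer arrays of alternate and called allele
    counts for r populations.  Returns (a, b, usable) arrays of length S;
    sites where any population has < 2 called alleles are unusable.
    """
    n = called.astype(float)
    usable = (n >= 2).all(axis=1)
    r = n.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        N = n.sum(axis=1)
        pbar = alt.sum(axis=1) / N
        nc = (N - (n ** 2).sum(axis=1) / N) / (r - 1)
        msa = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
        msw = (n * p * (1 - p)).sum(axis=1) / (N - r)
        a = (msa - msw) / nc
        b = msw
    a[~usable] = np.nan
    b[~usable] = np.nan
    return a, b, usable


def _wc_diploid_components(n_ind: np.ndarray, p: np.ndarray, het: np.ndarray):
    """Weir & Cockerham (1984) a, b, c from per-population genotype summaries.

    ``n_ind``: (S, r) diploid sample sizes; ``p``: (S, r) alt-allele
    frequencies; ``het``: (S, r) observed heterozygote proportions.
    """
    n = n_ind.astype(float)
    usable = (n >= 1).all(axis=1) & (n.sum(axis=1) > n.shape[1])
    r = n.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=1)
        N = n.sum(axis=1)
        nc = (N - (n ** 2).sum(axis=1) / N) / (r - 1)
        pbar = (n * p).sum(axis=1) / N
        s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n * het).sum(axis=1) / N
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return a, b, c, usable


def wc_fst(
    alt_by_pop: np.ndarray,
    called_by_pop: np.ndarray,
    het_by_pop: np.ndarray | None = None,
    n_ind_by_pop: np.ndarray | None = None,
    variant_ids: np.ndarray | None = None,
) -> FstResult:
    """Weir–Cockerham Fst from per-site, per-population counts.

    With only allele counts (``alt_by_pop``, ``called_by_pop``; shape
    ``(S, r)``), the haploid reduction is used (``c = 0``).  Passing
    ``het_by_pop`` (observed heterozygote proportions) together with
    ``n_ind_by_pop`` (diploid sample sizes) selects the full diploid
    estimator; ``alt/called`` are then only used for the frequencies.
    """
    alt = np.atleast_2d(np.asarray(alt_by_pop))
    called = np.atleast_2d(np.asarray(called_by_pop))
    if alt.shape != called.shape or alt.shape[1] < 2:
        raise ValueError("need per-site alt/called counts for >= 2 populations")
    if (called.sum(axis=0) == 0).any():
        raise ValueError("a population has zero called alleles at every site")
    if het_by_pop is not None:
        if n_ind_by_pop is None:
            raise ValueError("diploid path needs n_ind_by_pop alongside het_by_pop")
        with np.errstate(invalid="ignore"):
            p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        a, b, c, usable = _wc_diploid_components(
            np.atleast_2d(np.asarray(n_ind_by_pop)), p,
            np.atleast_2d(np.asarray(het_by_pop)),
        )
    else:
        a, b, usable = _wc_haploid_components(alt, called)
        c = np.zeros_like(a)
        c[~usable] = np.nan
    denom = a + b + c
    informative = usable & (np.nan_to_num(denom, nan=0.0) != 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(informative, a / np.where(denom == 0, np.nan, denom), np.nan)
    per_site = pd.DataFrame({
        "variant": variant_ids if variant_ids is not None else np.arange(len(a)),
        "a": a, "b": b, "c": c, "theta": theta,
    })
    for j in range(called.shape[1]):
        per_site[f"n{j + 1}"] = called[:, j]
    weighted = (np.nansum(a[informative]) / np.nansum(denom[informative])
                if informative.any() else np.nan)
    mean = float(np.nanmean(theta)) if informative.any() else np.nan
    return FstResult(per_site=per_site, weighted=float(weighted), mean=mean,
                     n_excluded=int((~informative).sum()))


def _stratum_counts(haps: HaplotypeSet, strata: dict[str, str], labels: list[str]):
    """Per-site alt/called allele counts and genotype summaries per stratum."""
    out = {}
    for lab in labels:
        rows = np.array([2 * i + j for i, s in enumerate(haps.samples)
                         if strata[s] == lab for j in (0, 1)])
        sub = haps.alleles[rows]
        alt = (sub == 1).sum(axis=0)
        called = (sub >= 0).sum(axis=0)
        h0, h1 = sub[0::2], sub[1::2]
        full = (h0 >= 0) & (h1 >= 0)
        n_ind = full.sum(axis=0)
        with np.errstate(invalid="ignore"):
            het = np.where(n_ind > 0,
                           ((h0 != h1) & full).sum(axis=0) / np.maximum(n_ind, 1),
                           np.nan)
        out[lab] = (alt, called, n_ind, het)
    return out


def pairwise_state_fst(
    haps: HaplotypeSet,
    strata: dict[str, str],
    variant_ids: list[str] | None = None,
    mode: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric stratum x stratum Fst matrices (weighted and mean-of-ratios).

    ``mode``: ``"haploid"``, ``"diploid"`` or ``"auto"`` (diploid when the
    input is unmasked, haploid when it carries a mask).  Strata with fewer
    than 2 samples are skipped with a warning (NaN row/column).
    """
    if mode == "auto":
        mode = "haploid" if haps.mask_ancestry else "diploid"
    labels = sorted(set(strata[s] for s in haps.samples))
    sizes = {lab: sum(1 for s in haps.samples if strata[s] == lab) for lab in labels}
    keep_sites = np.ones(haps.n_sites, bool)
    if variant_ids is not None:
        keep_sites = haps.variant_ids().isin(set(variant_ids)).to_numpy()
    counts = _stratum_counts(haps, strata, labels)
    W = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    M = W.copy()
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if j <= i:
                continue
            if sizes[la] < 2 or sizes[lb] < 2:
                logger.warning("skipping pair (%s, %s): a stratum has < 2 samples",
                               la, lb)
                W.iloc[i, j] = W.iloc[j, i] = np.nan
                M.iloc[i, j] = M.iloc[j, i] = np.nan
                continue
            alt = np.column_stack([counts[la][0][keep_sites], counts[lb][0][keep_sites]])
            called = np.column_stack([counts[la][1][keep_sites],
                                      counts[lb][1][keep_sites]])
            if mode == "diploid":
                n_ind = np.column_stack([counts[la][2][keep_sites],
                                         counts[lb][2][keep_sites]])
                het = np.column_stack([counts[la][3][keep_sites],
                                       counts[lb][3][keep_sites]])
                res = wc_fst(alt, called, het_by_pop=het, n_ind_by_pop=n_ind)
            else:
                res = wc_fst(alt, called)
            W.iloc[i, j] = W.iloc[j, i] = res.weighted
            M.iloc[i, j] = M.iloc[j, i] = res.mean
    return W, M


def compare_asfst(
    asfst_ind: np.ndarray,
    asfst_eur: np.ndarray,
    paired: bool = False,
) -> dict:
    """Two-sided t test comparing per-variant asFst between two ancestries.

    Welch's unequal-variance test by default (``paired=True`` switches to a
    paired test on the per-variant differences).  The reported 95% CI is on
    ``mean(eur) - mean(ind)``; NaN values are dropped (pairwise when
    ``paired``).
    """
    x = np.asarray(asfst_ind, float)
    y = np.asarray(asfst_eur, float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length vectors")
        keep = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[keep], y[keep]
        if len(x) < 2:
            raise ValueError("fewer than 2 complete pairs")
        res = stats.ttest_rel(y, x)
    else:
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError("fewer than 2 observations in a group")
        res = stats.ttest_ind(y, x, equal_var=False)
    ci = res.confidence_interval(0.95)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "mean_diff": float(np.mean(y) - np.mean(x)),
        "n_ind": len(x),
        "n_eur": len(y),
    }


def asfst_per_variant(
    masked: HaplotypeSet,
    strata: dict[str, str],
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Per-variant multi-stratum asFst (all strata jointly), MAF-filtered.

    The MAF filter uses the pooled (NATIONAL) masked frequency, matching a
    'MAF > threshold on the analysis set' convention.  Returns per-variant
    theta with the pooled frequency.
    """
    labels = sorted(set(strata[s] for s in masked.samples))
    counts = _stratum_counts(masked, strata, labels)
    alt = np.column_stack([counts[lab][0] for lab in labels])
    called = np.column_stack([counts[lab][1] for lab in labels])
    tot_alt, tot_called = alt.sum(axis=1), called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pooled = np.where(tot_called > 0, tot_alt / np.maximum(tot_called, 1), np.nan)
    maf = np.minimum(pooled, 1 - pooled)
    keep = maf > min_maf
    res = wc_fst(alt[keep], called[keep],
                 variant_ids=masked.variant_ids().to_numpy()[keep])
    out = res.per_site[["variant", "theta"]].copy()
    out["pooled_freq"] = pooled[keep]
    return out
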