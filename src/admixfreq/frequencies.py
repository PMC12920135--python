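"""Allele frequencies, ancestry-specific frequencies (asF) and related summaries.

The ancestry-specific frequency of a variant for ancestry ``x`` is

    asF_x = p / (p + q)

where ``p`` is the number of alternate alleles lying on chromosomal segments
assigned to ``x`` and ``p + q`` the total number of called alleles on such
segments.  Operationally this is the plain allele frequency of an
ancestry-masked haplotype matrix.  Cells with zero called alleles are
*undefined* (NaN), never 0 — with K=4 ancestries and small minor-ancestry
genome fractions, empty cells are common and the distinction is material.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ancestry import ConfusionMatrix
from .haplotypes import HaplotypeSet

NATIONAL = "NATIONAL"
ALL = "ALL"

FREQ_COLUMNS = ["variant", "stratum", "ancestry", "alt_count", "called_count", "freq"]


def _counts(alleles: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = alleles[rows]
    return (sub == 1).sum(axis=0), (sub >= 0).sum(axis=0)


def allele_frequency(
    haps: HaplotypeSet,
    strata: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Frequency table per (variant, stratum) plus the NATIONAL pool.

    Parameters
    ----------
    haps
        Masked or unmasked haplotypes; the ``ancestry`` column of the result
        is the mask ancestry, or ``"ALL"`` for unmasked input.
    strata
        Mapping sample id -> stratum label.  ``None`` computes the NATIONAL
        level only.

    Returns
    -------
    DataFrame with columns ``variant, stratum, ancestry, alt_count,
    called_count, freq``; ``freq`` is NaN wherever ``called_count`` is 0.
    """
    if strata is not None:
        strata = dict(strata) if not isinstance(strata, dict) else strata
        unmapped = sorted(set(haps.samples) - set(strata))
        if unmapped:
            raise ValueError(f"samples without a stratum: {unmapped}")
    ancestry = haps.mask_ancestry or ALL
    ids = haps.variant_ids().to_numpy()
    blocks = []

    def block(stratum_label: str, rows: np.ndarray) -> pd.DataFrame:
        alt, called = _counts(haps.alleles, rows)
        with np.errstate(invalid="ignore"):
            freq = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        return pd.DataFrame({
            "variant": ids, "stratum": stratum_label, "ancestry": ancestry,
            "alt_count": alt, "called_count": called, "freq": freq,
        })

    blocks.append(block(NATIONAL, np.arange(2 * haps.n_samples)))
    if strata is not None:
        by_stratum: dict[str, list[int]] = {}
        for i, s in enumerate(haps.samples):
            by_stratum.setdefault(strata[s], []).extend((2 * i, 2 * i + 1))
        for label in sorted(by_stratum):
            blocks.append(block(label, np.array(by_stratum[label])))
    return pd.concat(blocks, ignore_index=True)


def carrier_stats(
    haps: HaplotypeSet,
    variant: str,
    strata: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-stratum carrier and homozygote percentages for one variant.

    Carriers have >= 1 alternate allele; homozygotes have 2.  Individuals
    with any missing allele at the site are excluded from the denominator;
    a stratum with zero fully-called individuals gets NaN percentages.
    """
    ids = haps.variant_ids()
    hits = np.flatnonzero(ids.to_numpy() == variant)
    if hits.size == 0:
        raise KeyError(f"variant {variant!r} not found")
    dose = haps.dosage()[:, hits[0]]  # NaN where partially missing
    labels = np.array([strata[s] for s in haps.samples]) if strata else None

    def row(label: str, sel: np.ndarray) -> tuple:
        d = dose[sel]
        d = d[~np.isnan(d)]
        n = len(d)
        if n == 0:
            return (label, 0, np.nan, np.nan)
        return (label, n, 100.0 * (d >= 1).mean(), 100.0 * (d == 2).mean())

    rows = [row(NATIONAL, np.arange(haps.n_samples))]
    if labels is not None:
        for lab in sorted(set(labels)):
            rows.append(row(lab, np.flatnonzero(labels == lab)))
    return pd.DataFrame(rows, columns=["stratum", "n_called", "carrier_pct",
                                       "homozygote_pct"])


def ancestry_freq_contrast(
    table: pd.DataFrame,
    ancestry_a: str,
    ancestry_b: str,
    stratum: str = NATIONAL,
) -> pd.DataFrame:
    """Per-variant asF difference between two ancestries at one stratum.

    Variants undefined (zero called alleles) in either ancestry are flagged
    ``comparable = False`` with NaN differences rather than treated as 0.
    Enrichment direction is the ancestry with the higher frequency.
    """
    sub = table[table["stratum"] == stratum]
    a = sub[sub["ancestry"] == ancestry_a].set_index("variant")["freq"]
    b = sub[sub["ancestry"] == ancestry_b].set_index("variant")["freq"]
    variants = a.index.union(b.index, sort=False)
    fa = a.reindex(variants)
    fb = b.reindex(variants)
    delta = fa - fb
    out = pd.DataFrame({
        "variant": variants,
        f"freq_{ancestry_a}": fa.to_numpy(),
        f"freq_{ancestry_b}": fb.to_numpy(),
        "delta": delta.to_numpy(),
        "abs_delta": np.abs(delta.to_numpy()),
        "comparable": (~fa.isna() & ~fb.isna()).to_numpy(),
    }).reset_index(drop=True)
    direction = np.where(out["delta"] > 0, ancestry_a,
                         np.where(out["delta"] < 0, ancestry_b, "equal"))
    out["enriched_in"] = np.where(out["comparable"], direction, "incomparable")
    return out


def expected_asf_under_confusion(
    proportions: np.ndarray,
    cm: ConfusionMatrix,
    true_freqs: np.ndarray,
    ancestry: str | int,
) -> float:
    """Analytic expectation of estimated asF under ancestry-call error.

    A site's true ancestry is ``y`` with probability ``pi_y``; the caller
    assigns ``x`` with probability ``C[y, x]``; the allele is Bernoulli of
    the *true* ancestry's frequency ``f_y``.  Alleles counted towards
    ancestry ``x`` therefore have expected frequency

        E[asF_x] = sum_y pi_y C[y, x] f_y / sum_y pi_y C[y, x].

    Returns NaN when ``x`` is never assigned (zero denominator).
    """
    pi = np.asarray(proportions, float)
    f = np.asarray(true_freqs, float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise ValueError("proportions must sum to 1")
    if pi.shape != f.shape or len(pi) != len(cm.labels):
        raise ValueError("proportions, freqs and confusion matrix disagree on K")
    x = cm.labels.index(ancestry) if isinstance(ancestry, str) else int(ancestry)
    weights = pi * cm.matrix[:, x]
    denom = weights.sum()
    if denom == 0:
        return float("nan")
    return float((weights * f).sum() / denom)


def write_frequency_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_frequency_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
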