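"""Ancestry masking: keep only alleles lying on segments of one ancestry.

Masking turns a phased :class:`~admixfreq.haplotypes.HaplotypeSet` plus
per-haplotype local-ancestry calls into an "ancestry-masked" matrix in which
every allele whose haplotype is NOT assigned the requested ancestry at that
site is set missing.  Ancestry-specific allele frequencies (asF) are then
ordinary allele frequencies of the masked matrix.

The key conservation property (tested): across the K ancestry masks, per-site
called-allele counts and alternate-allele counts partition the unmasked
counts exactly, because every called allele lies on exactly one ancestry.
Sites not covered by any tract are masked under every ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .ancestry import AncestryCalls
from .haplotypes import MISSING, HaplotypeSet

logger = logging.getLogger(__name__)


def mask(haps: HaplotypeSet, calls: AncestryCalls, ancestry: str | int) -> HaplotypeSet:
    """Return a copy of ``haps`` keeping only alleles of one local ancestry.

    Parameters
    ----------
    haps
        Phased haplotypes. Unphased input is rejected: local ancestry is a
        per-haplotype quantity.
    calls
        Local-ancestry calls covering (at least) the samples of ``haps``.
    ancestry
        Ancestry label (e.g. ``"IND"``) or integer code from the call set's
        code book.

    Notes
    -----
    Already-missing alleles stay missing; sites uncovered by any tract are
    masked everywhere (their count is logged).  Masking is idempotent and
    masking an already-masked set for a different ancestry yields an
    all-missing matrix.
    """
    if not haps.phased:
        raise ValueError("masking requires phased haplotypes")
    missing_samples = sorted(set(haps.samples) - set(calls.samples))
    if missing_samples:
        raise ValueError(
            f"samples in VCF but absent from ancestry calls: {missing_samples}"
        )
    code = calls.code_for(ancestry) if isinstance(ancestry, str) else int(ancestry)
    if code not in calls.code_book:
        raise KeyError(f"ancestry code {code} not in code book {calls.code_book}")
    label = calls.code_book[code]

    sample_idx = {s: i for i, s in enumerate(calls.samples)}
    hap_rows = np.array(
        [2 * sample_idx[s] + j for s in haps.samples for j in (0, 1)]
    )
    out = haps.alleles.copy()
    n_uncovered = 0
    for chrom, grp in haps.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        codes = calls.ancestry_at(str(chrom), grp["pos"].to_numpy())[hap_rows]
        n_uncovered += int((codes[0] == -1).sum())
        out[:, cols] = np.where(codes == code, out[:, cols], MISSING)
    if n_uncovered:
        logger.info("%d site(s) uncovered by tracts: masked in every ancestry",
                    n_uncovered)
    return replace(haps, alleles=out, mask_ancestry=label,
                   variants=haps.variants.copy())
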