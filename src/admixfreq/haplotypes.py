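"""Phased haplotype matrices and VCF input/output.

The central container is :class:`HaplotypeSet`: a ``(2N, M)`` matrix of
alternate-allele indicators over haplotypes x biallelic SNP sites, with
``-1`` marking a missing (or ancestry-masked) allele.  Haplotype rows are
ordered ``sample0.hap0, sample0.hap1, sample1.hap0, ...`` so that row
``2*i + j`` is haplotype ``j`` of sample ``i``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: columns of the variant table, in order
VARIANT_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt"]


class VcfFormatError(ValueError):
    """Raised for malformed or unsupported VCF content."""


@dataclass
class HaplotypeSet:
    """Phased biallelic genotypes as a haplotype x site allele matrix.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length N).
    variants
        Table with columns ``chrom, pos, rsid, ref, alt``; ``pos`` is
        1-based and strictly increasing within each chromosome.
    alleles
        ``(2N, M)`` int8 matrix with values {0, 1, -1}.
    phased
        Whether rows carry true haplotype phase (required for masking).
    mask_ancestry
        Ancestry label the matrix was masked for, or ``None`` if unmasked.
    """

    samples: list[str]
    variants: pd.DataFrame
    alleles: np.ndarray
    phased: bool = True
    mask_ancestry: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"2x{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("allele matrix entries must be in {-1, 0, 1}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> pd.Series:
        """rsid where present, else chrom:pos:ref:alt."""
        v = self.variants
        fallback = (
            v["chrom"].astype(str) + ":" + v["pos"].astype(str)
            + ":" + v["ref"] + ":" + v["alt"]
        )
        rsid = v["rsid"].astype("string")
        return rsid.where(rsid.notna() & (rsid != "."), fallback).astype(str)

    def dosage(self) -> np.ndarray:
        """Per-individual alternate-allele count, NaN where any allele missing."""
        a = self.alleles.astype(float)
        a[a < 0] = np.nan
        return a[0::2] + a[1::2]

    def copy(self) -> "HaplotypeSet":
        return replace(
            self, variants=self.variants.copy(), alleles=self.alleles.copy()
        )


def read_vcf(path: str, on_unphased: str = "error") -> HaplotypeSet:
    """Read a phased, biallelic-SNP VCF into a :class:`HaplotypeSet`.

    Multiallelic records are skipped with a warning.  Half-called alleles
    become missing.  Unphased heterozygous genotypes are a hard error by
    default because downstream ancestry masking is per-haplotype; pass
    ``on_unphased="missing"`` to set both alleles missing instead.
    """
    if on_unphased not in ("error", "missing"):
        raise ValueError("on_unphased must be 'error' or 'missing'")
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[tuple] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = var.genotype.array()  # (N, 3): allele0, allele1, phased flag
        if gt.shape[1] != 3:
            raise VcfFormatError(
                f"{path} record {i + 1} ({var.CHROM}:{var.POS}): ploidy != 2"
            )
        a = gt[:, :2].astype(np.int8)
        unphased_het = (gt[:, 2] == 0) & (a[:, 0] != a[:, 1]) & (a >= 0).all(axis=1)
        if unphased_het.any():
            if on_unphased == "error":
                bad = [samples[j] for j in np.nonzero(unphased_het)[0]]
                raise VcfFormatError(
                    f"unphased heterozygote(s) at {var.CHROM}:{var.POS} "
                    f"for samples {bad[:5]}; rerun with on_unphased='missing'"
                )
            a[unphased_het] = MISSING
        a[a > 1] = MISSING  # defensive: non-biallelic allele index
        rows.append((var.CHROM, var.POS, var.ID or ".", var.REF, var.ALT[0]))
        cols.append(a.reshape(-1))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multiallelic record(s)")
    if not rows:
        raise VcfFormatError(f"{path}: no biallelic SNP records")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    alleles = np.stack(cols, axis=1)
    return HaplotypeSet(samples=samples, variants=variants, alleles=alleles)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(haps: HaplotypeSet, path: str) -> None:
    """Write a :class:`HaplotypeSet` as a phased VCF v4.2 text file.

    Masked or missing alleles are written as ``.`` within the phased GT
    (e.g. ``.|1``), matching the ancestry-masked VCF convention.
    """
    sym = np.array([".", "0", "1"])  # index by allele + 1
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = pd.unique(haps.variants["chrom"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(haps.samples) + "\n"
        )
        a0 = sym[haps.alleles[0::2] + 1]  # (N, M)
        a1 = sym[haps.alleles[1::2] + 1]
        for s, row in enumerate(haps.variants.itertuples(index=False)):
            gts = "\t".join(
                a0[j, s] + "|" + a1[j, s] for j in range(haps.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    logger.info("wrote %d sites x %d samples to %s", haps.n_sites, haps.n_samples, path)
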