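#!/usr/bin/env python
"""Ancestry-specific allele frequencies (asF) and ancestry enrichment.

Masks the cohort's genotypes by local ancestry, estimates asF per ancestry
at the national and stratum level, checks the estimates against the
simulator's truth table, and contrasts Indigenous vs European frequencies
per variant.
"""

import os

import numpy as np
import pandas as pd

from admixfreq.ancestry import read_msp
from admixfreq.frequencies import (allele_frequency, ancestry_freq_contrast,
                                   write_frequency_table)
from admixfreq.haplotypes import read_vcf
from admixfreq.masking import mask

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
SCRATCH = os.path.join(ROOT, "scratch", "cohort")
RESULTS = os.path.join(ROOT, "results")
ANCESTRIES = ("AFR", "EUR", "EAS", "IND")


def main() -> None:
    haps = read_vcf(os.path.join(SCRATCH, "cohort.vcf"))
    calls = read_msp(os.path.join(SCRATCH, "cohort.msp.tsv"))
    meta = pd.read_csv(os.path.join(SCRATCH, "metadata.tsv"), sep="\t")
    strata = dict(zip(meta["sample_id"], meta["stratum"]))

    tables = [allele_frequency(haps, strata)]
    for anc in ANCESTRIES:
        tables.append(allele_frequency(mask(haps, calls, anc), strata))
    freq = pd.concat(tables, ignore_index=True)
    # full stratum-level table is bulky -> scratch; national slice -> results
    full_path = os.path.join(SCRATCH, "frequencies_full.tsv")
    write_frequency_table(freq, full_path)
    out_freq = os.path.join(RESULTS, "02_frequencies_national.tsv")
    write_frequency_table(freq[freq["stratum"] == "NATIONAL"], out_freq)

    # accuracy of stratum-level asF against the simulator's configured truth
    # (cells with few called alleles are dominated by binomial noise)
    truth = pd.read_csv(os.path.join(SCRATCH, "truth_freqs.tsv"), sep="\t")
    print("mean |asF - truth| per ancestry (stratum level, >= 30 called alleles):")
    for anc in ANCESTRIES:
        est = freq[(freq["ancestry"] == anc) & (freq["stratum"] != "NATIONAL")
                   & (freq["called_count"] >= 30)]
        merged = est.merge(truth, left_on=["variant", "stratum"],
                           right_on=["site", "stratum"])
        err = (merged["freq"] - merged[f"f_{anc}"]).abs()
        print(f"  {anc}: {err.mean():.4f} over {len(merged)} cells"
              if len(merged) else f"  {anc}: no well-covered cells")

    contrast = ancestry_freq_contrast(freq, "IND", "EUR")
    out_contrast = os.path.join(RESULTS, "02_asf_contrast_IND_vs_EUR.tsv")
    contrast.to_csv(out_contrast, sep="\t", index=False, float_format="%.5f")
    comp = contrast[contrast["comparable"]]
    print(f"\n{len(comp)}/{len(contrast)} variants comparable in both ancestries")
    print(f"enriched in IND: {(comp['enriched_in'] == 'IND').sum()}, "
          f"in EUR: {(comp['enriched_in'] == 'EUR').sum()}; "
          f"mean |delta asF| = {comp['abs_delta'].mean():.4f}")
    print(f"tables -> {out_freq}, {out_contrast}")


if __name__ == "__main__":
    main()
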