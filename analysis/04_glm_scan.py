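#!/usr/bin/env python
"""Attribute per-variant frequency variation to ancestry vs geography.

Fits a binomial GLM per variant (alternate-allele count out of 2 on
standardized Indigenous fraction, African fraction, latitude, longitude),
classifies each variant by its exact set of significant terms (UpSet-style)
and contrasts effect magnitudes by sign.
"""

import os

import pandas as pd

from admixfreq.ancestry import read_msp
from admixfreq.glm import (TERMS, build_predictors, effect_direction_contrast,
                           glm_scan, upset_categories)
from admixfreq.haplotypes import read_vcf

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
SCRATCH = os.path.join(ROOT, "scratch", "cohort")
RESULTS = os.path.join(ROOT, "results")


def main() -> None:
    haps = read_vcf(os.path.join(SCRATCH, "cohort.vcf"))
    calls = read_msp(os.path.join(SCRATCH, "cohort.msp.tsv"))
    meta = pd.read_csv(os.path.join(SCRATCH, "metadata.tsv"), sep="\t")

    preds = build_predictors(calls.genome_fractions(), meta)
    results, skipped = glm_scan(haps, preds, alpha=0.05)
    results.to_csv(os.path.join(RESULTS, "04_glm_results.tsv"), sep="\t",
                   index=False, float_format="%.6g")

    counts = upset_categories(results)
    counts.rename_axis("category").to_frame("count").to_csv(
        os.path.join(RESULTS, "04_glm_categories.tsv"), sep="\t")
    n = len(results)
    print(f"scanned {n} variants ({len(skipped)} skipped)")
    ind_any = results["category"].str.contains("IND").sum()
    print(f"significant for Indigenous ancestry (alone or combined): "
          f"{ind_any} ({100 * ind_any / n:.0f}%)")
    print(f"unexplained: {counts.get('unexplained', 0)} "
          f"({100 * counts.get('unexplained', 0) / n:.0f}%)")
    print("\ntop categories:")
    print(counts.head(8).to_string())

    rows = [effect_direction_contrast(results, t) for t in TERMS]
    contrast = pd.DataFrame(rows)
    contrast.to_csv(os.path.join(RESULTS, "04_effect_directions.tsv"), sep="\t",
                    index=False, float_format="%.5g")
    print("\n|beta| by effect sign per term:")
    print(contrast[["term", "n_pos", "n_neg", "mean_abs_pos", "mean_abs_neg",
                    "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
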