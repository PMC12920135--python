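#!/usr/bin/env python
"""Ancestry-specific Fst (asFst) across geographic strata.

Computes per-variant Weir-Cockerham Fst between strata separately within
Indigenous-masked and European-masked segments (MAF > 0.05), tests whether
Indigenous segments are more geographically differentiated than European
ones, and writes the pairwise stratum Fst matrix.
"""

import json
import os

import numpy as np
import pandas as pd

from admixfreq.ancestry import read_msp
from admixfreq.fst import asfst_per_variant, compare_asfst, pairwise_state_fst
from admixfreq.haplotypes import read_vcf
from admixfreq.masking import mask

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
SCRATCH = os.path.join(ROOT, "scratch", "cohort")
RESULTS = os.path.join(ROOT, "results")


def main() -> None:
    haps = read_vcf(os.path.join(SCRATCH, "cohort.vcf"))
    calls = read_msp(os.path.join(SCRATCH, "cohort.msp.tsv"))
    meta = pd.read_csv(os.path.join(SCRATCH, "metadata.tsv"), sep="\t")
    strata = dict(zip(meta["sample_id"], meta["stratum"]))

    per_variant = {}
    for anc in ("IND", "EUR"):
        masked = mask(haps, calls, anc)
        pv = asfst_per_variant(masked, strata, min_maf=0.05)
        pv.to_csv(os.path.join(RESULTS, f"03_asfst_{anc}.tsv"), sep="\t",
                  index=False, float_format="%.6g")
        per_variant[anc] = pv.set_index("variant")["theta"]
        print(f"asFst[{anc}]: {len(pv)} variants, "
              f"mean theta = {pv['theta'].mean():.5f}")

    shared = per_variant["IND"].index.intersection(per_variant["EUR"].index)
    res = compare_asfst(per_variant["IND"][shared], per_variant["EUR"][shared])
    with open(os.path.join(RESULTS, "03_asfst_contrast.json"), "w") as fh:
        json.dump(res, fh, indent=1)
    print(f"\nWelch t test, mean(EUR) - mean(IND) over {len(shared)} shared "
          f"variants:\n  t = {res['t']:.3f}, p = {res['p']:.4g}, "
          f"95% CI [{res['ci_low']:.3g}, {res['ci_high']:.3g}]")

    W, _ = pairwise_state_fst(haps, strata)
    out_matrix = os.path.join(RESULTS, "03_pairwise_fst.tsv")
    W.to_csv(out_matrix, sep="\t", float_format="%.6g")
    ordered = meta.sort_values("latitude")["stratum"].unique()
    extremes = W.loc[ordered[0], ordered[-1]]
    adjacent = W.loc[ordered[0], ordered[1]]
    print(f"\npairwise Fst: extreme south-north = {extremes:.5f}, "
          f"adjacent south pair = {adjacent:.5f} "
          f"(cline implies the former exceeds the latter: {extremes > adjacent})")
    print(f"matrix -> {out_matrix}")


if __name__ == "__main__":
    main()
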