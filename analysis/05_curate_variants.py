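#!/usr/bin/env python
"""Curate clinically relevant and actionable variants for the cohort.

Builds small ClinVar-like and PharmGKB-like annotation tables over the
cohort's genotyped sites, intersects them with the array content, applies
the national 5% MAF filter for the frequency analyses, and flags the
actionable subset (PharmGKB levels 1A-2B; pathogenic in panel genes without
conflicting interpretations - no MAF filter there).
"""

import os

import pandas as pd

from admixfreq.catalog import (ANNOTATION_COLUMNS, GenePanel,
                               classify_actionable, curate, maf_filter,
                               top_drug)
from admixfreq.frequencies import read_frequency_table

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
SCRATCH = os.path.join(ROOT, "scratch", "cohort")
RESULTS = os.path.join(ROOT, "results")

PANEL = GenePanel.from_symbols("actionable-demo", ["BRCA2", "LDLR", "MYH7"])


def demo_annotations() -> pd.DataFrame:
    rows = [
        # rsid, chrom, pos, ref, alt, gene, significance, level, drugs, pheno, cites
        ("site00010", "1", 0, "A", "G", "BRCA2", "Pathogenic", "",
         "", "hereditary cancer", "PMID:1", "clinvar"),
        ("site00020", "1", 0, "A", "G", "CYP3A4", "", "1B",
         "fentanyl:1B", "opioid metabolism", "PMID:2", "pharmgkb"),
        ("site00020", "1", 0, "A", "G", "CYP3A4", "drug response", "",
         "", "opioid metabolism", "PMID:3", "clinvar"),
        ("site00030", "1", 0, "A", "G", "SLCO1B1", "", "2A",
         "simvastatin:2A;pravastatin:3", "statin myopathy", "PMID:4", "pharmgkb"),
        ("site00040", "1", 0, "A", "G", "MYH7",
         "Conflicting interpretations of pathogenicity", "", "",
         "cardiomyopathy", "PMID:5", "clinvar"),
        ("site00050", "1", 0, "A", "G", "MTHFR", "", "3",
         "methotrexate:3", "methotrexate response", "PMID:6", "pharmgkb"),
        ("rs_not_on_array", "9", 12345, "C", "T", "GHOST", "Pathogenic", "",
         "", "not genotyped", "PMID:7", "clinvar"),
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["source"])


def main() -> None:
    vcf_sites = pd.read_csv(os.path.join(SCRATCH, "cohort.vcf"), sep="\t",
                            comment="#", header=None, usecols=[2], names=["rsid"])
    genotyped = set(vcf_sites["rsid"])
    ann = demo_annotations()
    cur = curate(ann, genotyped_rsids=genotyped)
    cur = classify_actionable(cur, PANEL)
    cur["top_drug"] = [top_drug(d) for d in cur["drugs"]]

    freq = read_frequency_table(os.path.join(RESULTS,
                                             "02_frequencies_national.tsv"))
    kept = set(maf_filter(freq, list(cur["rsid"]), threshold=0.05))
    cur["passes_maf"] = cur["rsid"].isin(kept)

    out = os.path.join(RESULTS, "05_curated_variants.tsv")
    cur.to_csv(out, sep="\t", index=False)
    print(f"{len(ann)} annotation rows -> {len(cur)} curated genotyped variants")
    print(f"PGx-actionable: {int(cur['pgx_actionable'].sum())}; "
          f"panel pathogenic: {int(cur['acmg_pathogenic'].sum())}; "
          f"passing MAF>=5%: {int(cur['passes_maf'].sum())}")
    cols = ["rsid", "gene", "source", "pharmgkb_level", "pgx_actionable",
            "acmg_pathogenic", "top_drug", "passes_maf"]
    print(cur[cols].to_string(index=False))
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
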