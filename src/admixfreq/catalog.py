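"""Curation of biomedically relevant variants and actionability flags.

Annotation tables arrive as simplified TSV exports (one per source database,
ClinVar-like / PharmGKB-like), are intersected with the genotyped variant
set, deduplicated across sources, MAF-filtered for the frequency analyses,
and flagged for two actionability criteria:

* ``pgx_actionable`` — a PharmGKB evidence level in {1A, 1B, 2A, 2B}
  (gene-drug associations supported by clinical guidance or moderate
  replicated evidence).
* ``acmg_pathogenic`` — pathogenic or likely pathogenic clinical
  significance, with no conflicting interpretations, in a gene on a
  medically actionable secondary-findings panel (e.g. ACMG SF v3.2).  No
  frequency threshold applies: actionable variants are often rare.

Annotation TSV columns (header required)::

    rsid  chrom  pos  ref  alt  gene  clinical_significance
    pharmgkb_level  drugs  phenotype  citations

``drugs`` holds ``name:level`` entries separated by ``;`` (level may be
empty); ``pharmgkb_level`` may be empty and is then derived from ``drugs``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: PharmGKB evidence scale, strongest first
EVIDENCE_ORDER = ("1A", "1B", "2A", "2B", "3", "4")
_EVIDENCE_RANK = {lvl: i for i, lvl in enumerate(EVIDENCE_ORDER)}
ACTIONABLE_LEVELS = frozenset({"1A", "1B", "2A", "2B"})

ANNOTATION_COLUMNS = [
    "rsid", "chrom", "pos", "ref", "alt", "gene", "clinical_significance",
    "pharmgkb_level", "drugs", "phenotype", "citations",
]


@dataclass(frozen=True)
class GenePanel:
    """A named panel of actionable genes (symbols uppercase, unique)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols) -> "GenePanel":
        return cls(name, frozenset(s.strip().upper() for s in symbols if s.strip()))

    @classmethod
    def from_file(cls, path: str, name: str | None = None) -> "GenePanel":
        with open(path) as fh:
            symbols = [line.strip() for line in fh if line.strip()
                       and not line.startswith("#")]
        return cls.from_symbols(name or path, symbols)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.genes


def read_annotations(path: str, source: str) -> pd.DataFrame:
    """Read one source's annotation TSV, tagging rows with the source label."""
    if not source:
        raise ValueError("source label must be non-empty")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    bad = df["pharmgkb_level"].dropna().astype(str)
    bad = bad[(bad != "") & ~bad.isin(EVIDENCE_ORDER)]
    if len(bad):
        raise ValueError(f"{path}: invalid PharmGKB level(s) {sorted(set(bad))}")
    df = df.copy()
    df["source"] = source
    return df


def _positional_key(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype("Int64").astype(str)
            + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str))


def curate(
    annotations: pd.DataFrame,
    genotyped_rsids: set[str] | None = None,
    genotyped_positions: set[str] | None = None,
) -> pd.DataFrame:
    """Keep annotations present on the genotyping array; collapse duplicates.

    A variant matches by rsid when possible, else by ``chrom:pos:ref:alt``.
    The same variant reported by several source databases collapses to one
    record whose ``source`` is the sorted ``;``-joined label set.  An rsid
    mapping to several loci triggers a warning and falls back to the
    positional key.  Curation is idempotent.
    """
    if genotyped_rsids is None and genotyped_positions is None:
        raise ValueError("need a genotyped rsid set and/or positional set")
    ann = annotations.copy()
    ann["_poskey"] = _positional_key(ann)
    has_rsid = ann["rsid"].notna() & (ann["rsid"].astype(str) != "") \
        & (ann["rsid"].astype(str) != ".")
    multi = (ann[has_rsid].groupby("rsid")["_poskey"].nunique() > 1)
    ambiguous = set(multi[multi].index)
    if ambiguous:
        warnings.warn(f"rsid(s) mapping to multiple loci, using positional key: "
                      f"{sorted(ambiguous)}")
    by_rsid = has_rsid & ~ann["rsid"].isin(ambiguous)
    hit = pd.Series(False, index=ann.index)
    if genotyped_rsids is not None:
        hit |= by_rsid & ann["rsid"].isin(genotyped_rsids)
    if genotyped_positions is not None:
        hit |= ann["_poskey"].isin(genotyped_positions)
    kept = ann[hit].copy()
    kept["_key"] = np.where(by_rsid[hit], kept["rsid"], kept["_poskey"])

    def collapse(grp: pd.DataFrame) -> pd.Series:
        first = grp.iloc[0].copy()
        first["source"] = ";".join(sorted(set(";".join(grp["source"]).split(";"))))
        levels = [lv for lv in grp["pharmgkb_level"].dropna().astype(str)
                  if lv in _EVIDENCE_RANK]
        if levels:
            first["pharmgkb_level"] = min(levels, key=_EVIDENCE_RANK.get)
        drugs = sorted(set(d for ds in grp["drugs"].dropna().astype(str)
                           for d in ds.split(";") if d))
        first["drugs"] = ";".join(drugs) if drugs else first["drugs"]
        return first

    if kept.empty:
        return kept.drop(columns=["_poskey", "_key"])
    out = (kept.groupby("_key", sort=False, group_keys=False)
           .apply(collapse, include_groups=False)
           .reset_index(drop=True))
    return out.drop(columns=["_poskey"], errors="ignore")


def maf_filter(
    freq_table: pd.DataFrame,
    variants: list[str],
    threshold: float = 0.05,
    stratum: str = "NATIONAL",
    ancestry: str = "ALL",
) -> list[str]:
    """Variants whose national minor allele frequency is >= ``threshold``.

    Uses the ALL-ancestry frequency at the national stratum.  Variants
    missing from the frequency table (or undefined there) are excluded with
    a warning.
    """
    sub = freq_table[(freq_table["stratum"] == stratum)
                     & (freq_table["ancestry"] == ancestry)]
    freqs = sub.set_index("variant")["freq"]
    kept, absent = [], []
    for v in variants:
        f = freqs.get(v, np.nan)
        if np.isnan(f):
            absent.append(v)
        elif min(f, 1 - f) >= threshold:
            kept.append(v)
    if absent:
        warnings.warn(f"{len(absent)} variant(s) without a defined frequency "
                      f"were excluded: {absent[:5]}")
    return kept


_PATHOGENIC = ("pathogenic", "likely pathogenic")


def _is_pathogenic_no_conflict(significance) -> bool:
    if not isinstance(significance, str):
        return False
    s = significance.strip().lower()
    if "conflicting" in s:
        return False
    terms = {t.strip() for t in s.replace("/", ";").split(";") if t.strip()}
    has_path = any(t in _PATHOGENIC for t in terms)
    has_benign = any("benign" in t for t in terms)
    return has_path and not has_benign


def classify_actionable(curated: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Add ``pgx_actionable`` and ``acmg_pathogenic`` boolean flags.

    ``pgx_actionable`` iff the PharmGKB level is 1A/1B/2A/2B;
    ``acmg_pathogenic`` iff the clinical significance is (likely)
    pathogenic without conflicting interpretations and the gene is on the
    panel.  Absent fields yield False.  No frequency threshold is applied.
    """
    out = curated.copy()
    lev = out["pharmgkb_level"].astype(str).str.strip()
    out["pgx_actionable"] = lev.isin(ACTIONABLE_LEVELS)
    out["acmg_pathogenic"] = [
        _is_pathogenic_no_conflict(sig) and str(g).upper() in panel.genes
        for sig, g in zip(out["clinical_significance"], out["gene"])
    ]
    return out


def top_drug(drugs) -> str | None:
    """The associated drug with the strongest evidence level.

    ``drugs`` is the ``name:level;name:level`` string of one variant.  Ties
    on evidence level break lexicographically by drug name; entries without
    a parsable level rank below level 4.  Returns None when there is no
    drug annotation.
    """
    if drugs is None or (isinstance(drugs, float) and np.isnan(drugs)):
        return None
    entries = []
    for tok in str(drugs).split(";"):
        if not tok.strip():
            continue
        name, _, level = tok.partition(":")
        rank = _EVIDENCE_RANK.get(level.strip(), len(EVIDENCE_ORDER))
        entries.append((rank, name.strip()))
    if not entries:
        return None
    entries.sort()
    return entries[0][1]
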