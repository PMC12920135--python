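"""End-to-end orchestration: simulate → mask → freq → fst → glm → curate → error-sim.

A :class:`PipelineConfig` (typically loaded from YAML) names the inputs or
asks for a simulated cohort, and :func:`run_pipeline` executes the stages,
writing every product under ``outdir`` plus a ``manifest.json`` mapping each
output file to its SHA-256 hash.  Stages whose outputs already exist with
hashes matching the manifest are skipped, so deleting one intermediate
re-executes only that stage and everything downstream of it.  A single seed
governs the whole run; per-stage seeds are derived from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import catalog, frequencies, fst, glm
from .ancestry import ConfusionMatrix, read_msp
from .haplotypes import read_vcf, write_vcf
from .masking import mask
from .simulate import SimulationConfig, asf_error_experiment, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "mask", "freq", "fst", "glm", "curate", "error_sim")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    outdir: str
    vcf: str | None = None
    msp: str | None = None
    metadata: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)
    gene_panel: str | None = None
    confusion_matrix: str | None = None
    maf: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    ancestries: tuple[str, ...] = ("AFR", "EUR", "EAS", "IND")
    fst_ancestries: tuple[str, ...] = ("IND", "EUR")
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    error_sim: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if not 0 < self.maf < 1 or not 0 < self.alpha < 1:
            raise PipelineConfigError("maf and alpha must lie in (0, 1)")
        have_inputs = all(p for p in (self.vcf, self.msp, self.metadata))
        if not have_inputs and "simulate" not in self.stages:
            raise PipelineConfigError(
                "either provide vcf+msp+metadata or enable the simulate stage")
        for name, p in [("vcf", self.vcf), ("msp", self.msp),
                        ("metadata", self.metadata), ("gene_panel", self.gene_panel),
                        ("confusion_matrix", self.confusion_matrix),
                        *self.annotations.items()]:
            if p is not None and not os.path.exists(p) and have_inputs:
                raise PipelineConfigError(f"{name} path does not exist: {p}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**{k: tuple(v) if k in ("ancestries", "fst_ancestries", "stages")
                         else v for k, v in raw.items()})
        except TypeError as exc:
            raise PipelineConfigError(f"{path}: {exc}") from exc
        cfg.validate()
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(manifest: dict, stage: str, outdir: str) -> bool:
    entry = manifest.get("stages", {}).get(stage)
    if not entry:
        return False
    return all(
        os.path.exists(os.path.join(outdir, f)) and _sha256(os.path.join(outdir, f)) == h
        for f, h in entry.items()
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; return the output manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    previous: dict = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            previous = json.load(fh)
        if previous.get("seed") != cfg.seed:
            previous = {}

    def record(stage: str, files: list[str]) -> None:
        manifest["stages"][stage] = {
            os.path.relpath(f, cfg.outdir): _sha256(f) for f in files
        }

    def reuse(stage: str) -> bool:
        if _stage_done(previous, stage, cfg.outdir):
            manifest["stages"][stage] = previous["stages"][stage]
            logger.info("stage %s: outputs up to date, skipped", stage)
            return True
        return False

    state: dict = {}

    # ---- simulate -----------------------------------------------------
    vcf_path, msp_path, meta_path = cfg.vcf, cfg.msp, cfg.metadata
    if "simulate" in cfg.stages and not (vcf_path and msp_path and meta_path):
        stage = "simulate"
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulate})
        simdir = os.path.join(cfg.outdir, "simulated")
        expected = {k: os.path.join(simdir, f) for k, f in [
            ("vcf", "cohort.vcf"), ("msp", "cohort.msp.tsv"),
            ("metadata", "metadata.tsv"), ("truth_tracts", "truth_tracts.tsv"),
            ("truth_freqs", "truth_freqs.tsv")]}
        if not reuse(stage):
            try:
                expected = simulate_cohort(sim_cfg, simdir)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, list(expected.values()))
        vcf_path, msp_path, meta_path = (expected["vcf"], expected["msp"],
                                         expected["metadata"])

    haps = read_vcf(vcf_path)
    calls = read_msp(msp_path)
    meta = pd.read_csv(meta_path, sep="\t")
    strata = dict(zip(meta["sample_id"], meta["stratum"].astype(str)))
    masked = {}

    def get_masked(anc: str):
        if anc not in masked:
            masked[anc] = mask(haps, calls, anc)
        return masked[anc]

    # ---- mask ----------------------------------------------------------
    if "mask" in cfg.stages:
        stage = "mask"
        files = [os.path.join(cfg.outdir, f"masked_{a}.vcf") for a in cfg.ancestries]
        if not reuse(stage):
            try:
                for a, f in zip(cfg.ancestries, files):
                    write_vcf(get_masked(a), f)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, files)

    # ---- freq ----------------------------------------------------------
    freq_all_path = os.path.join(cfg.outdir, "freq_ALL.tsv")
    if "freq" in cfg.stages:
        stage = "freq"
        files = [freq_all_path] + [
            os.path.join(cfg.outdir, f"freq_{a}.tsv") for a in cfg.ancestries]
        if not reuse(stage):
            try:
                tab = frequencies.allele_frequency(haps, strata)
                frequencies.write_frequency_table(tab, freq_all_path)
                for a in cfg.ancestries:
                    t = frequencies.allele_frequency(get_masked(a), strata)
                    frequencies.write_frequency_table(
                        t, os.path.join(cfg.outdir, f"freq_{a}.tsv"))
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, files)

    # ---- fst -----------------------------------------------------------
    if "fst" in cfg.stages:
        stage = "fst"
        per_variant_files = [os.path.join(cfg.outdir, f"asfst_{a}.tsv")
                             for a in cfg.fst_ancestries]
        files = per_variant_files + [
            os.path.join(cfg.outdir, "pairwise_fst.tsv"),
            os.path.join(cfg.outdir, "asfst_contrast.json")]
        if not reuse(stage):
            try:
                per_variant = {}
                for a, f in zip(cfg.fst_ancestries, per_variant_files):
                    pv = fst.asfst_per_variant(get_masked(a), strata, min_maf=cfg.maf)
                    pv.to_csv(f, sep="\t", index=False)
                    per_variant[a] = pv.set_index("variant")["theta"]
                W, _ = fst.pairwise_state_fst(haps, strata)
                W.to_csv(files[-2], sep="\t")
                a0, a1 = cfg.fst_ancestries[:2]
                shared = per_variant[a0].index.intersection(per_variant[a1].index)
                contrast = (fst.compare_asfst(per_variant[a0][shared],
                                              per_variant[a1][shared])
                            if len(shared) >= 2 else {"note": "too few shared variants"})
                with open(files[-1], "w") as fh:
                    json.dump(contrast, fh, indent=1)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, files)

    # ---- glm -----------------------------------------------------------
    if "glm" in cfg.stages:
        stage = "glm"
        files = [os.path.join(cfg.outdir, "glm_results.tsv"),
                 os.path.join(cfg.outdir, "glm_categories.tsv")]
        if not reuse(stage):
            try:
                fractions = calls.genome_fractions()
                preds = glm.build_predictors(fractions, meta)
                results, skipped = glm.glm_scan(haps, preds, alpha=cfg.alpha)
                results.to_csv(files[0], sep="\t", index=False)
                glm.upset_categories(results).rename_axis("category") \
                    .to_frame("count").to_csv(files[1], sep="\t")
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, files)

    # ---- curate --------------------------------------------------------
    if "curate" in cfg.stages and cfg.annotations:
        stage = "curate"
        files = [os.path.join(cfg.outdir, "curated_variants.tsv")]
        if not reuse(stage):
            try:
                ann = pd.concat([catalog.read_annotations(p, src)
                                 for src, p in sorted(cfg.annotations.items())],
                                ignore_index=True)
                ids = set(haps.variant_ids())
                rsids = set(haps.variants["rsid"].astype(str)) - {"."}
                cur = catalog.curate(ann, genotyped_rsids=rsids | ids)
                panel = (catalog.GenePanel.from_file(cfg.gene_panel, "panel")
                         if cfg.gene_panel else catalog.GenePanel("empty", frozenset()))
                cur = catalog.classify_actionable(cur, panel)
                cur["top_drug"] = [catalog.top_drug(d) for d in cur["drugs"]]
                freq_tab = frequencies.read_frequency_table(freq_all_path) \
                    if os.path.exists(freq_all_path) \
                    else frequencies.allele_frequency(haps, strata)
                kept = set(catalog.maf_filter(freq_tab, list(cur["rsid"].astype(str)),
                                              threshold=cfg.maf))
                cur["passes_maf"] = cur["rsid"].astype(str).isin(kept)
                cur.to_csv(files[0], sep="\t", index=False)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, files)

    # ---- error_sim -----------------------------------------------------
    if "error_sim" in cfg.stages:
        stage = "error_sim"
        files = [os.path.join(cfg.outdir, "asf_error_sim.tsv")]
        if not reuse(stage):
            try:
                cm = (ConfusionMatrix.read_tsv(cfg.confusion_matrix)
                      if cfg.confusion_matrix else default_confusion_matrix())
                es = {"n_individuals": 200, "maf_grid": [0.05, 0.1, 0.25, 0.5],
                      "n_replicates": 8, **cfg.error_sim}
                sim_cfg = SimulationConfig(
                    n_individuals=int(es["n_individuals"]), seed=cfg.seed,
                    n_sites=4,
                )
                table = asf_error_experiment(
                    sim_cfg, cm, list(es["maf_grid"]),
                    n_replicates=int(es["n_replicates"]), seed=cfg.seed + 101)
                table.to_csv(files[0], sep="\t", index=False)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            record(stage, files)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def default_confusion_matrix(accuracy: float = 0.95) -> ConfusionMatrix:
    """A simple caller-error model: ``accuracy`` on the diagonal, the rest
    spread evenly over the other ancestries."""
    K = 4
    off = (1 - accuracy) / (K - 1)
    m = np.full((K, K), off)
    np.fill_diagonal(m, accuracy)
    return ConfusionMatrix(m)


# ---------------------------------------------------------------------------
# version-controlled-size fixtures for tests and docs
# ---------------------------------------------------------------------------

def make_fixtures(outdir: str, seed: int = 7) -> dict[str, str]:
    """Write a small, edge-case-rich synthetic bundle (VCF, MSP, metadata,
    annotations, gene panel, confusion matrix).

    Designed-in edge cases: an ancestry with zero tracts (EAS; its mask is
    all-missing), a monomorphic site, a site failing the 5% MAF filter, a
    conflicting ClinVar-like interpretation, and a PharmGKB evidence-level
    tie.
    """
    rng = np.random.default_rng(seed)
    n_sites = 40
    freqs = rng.uniform(0.1, 0.9, size=(n_sites, 4))
    freqs[0] = 0.0          # monomorphic site
    freqs[1] = 0.01         # fails the MAF filter
    cfg = SimulationConfig(
        n_individuals=20,
        proportions_by_stratum=np.array([[0.05, 0.30, 0.0, 0.65],
                                         [0.05, 0.55, 0.0, 0.40]]),
        stratum_labels=("south", "north"),
        stratum_coords=np.array([[16.0, -92.0], [29.0, -110.0]]),
        chrom_lengths_morgans=(0.5,),
        n_sites=n_sites,
        per_ancestry_freqs=freqs,
        seed=seed,
    )
    paths = simulate_cohort(cfg, outdir)

    ann_clinvar = pd.DataFrame([
        # rsid, chrom, pos, ref, alt, gene, significance, level, drugs, phenotype, cites
        ("site00002", "1", 0, "A", "G", "BRCA2", "Pathogenic", "", "",
         "hereditary cancer", "PMID:1"),
        ("site00003", "1", 0, "A", "G", "LDLR", "Likely pathogenic", "", "",
         "hypercholesterolemia", "PMID:2"),
        ("site00004", "1", 0, "A", "G", "MYH7", "Conflicting interpretations of pathogenicity",
         "", "", "cardiomyopathy", "PMID:3"),
        ("site00005", "1", 0, "A", "G", "TTN2", "Benign", "", "",
         "none", "PMID:4"),
        ("rs_absent", "9", 999, "C", "T", "GHOST", "Pathogenic", "", "",
         "not genotyped", "PMID:5"),
    ], columns=catalog.ANNOTATION_COLUMNS)
    ann_pharmgkb = pd.DataFrame([
        ("site00002", "1", 0, "A", "G", "BRCA2", "", "1A",
         "simvastatin:1A;warfarin:2B", "drug response", "PMID:6"),
        ("site00006", "1", 0, "A", "G", "CYP3A4", "", "2B",
         "alpha:2A;beta:2A", "fentanyl metabolism", "PMID:7"),  # evidence tie
        ("site00007", "1", 0, "A", "G", "SLCO1B1", "", "3",
         "pravastatin:3", "statin myopathy", "PMID:8"),
    ], columns=catalog.ANNOTATION_COLUMNS)
    sites = cfg.site_table().set_index("site")
    for df in (ann_clinvar, ann_pharmgkb):
        known = df["rsid"].isin(sites.index)
        df.loc[known, "pos"] = sites.loc[df.loc[known, "rsid"], "pos"].to_numpy()
    paths["clinvar"] = os.path.join(outdir, "annotations_clinvar.tsv")
    paths["pharmgkb"] = os.path.join(outdir, "annotations_pharmgkb.tsv")
    ann_clinvar.to_csv(paths["clinvar"], sep="\t", index=False)
    ann_pharmgkb.to_csv(paths["pharmgkb"], sep="\t", index=False)

    paths["gene_panel"] = os.path.join(outdir, "acmg_panel.txt")
    with open(paths["gene_panel"], "w") as fh:
        fh.write("\n".join(["BRCA2", "LDLR", "MYH7", "TTN2"]) + "\n")

    paths["confusion_matrix"] = os.path.join(outdir, "confusion.tsv")
    default_confusion_matrix(0.95).write_tsv(paths["confusion_matrix"])

    paths["pipeline_config"] = os.path.join(outdir, "pipeline.yaml")
    with open(paths["pipeline_config"], "w") as fh:
        yaml.safe_dump({
            "outdir": os.path.join(outdir, "run"),
            "vcf": paths["vcf"], "msp": paths["msp"], "metadata": paths["metadata"],
            "annotations": {"clinvar": paths["clinvar"],
                            "pharmgkb": paths["pharmgkb"]},
            "gene_panel": paths["gene_panel"],
            "confusion_matrix": paths["confusion_matrix"],
            "seed": seed,
            "error_sim": {"n_individuals": 60, "n_replicates": 3,
                          "maf_grid": [0.1, 0.5]},
        }, fh)
    return paths
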