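"""Synthetic admixed cohorts with known local-ancestry ground truth.

The generator emulates a nationwide admixed cohort sampled from G geographic
strata, with K=4 continental ancestries (African, European, East Asian,
Indigenous American) whose admixture proportions vary along a latitudinal
cline.  Haplotypes are built under a single-pulse admixture approximation:
``g`` generations after admixture, recombination breakpoints along a
chromosome of genetic length L form a Poisson process of rate ``g`` per
Morgan, and the ancestry of each resulting segment is drawn i.i.d. from the
stratum's proportion vector.  Alleles are then Bernoulli draws from
per-ancestry site frequencies, so the true ancestry-specific frequency of
every site is known by construction.

Ancestry-caller noise is modelled by re-assigning the ancestry of fixed
genetic-map windows (default 0.2 cM) i.i.d. from the row of a K x K
confusion matrix corresponding to the window's true ancestry.

All genomic coordinates live on a 1 bp lattice under a constant map of
1 cM/Mb (1 Morgan = 1e8 bp), so genetic (Morgan) and physical (bp)
representations convert exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import AncestryCalls, ConfusionMatrix
from .haplotypes import HaplotypeSet

logger = logging.getLogger(__name__)

BP_PER_MORGAN = 100_000_000  # constant 1 cM/Mb map

DEFAULT_LABELS = ("AFR", "EUR", "EAS", "IND")
#: nationwide admixture proportions (Afr, Eur, Eas, Ind) used as defaults
DEFAULT_PROPORTIONS = (0.04, 0.30, 0.01, 0.65)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic admixed cohort.

    Defaults mirror a nationwide Mexican cohort design: 6,011 diploid
    individuals, four-way admixture with nationwide proportions
    (AFR, EUR, EAS, IND) = (0.04, 0.30, 0.01, 0.65), and ~16 generations
    since the onset of admixture.
    """

    n_individuals: int = 6011
    ancestry_labels: tuple[str, ...] = DEFAULT_LABELS
    proportions_by_stratum: np.ndarray = field(
        default_factory=lambda: np.array([DEFAULT_PROPORTIONS])
    )
    stratum_labels: tuple[str, ...] | None = None
    stratum_coords: np.ndarray | None = None  # (G, 2) latitude, longitude
    generations: int = 16
    chrom_lengths_morgans: tuple[float, ...] = (1.0,)
    n_sites: int = 100
    per_ancestry_freqs: np.ndarray | None = None  # (n_sites, K)
    regional_ancestry: str | None = None
    regional_freqs: np.ndarray | None = None  # (G, n_sites) override column
    seed: int = 0

    def __post_init__(self) -> None:
        self.proportions_by_stratum = np.atleast_2d(
            np.asarray(self.proportions_by_stratum, dtype=float)
        )
        G = self.proportions_by_stratum.shape[0]
        if self.stratum_labels is None:
            self.stratum_labels = tuple(f"stratum{i}" for i in range(G))
        if self.stratum_coords is None:
            # arbitrary south-to-north line if the caller gave no geography
            self.stratum_coords = np.column_stack(
                [np.linspace(15.0, 32.0, G), np.linspace(-92.0, -110.0, G)]
            )
        else:
            self.stratum_coords = np.asarray(self.stratum_coords, dtype=float)
        if self.per_ancestry_freqs is not None:
            self.per_ancestry_freqs = np.asarray(self.per_ancestry_freqs, float)
        if self.regional_freqs is not None:
            self.regional_freqs = np.asarray(self.regional_freqs, float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        K = len(self.ancestry_labels)
        P = self.proportions_by_stratum
        if P.shape[1] != K:
            raise ConfigError(f"proportions have {P.shape[1]} columns, need {K}")
        if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("each stratum's proportions must be a probability "
                              "vector summing to 1")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if self.n_individuals < 1:
            raise ConfigError("need at least one individual")
        if any(length <= 0 for length in self.chrom_lengths_morgans):
            raise ConfigError("chromosome lengths must be positive")
        if len(self.stratum_labels) != P.shape[0]:
            raise ConfigError("stratum_labels length mismatch")
        if self.stratum_coords.shape != (P.shape[0], 2):
            raise ConfigError("stratum_coords must be (G, 2)")
        if self.per_ancestry_freqs is not None:
            F = self.per_ancestry_freqs
            if F.shape != (self.n_sites, K):
                raise ConfigError(f"per_ancestry_freqs must be ({self.n_sites}, {K})")
            if (F < 0).any() or (F > 1).any():
                raise ConfigError("frequencies must lie in [0, 1]")
        if (self.regional_ancestry is None) != (self.regional_freqs is None):
            raise ConfigError("regional_ancestry and regional_freqs go together")
        if self.regional_freqs is not None:
            if self.regional_freqs.shape != (P.shape[0], self.n_sites):
                raise ConfigError("regional_freqs must be (G, n_sites)")
            if self.regional_ancestry not in self.ancestry_labels:
                raise ConfigError(f"unknown regional ancestry {self.regional_ancestry}")

    # -- derived quantities ---------------------------------------------
    @property
    def n_strata(self) -> int:
        return self.proportions_by_stratum.shape[0]

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestry_labels)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(str(i + 1) for i in range(len(self.chrom_lengths_morgans)))

    @property
    def code_book(self) -> dict[int, str]:
        return dict(enumerate(self.ancestry_labels))

    def stratum_of(self, individual: int) -> int:
        """Block assignment of individuals to strata (near-equal sizes)."""
        return min(individual * self.n_strata // self.n_individuals,
                   self.n_strata - 1)

    def site_table(self) -> pd.DataFrame:
        """Deterministic site placement: evenly spaced 1-based bp positions.

        Sites are apportioned to chromosomes proportionally to genetic
        length.  Columns: site, chrom, pos (bp), gpos (Morgans).
        """
        lengths = np.asarray(self.chrom_lengths_morgans, float)
        raw = lengths / lengths.sum() * self.n_sites
        counts = np.floor(raw).astype(int)
        for _ in range(self.n_sites - counts.sum()):
            counts[np.argmax(raw - counts)] += 1
        rows = []
        k = 0
        for name, L, m in zip(self.chrom_names, lengths, counts):
            L_bp = int(round(L * BP_PER_MORGAN))
            pos = np.round(np.arange(1, m + 1) * L_bp / (m + 1)).astype(np.int64)
            for p in pos:
                rows.append((f"site{k:05d}", name, int(p), (int(p) - 1) / BP_PER_MORGAN))
                k += 1
        return pd.DataFrame(rows, columns=["site", "chrom", "pos", "gpos"])

    def freqs_for(self, stratum: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-ancestry site frequencies for one stratum, ``(n_sites, K)``.

        If ``per_ancestry_freqs`` was not supplied, frequencies are drawn
        once from Uniform(0.05, 0.95) using the config seed (so repeated
        calls agree).
        """
        if self.per_ancestry_freqs is None:
            rng = np.random.default_rng(self.seed + 777)
            self.per_ancestry_freqs = rng.uniform(
                0.05, 0.95, size=(self.n_sites, self.n_ancestries)
            )
        F = self.per_ancestry_freqs.copy()
        if self.regional_ancestry is not None:
            j = self.ancestry_labels.index(self.regional_ancestry)
            F[:, j] = self.regional_freqs[stratum]
        return F

    @classmethod
    def cline(
        cls,
        n_individuals: int,
        n_strata: int,
        north_proportions: tuple[float, ...],
        south_proportions: tuple[float, ...],
        north_lat: float = 32.0,
        south_lat: float = 15.0,
        **kwargs,
    ) -> "SimulationConfig":
        """Build a config whose strata interpolate linearly between two
        anchor proportion vectors along latitude (south = index 0)."""
        t = np.linspace(0.0, 1.0, n_strata)[:, None]  # 0 = south, 1 = north
        south = np.asarray(south_proportions, float)
        north = np.asarray(north_proportions, float)
        props = (1 - t) * south + t * north
        lats = np.linspace(south_lat, north_lat, n_strata)
        # non-monotone east-west placement so longitude is not collinear
        # with latitude in downstream regressions
        lons = -101.0 - 9.0 * np.cos(2 * np.pi * t.ravel())
        return cls(
            n_individuals=n_individuals,
            proportions_by_stratum=props,
            stratum_coords=np.column_stack([lats, lons]),
            **kwargs,
        )


@dataclass
class TractSet:
    """Local-ancestry tracts of a set of haplotypes, in genetic coordinates.

    For each chromosome ``c`` and haplotype ``h``, ``breaks[c][h]`` holds the
    sorted interior breakpoints (Morgans) and ``codes[c][h]`` the ancestry
    codes of the ``len(breaks)+1`` segments tiling ``[0, chrom_length)``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[float, ...]
    code_book: dict[int, str]
    breaks: list[list[np.ndarray]]
    codes: list[list[np.ndarray]]

    @property
    def n_haplotypes(self) -> int:
        return len(self.breaks[0])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.code_book[k] for k in sorted(self.code_book))

    def ancestry_at(self, chrom_index: int, gpos: np.ndarray) -> np.ndarray:
        """Ancestry code of every haplotype at each position: ``(2N, m)``.

        Segments are half-open, so a position equal to a breakpoint belongs
        to the segment that starts there.
        """
        gpos = np.asarray(gpos, float)
        L = self.chrom_lengths[chrom_index]
        if (gpos < 0).any() or (gpos >= L).any():
            raise ValueError("position outside [0, chromosome length) — tiling violation")
        out = np.empty((self.n_haplotypes, len(gpos)), np.int8)
        br, cd = self.breaks[chrom_index], self.codes[chrom_index]
        for h in range(self.n_haplotypes):
            out[h] = cd[h][np.searchsorted(br[h], gpos, side="right")]
        return out

    def genome_fractions(self) -> np.ndarray:
        """``(2N, K)`` genome fraction of each ancestry per haplotype."""
        K = len(self.code_book)
        out = np.zeros((self.n_haplotypes, K))
        for ci, L in enumerate(self.chrom_lengths):
            for h in range(self.n_haplotypes):
                edges = np.concatenate(([0.0], self.breaks[ci][h], [L]))
                np.add.at(out[h], self.codes[ci][h], np.diff(edges))
        return out / sum(self.chrom_lengths)

    def merged(self) -> "TractSet":
        """Merge adjacent segments with equal ancestry codes."""
        new_breaks, new_codes = [], []
        for ci in range(len(self.chrom_names)):
            nb, nc = [], []
            for h in range(self.n_haplotypes):
                cd = self.codes[ci][h]
                keep = np.nonzero(cd[1:] != cd[:-1])[0]
                nb.append(self.breaks[ci][h][keep])
                nc.append(np.concatenate(([cd[0]], cd[keep + 1])))
            new_breaks.append(nb)
            new_codes.append(nc)
        return TractSet(self.chrom_names, self.chrom_lengths, dict(self.code_book),
                        new_breaks, new_codes)

    def to_ancestry_calls(self, samples: list[str]) -> AncestryCalls:
        """Convert to physical-coordinate interval calls (exact union rows).

        Rows are the union of all haplotype breakpoints, so the result is an
        exact MSP-style representation of the tracts; intended for cohort
        sizes where ``total breakpoints`` stays modest.
        """
        if 2 * len(samples) != self.n_haplotypes:
            raise ValueError("need exactly 2 haplotypes per sample")
        intervals = {}
        for ci, (name, L) in enumerate(zip(self.chrom_names, self.chrom_lengths)):
            edges = np.unique(np.concatenate(
                [np.concatenate(self.breaks[ci])] if self.breaks[ci] else [[]]
            ))
            edges = np.concatenate(([0.0], edges, [L]))
            mids = (edges[:-1] + edges[1:]) / 2.0
            codes = self.ancestry_at(ci, mids).T.astype(np.int8)  # (rows, 2N)
            spos = np.round(edges[:-1] * BP_PER_MORGAN).astype(np.int64) + 1
            epos = np.round(edges[1:] * BP_PER_MORGAN).astype(np.int64) + 1
            intervals[name] = (spos, epos, codes)
        return AncestryCalls(code_book=dict(self.code_book), samples=list(samples),
                             intervals=intervals)

    def tract_table(self, samples: list[str]) -> pd.DataFrame:
        """Long-format truth table: one row per (haplotype, tract)."""
        rows = []
        for ci, (name, L) in enumerate(zip(self.chrom_names, self.chrom_lengths)):
            for h in range(self.n_haplotypes):
                edges = np.concatenate(([0.0], self.breaks[ci][h], [L]))
                for s, e, c in zip(edges[:-1], edges[1:], self.codes[ci][h]):
                    rows.append((
                        f"{samples[h // 2]}.{h % 2}", name,
                        int(round(s * BP_PER_MORGAN)) + 1,
                        int(round(e * BP_PER_MORGAN)) + 1,
                        self.code_book[int(c)],
                    ))
        return pd.DataFrame(rows, columns=["haplotype", "chrom", "spos", "epos",
                                           "ancestry"])


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def simulate_tracts(
    config: SimulationConfig,
    stratum: int = 0,
    n_haplotypes: int | None = None,
    rng: np.random.Generator | None = None,
) -> TractSet:
    """Simulate ancestry tracts for one stratum's haplotypes.

    Breakpoints along each chromosome are a Poisson process of rate
    ``generations`` per Morgan (single-pulse admixture approximation) and
    segment ancestries are i.i.d. draws from the stratum's proportion
    vector, so the expected genome-wide ancestry fractions equal that
    vector.  Breakpoints land on the 1 bp lattice.
    """
    if not 0 <= stratum < config.n_strata:
        raise ConfigError(f"stratum {stratum} out of range")
    props = config.proportions_by_stratum[stratum]
    cum = np.cumsum(props)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if n_haplotypes is None:
        block = [i for i in range(config.n_individuals)
                 if config.stratum_of(i) == stratum]
        n_haplotypes = 2 * len(block)
    g = config.generations
    breaks, codes = [], []
    for L in config.chrom_lengths_morgans:
        L_bp = int(round(L * BP_PER_MORGAN))
        nb = rng.poisson(g * L, size=n_haplotypes)
        cb, cc = [], []
        for h in range(n_haplotypes):
            pos = np.unique(rng.integers(1, L_bp, size=nb[h])) / BP_PER_MORGAN
            anc = np.searchsorted(cum, rng.random(len(pos) + 1), side="right")
            cb.append(pos)
            cc.append(np.minimum(anc, len(props) - 1).astype(np.int8))
        breaks.append(cb)
        codes.append(cc)
    return TractSet(config.chrom_names, tuple(config.chrom_lengths_morgans),
                    config.code_book, breaks, codes)


def assign_alleles(
    tracts: TractSet,
    config: SimulationConfig,
    stratum: int = 0,
    rng: np.random.Generator | None = None,
    samples: list[str] | None = None,
    site_table: pd.DataFrame | None = None,
    freqs: np.ndarray | None = None,
) -> HaplotypeSet:
    """Draw alleles: Bernoulli(f_k) with k the tract ancestry covering each site.

    ``freqs`` (``n_sites x K``) defaults to the config's per-ancestry site
    frequencies for ``stratum``.  Returns a fully called, phased
    :class:`HaplotypeSet`.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sites = site_table if site_table is not None else config.site_table()
    F = freqs if freqs is not None else config.freqs_for(stratum)
    if F.shape != (len(sites), len(tracts.code_book)):
        raise ConfigError("frequency matrix does not match sites x ancestries")
    n_hap = tracts.n_haplotypes
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n_hap // 2)]
    alleles = np.empty((n_hap, len(sites)), np.int8)
    for ci, name in enumerate(tracts.chrom_names):
        sel = np.flatnonzero((sites["chrom"] == name).to_numpy())
        if sel.size == 0:
            continue
        codes = tracts.ancestry_at(ci, sites["gpos"].to_numpy()[sel])
        f_cell = F[sel][np.arange(sel.size)[None, :], codes]
        alleles[:, sel] = (rng.random(codes.shape) < f_cell).astype(np.int8)
    variants = pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"], "rsid": sites["site"],
        "ref": "A", "alt": "G",
    })
    return HaplotypeSet(samples=samples, variants=variants, alleles=alleles)


def corrupt_ancestry(
    tracts: TractSet,
    cm: ConfusionMatrix,
    window_cm: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> TractSet:
    """Apply confusion-matrix noise to ancestry calls in fixed map windows.

    The genome is partitioned into windows of ``window_cm`` centimorgans
    (mimicking window-based local-ancestry callers), additionally split at
    each haplotype's true tract boundaries so every window has a single
    well-defined true ancestry; each window's assigned ancestry is drawn
    independently from the confusion-matrix row of its true ancestry.  The
    identity matrix therefore reproduces the input tracts exactly (after
    merging).
    """
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    if tuple(cm.labels) != tracts.labels:
        raise ValueError(f"confusion labels {cm.labels} != tract labels {tracts.labels}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    w = window_cm / 100.0
    cumrows = np.cumsum(cm.matrix, axis=1)
    n_hap = tracts.n_haplotypes
    breaks, codes = [], []
    for ci, L in enumerate(tracts.chrom_lengths):
        n_win = max(1, int(np.ceil(L / w - 1e-9)))
        L_bp = int(round(L * BP_PER_MORGAN))
        # snap window edges to the bp lattice to keep coordinates exact
        edges_bp = np.round(np.arange(1, n_win) * w * BP_PER_MORGAN)
        fixed = np.unique(np.clip(edges_bp, 1, L_bp - 1)) / BP_PER_MORGAN
        cb, cc = [], []
        for h in range(n_hap):
            edges = np.union1d(fixed, tracts.breaks[ci][h])
            starts = np.concatenate(([0.0], edges))
            true = tracts.codes[ci][h][
                np.searchsorted(tracts.breaks[ci][h], starts, side="right")]
            u = rng.random(len(starts))
            assigned = (u[:, None] > cumrows[true]).sum(-1).astype(np.int8)
            cb.append(edges)
            cc.append(np.minimum(assigned, len(cm.labels) - 1))
        breaks.append(cb)
        codes.append(cc)
    return TractSet(tracts.chrom_names, tracts.chrom_lengths,
                    dict(tracts.code_book), breaks, codes)


# ---------------------------------------------------------------------------
# cohort generation and the ancestry-call error experiment
# ---------------------------------------------------------------------------

def simulate_full_cohort(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeSet, TractSet, pd.DataFrame]:
    """Simulate tracts + alleles for every stratum; return the assembled cohort.

    Individuals are assigned to strata in contiguous blocks of near-equal
    size; each stratum uses its own proportion vector and (optionally
    region-varying) per-ancestry site frequencies.  Returns the haplotypes,
    the ground-truth tracts (in the same haplotype order) and the sample
    metadata table (sample_id, stratum, latitude, longitude).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites = config.site_table()
    samples = [f"S{i:05d}" for i in range(config.n_individuals)]
    strata_of = np.array([config.stratum_of(i) for i in range(config.n_individuals)])
    hap_sets, tract_sets = [], []
    for s in range(config.n_strata):
        n_ind = int((strata_of == s).sum())
        if n_ind == 0:
            continue
        tr = simulate_tracts(config, stratum=s, n_haplotypes=2 * n_ind, rng=rng)
        ids = [samples[i] for i in np.flatnonzero(strata_of == s)]
        hs = assign_alleles(tr, config, stratum=s, rng=rng, samples=ids,
                            site_table=sites)
        tract_sets.append(tr)
        hap_sets.append(hs)
    haps = HaplotypeSet(
        samples=[s for hs in hap_sets for s in hs.samples],
        variants=hap_sets[0].variants,
        alleles=np.concatenate([hs.alleles for hs in hap_sets], axis=0),
    )
    tracts = TractSet(
        chrom_names=config.chrom_names,
        chrom_lengths=tuple(config.chrom_lengths_morgans),
        code_book=config.code_book,
        breaks=[[b for tr in tract_sets for b in tr.breaks[ci]]
                for ci in range(len(config.chrom_names))],
        codes=[[c for tr in tract_sets for c in tr.codes[ci]]
               for ci in range(len(config.chrom_names))],
    )
    meta = pd.DataFrame({
        "sample_id": haps.samples,
        "stratum": [config.stratum_labels[s] for s in strata_of],
        "latitude": config.stratum_coords[strata_of, 0],
        "longitude": config.stratum_coords[strata_of, 1],
    })
    return haps, tracts, meta


def simulate_cohort(config: SimulationConfig, outdir: str) -> dict[str, str]:
    """Generate a cohort and write the cross-consistent file bundle.

    Writes ``cohort.vcf`` (phased GT), ``cohort.msp.tsv`` (true local
    ancestry in MSP dialect), ``metadata.tsv`` and two truth tables
    (``truth_tracts.tsv``, ``truth_freqs.tsv``).  Fully deterministic under
    the config seed.  Returns the mapping of output names to paths.
    """
    import os

    from .haplotypes import write_vcf
    from .ancestry import write_msp

    os.makedirs(outdir, exist_ok=True)
    haps, tracts, meta = simulate_full_cohort(config)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("vcf", "cohort.vcf"), ("msp", "cohort.msp.tsv"),
        ("metadata", "metadata.tsv"), ("truth_tracts", "truth_tracts.tsv"),
        ("truth_freqs", "truth_freqs.tsv"),
    ]}
    try:
        write_vcf(haps, paths["vcf"])
        write_msp(tracts.to_ancestry_calls(haps.samples), paths["msp"],
                  bp_per_morgan=BP_PER_MORGAN)
        meta.to_csv(paths["metadata"], sep="\t", index=False)
        tracts.tract_table(haps.samples).to_csv(paths["truth_tracts"], sep="\t",
                                                index=False)
        sites = config.site_table()
        truth = []
        for s in range(config.n_strata):
            F = config.freqs_for(s)
            block = sites[["site", "chrom", "pos"]].copy()
            block["stratum"] = config.stratum_labels[s]
            for j, lab in enumerate(config.ancestry_labels):
                block[f"f_{lab}"] = F[:, j]
            truth.append(block)
        pd.concat(truth, ignore_index=True).to_csv(paths["truth_freqs"], sep="\t",
                                                   index=False)
    except OSError as exc:
        raise OSError(f"failed writing cohort files under {outdir}: {exc}") from exc
    logger.info("cohort written to %s (%d individuals, %d sites)", outdir,
                config.n_individuals, config.n_sites)
    return paths


def asf_error_experiment(
    config: SimulationConfig,
    cm: ConfusionMatrix,
    maf_grid: list[float],
    n_replicates: int = 20,
    seed: int = 0,
    focal: str = "IND",
    other_freqs: np.ndarray | None = None,
    window_cm: float = 0.2,
    sites_per_point: int = 1,
    stratum: int = 0,
) -> pd.DataFrame:
    """Quantify the impact of ancestry-call errors on asF across a MAF grid.

    For each replicate a fresh cohort of tracts is simulated with the
    stratum's admixture proportions; the focal ancestry's allele frequency
    sweeps ``maf_grid`` (other ancestries keep ``other_freqs``).  asF is then
    estimated through the masking + frequency machinery twice — once with
    the true ancestry calls and once with confusion-matrix-corrupted calls —
    and summarized per (maf, ancestry, call type).

    Returns a table with columns ``maf, ancestry, call_type, true_f,
    mean_est_f, sd_est_f, n_replicates``.
    """
    from dataclasses import replace as _dcreplace

    from .frequencies import allele_frequency

    if len(maf_grid) == 0:
        raise ValueError("maf_grid must be non-empty")
    if any(not 0 < m < 1 for m in maf_grid):
        raise ValueError("maf_grid values must lie in (0, 1)")
    labels = config.ancestry_labels
    K = len(labels)
    if focal not in labels:
        raise ConfigError(f"unknown focal ancestry {focal!r}")
    jf = labels.index(focal)
    if other_freqs is None:
        other_freqs = config.freqs_for(stratum).mean(axis=0)
    other_freqs = np.asarray(other_freqs, float)

    # one site per (grid point, within-replicate copy), all on chromosome 0
    m = len(maf_grid) * sites_per_point
    L = config.chrom_lengths_morgans[0]
    L_bp = int(round(L * BP_PER_MORGAN))
    pos = np.round(np.arange(1, m + 1) * L_bp / (m + 1)).astype(np.int64)
    sites = pd.DataFrame({
        "site": [f"site{k:05d}" for k in range(m)],
        "chrom": config.chrom_names[0],
        "pos": pos, "gpos": (pos - 1) / BP_PER_MORGAN,
    })
    F = np.tile(other_freqs, (m, 1))
    F[:, jf] = np.repeat(np.asarray(maf_grid, float), sites_per_point)

    single = _dcreplace(
        config,
        chrom_lengths_morgans=(L,),
        n_sites=m,
        per_ancestry_freqs=None,
        regional_ancestry=None,
        regional_freqs=None,
    )
    rng = np.random.default_rng(seed)
    # est[call_type][ancestry] -> (replicate, grid point) frequency estimates
    est = {ct: np.full((K, n_replicates, len(maf_grid)), np.nan)
           for ct in ("true", "corrupted")}
    for rep in range(n_replicates):
        tracts = simulate_tracts(single, stratum=stratum,
                                 n_haplotypes=2 * config.n_individuals, rng=rng)
        haps = assign_alleles(tracts, single, stratum=stratum, rng=rng,
                              site_table=sites, freqs=F)
        corrupted = corrupt_ancestry(tracts, cm, window_cm=window_cm, rng=rng)
        for call_type, tr in (("true", tracts), ("corrupted", corrupted)):
            codes = tr.ancestry_at(0, sites["gpos"].to_numpy())
            for j, lab in enumerate(labels):
                masked = _dcreplace(
                    haps,
                    alleles=np.where(codes == j, haps.alleles, np.int8(-1)),
                    variants=haps.variants.copy(),
                    mask_ancestry=lab,
                )
                tab = allele_frequency(masked)
                # pool the replicate's sites_per_point copies per grid point
                alt = tab["alt_count"].to_numpy().reshape(len(maf_grid),
                                                          sites_per_point).sum(1)
                called = tab["called_count"].to_numpy().reshape(
                    len(maf_grid), sites_per_point).sum(1)
                with np.errstate(invalid="ignore"):
                    est[call_type][j, rep] = np.where(called > 0, alt / np.maximum(called, 1),
                                                      np.nan)
    rows = []
    for call_type in ("true", "corrupted"):
        for j, lab in enumerate(labels):
            for gi, maf in enumerate(maf_grid):
                vals = est[call_type][j, :, gi]
                vals = vals[~np.isnan(vals)]
                true_f = maf if j == jf else float(other_freqs[j])
                rows.append((maf, lab, call_type, true_f,
                             float(np.mean(vals)) if len(vals) else np.nan,
                             float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                             len(vals)))
    return pd.DataFrame(rows, columns=["maf", "ancestry", "call_type", "true_f",
                                       "mean_est_f", "sd_est_f", "n_replicates"])
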