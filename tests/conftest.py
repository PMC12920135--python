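import numpy as np
import pandas as pd
import pytest

from admixfreq.ancestry import AncestryCalls
from admixfreq.haplotypes import HaplotypeSet
from admixfreq.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The bundled toy cohort: VCF + MSP + metadata + annotations + panel."""
    outdir = tmp_path_factory.mktemp("bundle")
    return make_fixtures(str(outdir), seed=7)


def random_haps_and_calls(seed: int, n_samples: int = 12, n_sites: int = 30,
                          k: int = 4, missing_rate: float = 0.05):
    """A random phased cohort with window-based ancestry calls (K ancestries)."""
    rng = np.random.default_rng(seed)
    chrom_len = 1_000_000
    pos = np.sort(rng.choice(np.arange(1, chrom_len), size=n_sites, replace=False))
    alleles = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.int8)
    alleles[rng.random(alleles.shape) < missing_rate] = -1
    samples = [f"S{i:03d}" for i in range(n_samples)]
    variants = pd.DataFrame({
        "chrom": "1", "pos": pos, "rsid": [f"rs{i}" for i in range(n_sites)],
        "ref": "A", "alt": "G",
    })
    haps = HaplotypeSet(samples=samples, variants=variants, alleles=alleles)
    n_win = 10
    edges = np.linspace(1, chrom_len + 1, n_win + 1).astype(np.int64)
    codes = rng.integers(0, k, size=(n_win, 2 * n_samples)).astype(np.int8)
    calls = AncestryCalls(
        code_book={0: "AFR", 1: "EUR", 2: "EAS", 3: "IND"},
        samples=samples,
        intervals={"1": (edges[:-1], edges[1:], codes)},
    )
    return haps, calls
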