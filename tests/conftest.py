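import numpy as np
import pytest

from sweepscan import sim_data
from sweepscan.core import GenotypeMatrix, HaplotypeMatrix


def maf_filter(hap: HaplotypeMatrix, maf_min: float = 0.05) -> HaplotypeMatrix:
    """Minimal selection-track QC for complete simulated haplotypes."""
    d = hap.derived_counts()
    n = hap.n_hap
    maf = np.minimum(d, n - d) / n
    return hap.take_sites(np.flatnonzero(maf > maf_min))


def hwe_genotypes(rng, n_samples: int, freqs: np.ndarray) -> GenotypeMatrix:
    """Random-mating diploid genotypes at the given ALT frequencies."""
    S = freqs.size
    dos = (rng.random((n_samples, S)) < freqs).astype(np.int8)
    dos += (rng.random((n_samples, S)) < freqs).astype(np.int8)
    pos = np.arange(1, S + 1) * 100
    return GenotypeMatrix(dos, np.full(S, "1", dtype=object), pos,
                          np.full(S, "A", dtype=object),
                          np.full(S, "C", dtype=object))


@pytest.fixture(scope="session")
def neutral_hap():
    cfg = sim_data.SimConfig(n_individuals=20, chrom_length_bp=2_000_000,
                             target_snp_count=4000, seed=7)
    return sim_data.simulate_neutral_haplotypes(cfg)


@pytest.fixture(scope="session")
def swept_hap(neutral_hap):
    spec = sim_data.SweepSpec(focal_pos=1_000_000, carrier_fraction=0.6,
                              core_halfwidth_bp=150_000)
    return sim_data.apply_sweep(neutral_hap, spec, seed=11)
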