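"""Synthetic phased-haplotype data with known neutral/sweep structure.

The neutral generator is deliberately not a coalescent simulator.  Sites get
derived-allele counts drawn from the neutral frequency spectrum
(``P(k) proportional to 1/k``), and linkage arises from a founder-style
lineage ordering that mixes slowly along the chromosome: at every site the
``k`` carriers are the current top-``k`` lineages of the ordering, and the
ordering is perturbed between sites by random lineage swaps at a rate set by
``ld_block_bp``.  Nearby sites therefore share nested carrier sets (positive
LD that decays over ``ld_block_bp``), while the marginal site-frequency
spectrum is exactly the drawn one.

A hard sweep is caricatured by copying one donor haplotype onto a random
carrier set over a core interval, which produces the long shared haplotype,
depressed diversity and skewed frequency spectrum that the downstream scan
statistics detect.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import HaplotypeMatrix

__all__ = [
    "SimConfig",
    "SweepSpec",
    "simulate_neutral_haplotypes",
    "apply_sweep",
    "write_simulated_vcf",
    "make_gene_annotation",
    "HARD_FILTER_RULES",
]

#: hard-filter rule name -> (annotation attribute, direction, threshold);
#: a site violates a rule when value <op> threshold (op '>' for FS, '<' otherwise)
HARD_FILTER_RULES = {
    "FS": ("fs", ">", 60.0),
    "QD": ("qd", "<", 2.0),
    "MQ": ("mq", "<", 40.0),
    "QUAL": ("qual", "<", 30.0),
    "MQRankSum": ("mq_rank", "<", -12.5),
    "ReadPosRankSum": ("readpos_rank", "<", -8.0),
}


@dataclass(frozen=True)
class SweepSpec:
    """A planted hard sweep: a shared core haplotype around a focal site."""

    focal_pos: int
    carrier_fraction: float
    core_halfwidth_bp: int

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.core_halfwidth_bp <= 0:
            raise ValueError("core_halfwidth_bp must be positive")


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int
    chrom_length_bp: int
    target_snp_count: Optional[int] = None
    theta: float = 0.001  # per-bp scaled mutation intensity, used when target_snp_count is None
    ld_block_bp: float = 50_000.0
    missing_rate: float = 0.0
    bad_site_fraction: float = 0.0
    dp_mean: float = 12.0
    sweep: Optional[SweepSpec] = None
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be positive")
        for name in ("missing_rate", "bad_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.target_snp_count is not None and \
                self.target_snp_count > self.chrom_length_bp:
            raise ValueError("target_snp_count exceeds chromosome length")
        if self.sweep is not None:
            if not 1 <= self.sweep.focal_pos <= self.chrom_length_bp:
                raise ValueError("sweep focal_pos outside chromosome")
            if self.sweep.carrier_fraction * 2 * self.n_individuals < 2:
                raise ValueError("sweep carrier set would have < 2 haplotypes")


def _neutral_sfs_weights(n_hap: int) -> np.ndarray:
    k = np.arange(1, n_hap)
    w = 1.0 / k
    return w / w.sum()


def simulate_neutral_haplotypes(config: SimConfig) -> HaplotypeMatrix:
    """Generate ``2 * n_individuals`` phased haplotypes with neutral SFS + LD.

    Deterministic under ``config.seed``; the sweep field is ignored here
    (apply it separately with :func:`apply_sweep`).
    """
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_individuals
    L = int(config.chrom_length_bp)

    if config.target_snp_count is not None:
        n_sites = int(config.target_snp_count)
    else:
        a1 = (1.0 / np.arange(1, n_hap)).sum()
        n_sites = int(min(L, rng.poisson(config.theta * L * a1)))
    if n_sites > L:
        raise ValueError("target_snp_count exceeds chromosome length")

    pos = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1  # 1-based

    counts = rng.choice(np.arange(1, n_hap), size=n_sites,
                        p=_neutral_sfs_weights(n_hap))

    alleles = np.zeros((n_hap, n_sites), dtype=np.uint8)
    order = rng.permutation(n_hap)
    # lineage swaps per bp; ~n_hap swaps over one ld_block_bp mixes the ordering
    swap_rate = 0.0 if config.ld_block_bp <= 0 else n_hap / float(config.ld_block_bp)
    full_mix = 3 * n_hap  # beyond this many swaps, just reshuffle
    for s in range(n_sites):
        if s > 0:
            gap = int(pos[s] - pos[s - 1])
            if config.ld_block_bp <= 0:
                order = rng.permutation(n_hap)
            else:
                n_swaps = rng.poisson(swap_rate * gap)
                if n_swaps >= full_mix:
                    order = rng.permutation(n_hap)
                elif n_swaps > 0:
                    ij = rng.integers(0, n_hap, size=(n_swaps, 2))
                    for i, j in ij:
                        order[i], order[j] = order[j], order[i]
        alleles[order[: counts[s]], s] = 1
    return HaplotypeMatrix(alleles, pos, chrom=config.chrom)


def apply_sweep(hap: HaplotypeMatrix, spec: SweepSpec, seed: int) -> HaplotypeMatrix:
    """Copy one donor haplotype onto a random carrier set over the core interval.

    Returns a new matrix; sites outside ``focal_pos +- core_halfwidth_bp``
    are untouched.
    """
    rng = np.random.default_rng(seed)
    lo = spec.focal_pos - spec.core_halfwidth_bp
    hi = spec.focal_pos + spec.core_halfwidth_bp
    in_core = (hap.pos >= lo) & (hap.pos <= hi)
    if in_core.all() and hap.n_sites > 0:
        raise ValueError("sweep core spans the whole chromosome")
    if not in_core.any():
        raise ValueError("no site inside the sweep core interval")
    n_carriers = int(np.ceil(spec.carrier_fraction * hap.n_hap))
    if n_carriers < 2:
        raise ValueError("carrier set must contain >= 2 haplotypes")
    carriers = rng.choice(hap.n_hap, size=n_carriers, replace=False)
    donor = int(carriers[0])
    alleles = hap.alleles.copy()
    alleles[np.ix_(carriers, np.flatnonzero(in_core))] = \
        hap.alleles[donor, in_core]
    return HaplotypeMatrix(alleles, hap.pos, hap.chrom)


# ---------------------------------------------------------------------------
# VCF + truth-table output
# ---------------------------------------------------------------------------

_GOOD_RANGES = {
    "FS": (0.0, 30.0),
    "QD": (5.0, 30.0),
    "MQ": (50.0, 60.0),
    "QUAL": (50.0, 1000.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}
_BAD_RANGES = {
    "FS": (60.5, 200.0),
    "QD": (0.0, 1.9),
    "MQ": (10.0, 39.5),
    "QUAL": (1.0, 29.5),
    "MQRankSum": (-20.0, -13.0),
    "ReadPosRankSum": (-15.0, -8.5),
}
_RULE_ORDER = list(HARD_FILTER_RULES)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=sweepscan-sim
##contig=<ID={chrom},length={length}>
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum z">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum z">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_simulated_vcf(hap: HaplotypeMatrix, config: SimConfig,
                        path: str | Path,
                        truth_path: str | Path | None = None) -> int:
    """Write a phased VCF 4.2 with planted annotation/missingness structure.

    A fraction ``config.bad_site_fraction`` of sites gets at least one
    annotation violating the hard-filter thresholds; ``config.missing_rate``
    of genotype calls are set to ``./.``.  The per-site truth table (violated
    rules, missingness) is written as TSV next to the VCF (or at
    ``truth_path``).  Returns the number of sites written.
    """
    path = Path(path)
    if truth_path is None:
        truth_path = path.with_suffix(path.suffix + ".truth.tsv")
    truth_path = Path(truth_path)
    rng = np.random.default_rng([config.seed, 202])
    n_ind = config.n_individuals
    if hap.n_hap != 2 * n_ind:
        raise ValueError("haplotype count does not match config.n_individuals")
    S = hap.n_sites

    # annotations: draw clean values everywhere, then plant violations
    ann = {name: rng.uniform(*_GOOD_RANGES[name], size=S) for name in _RULE_ORDER}
    violated = [[] for _ in range(S)]
    n_bad = int(round(config.bad_site_fraction * S))
    if n_bad:
        bad_sites = rng.choice(S, size=n_bad, replace=False)
        for s in bad_sites:
            n_rules = 1 + rng.binomial(2, 0.2)
            rules = rng.choice(_RULE_ORDER, size=n_rules, replace=False)
            for r in sorted(rules, key=_RULE_ORDER.index):
                ann[r][s] = rng.uniform(*_BAD_RANGES[r])
                violated[s].append(r)

    dp = rng.poisson(config.dp_mean, size=(n_ind, S))
    miss = (rng.random((n_ind, S)) < config.missing_rate) \
        if config.missing_rate > 0 else np.zeros((n_ind, S), dtype=bool)

    ref_alt = np.array(["A", "C", "G", "T"], dtype=object)
    ref_idx = rng.integers(0, 4, size=S)
    alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4

    samples = [f"S{i:03d}" for i in range(n_ind)]
    a = hap.alleles
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=hap.chrom, length=config.chrom_length_bp))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in range(S):
            info = (f"FS={ann['FS'][s]:.3f};QD={ann['QD'][s]:.3f};"
                    f"MQ={ann['MQ'][s]:.3f};MQRankSum={ann['MQRankSum'][s]:.3f};"
                    f"ReadPosRankSum={ann['ReadPosRankSum'][s]:.3f}")
            cells = []
            for i in range(n_ind):
                if miss[i, s]:
                    cells.append(f"./.:{dp[i, s]}")
                else:
                    cells.append(f"{a[2 * i, s]}|{a[2 * i + 1, s]}:{dp[i, s]}")
            fh.write(f"{hap.chrom}\t{hap.pos[s]}\t.\t{ref_alt[ref_idx[s]]}\t"
                     f"{ref_alt[alt_idx[s]]}\t{ann['QUAL'][s]:.2f}\t.\t{info}\t"
                     "GT:DP\t" + "\t".join(cells) + "\n")

    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tviolated_filters\thas_missing\n")
        for s in range(S):
            fh.write(f"{hap.chrom}\t{hap.pos[s]}\t"
                     f"{','.join(violated[s]) if violated[s] else '.'}\t"
                     f"{int(miss[:, s].any())}\n")
    return S


def make_gene_annotation(chrom_length: int, n_genes: int, seed: int,
                         path: str | Path, chrom: str = "1",
                         fmt: str = "gff3") -> int:
    """Write ``n_genes`` random gene intervals (GFF3 1-based inclusive, or BED).

    Intervals are sorted by start, may overlap, and carry stable IDs.
    Returns the number written.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if fmt not in ("gff3", "bed"):
        raise ValueError("fmt must be 'gff3' or 'bed'")
    rng = np.random.default_rng([seed, 303])
    path = Path(path)
    starts = np.sort(rng.integers(1, max(2, chrom_length), size=n_genes))
    lengths = rng.integers(2_000, 50_001, size=n_genes)
    ends = np.minimum(starts + lengths - 1, chrom_length)  # 1-based inclusive
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for i in range(n_genes):
                gid = f"gene{i + 1:04d}"
                fh.write(f"{chrom}\tsim\tgene\t{starts[i]}\t{ends[i]}\t.\t+\t.\t"
                         f"ID={gid};Name={gid.upper()}\n")
        else:
            for i in range(n_genes):
                gid = f"gene{i + 1:04d}"
                fh.write(f"{chrom}\t{starts[i] - 1}\t{ends[i]}\t{gid}\n")
    return n_genes


def file_digest(path: str | Path) -> str:
    """SHA256 of a file, for determinism checks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
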