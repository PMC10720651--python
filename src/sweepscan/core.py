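"""Shared data containers used across the scan pipeline.

Coordinate conventions
----------------------
* VCF positions are 1-based; they are stored as-is in :class:`GenotypeMatrix`
  and :class:`HaplotypeMatrix` (``pos`` arrays).
* All interval types (windows, candidate regions, gene intervals) use
  0-based half-open coordinates internally; converters sit at the file
  boundaries (VCF, GFF3 are 1-based; BED passes through).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: dosage code for a missing diploid genotype
MISSING = -1
#: allele code for a missing haplotype allele (removed by the call-rate rule
#: before any haplotype statistic is computed)
HAP_MISSING = 255


@dataclass
class HaplotypeMatrix:
    """Phased binary alleles: ``n_hap x n_sites`` with physical positions.

    ``0`` is the reference (treated as ancestral downstream), ``1`` the
    alternate allele; :data:`HAP_MISSING` marks alleles of missing genotypes.
    """

    alleles: np.ndarray
    pos: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.pos.size:
            raise ValueError("pos length does not match number of sites")
        if self.pos.size > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def is_complete(self) -> bool:
        return not bool((self.alleles == HAP_MISSING).any())

    def derived_counts(self) -> np.ndarray:
        """Per-site count of the alternate (derived) allele."""
        if not self.is_complete:
            raise ValueError("haplotype matrix contains missing alleles; "
                             "apply the call-rate filter first")
        return self.alleles.sum(axis=0, dtype=np.int64)

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(self.alleles[:, idx], self.pos[idx], self.chrom)


@dataclass
class GenotypeMatrix:
    """Diploid ALT-dosages (``n_samples x n_sites``; :data:`MISSING` = missing)."""

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        n_sites = self.dosages.shape[1]
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("ref", self.ref), ("alt", self.alt)):
            if arr.size != n_sites:
                raise ValueError(f"{name} length does not match site count")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.dosages.shape[0])]
        # strictly increasing positions within each chromosome
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def alt_frequency(self) -> np.ndarray:
        """Per-site ALT allele frequency over called genotypes (NaN if none)."""
        called = self.called_mask()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx], self.chrom[idx],
                              self.pos[idx], self.ref[idx], self.alt[idx],
                              list(self.sample_ids))

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(self.dosages[idx, :], self.chrom, self.pos,
                              self.ref, self.alt,
                              [self.sample_ids[i] for i in idx])


@dataclass
class SiteAnnotations:
    """Per-site VCF QUAL/INFO annotations plus per-sample depth.

    Absent values are NaN.  Arrays are site-aligned with the matrices
    returned by the same :func:`~sweepscan.vcf_qc.read_vcf` call.
    """

    qual: np.ndarray
    fs: np.ndarray
    qd: np.ndarray
    mq: np.ndarray
    mq_rank: np.ndarray
    readpos_rank: np.ndarray
    dp: Optional[np.ndarray] = None  # (n_samples, n_sites) or None

    def __post_init__(self) -> None:
        for name in ("qual", "fs", "qd", "mq", "mq_rank", "readpos_rank"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.qual.size
        for name in ("fs", "qd", "mq", "mq_rank", "readpos_rank"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match qual")
        if self.dp is not None:
            self.dp = np.asarray(self.dp, dtype=float)
            if self.dp.ndim != 2 or self.dp.shape[1] != n:
                raise ValueError("dp must be (n_samples, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.qual.size

    def take_sites(self, idx: np.ndarray) -> "SiteAnnotations":
        idx = np.asarray(idx)
        return SiteAnnotations(
            self.qual[idx], self.fs[idx], self.qd[idx], self.mq[idx],
            self.mq_rank[idx], self.readpos_rank[idx],
            None if self.dp is None else self.dp[:, idx])


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal union of overlapping significant scan windows."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    peak_neglogp: float
    n_windows: int

    @property
    def size(self) -> int:
        return self.end - self.start
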