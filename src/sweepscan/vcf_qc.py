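"""VCF ingestion and two-track SNP quality control.

Site filters, in order, with exclusive attribution of exclusion counts:

1. hard annotation filters (FS > 60, QD < 2, MQ < 40, QUAL < 30,
   MQRankSum < -12.5, ReadPosRankSum < -8) and a depth filter
   (mean per-site depth in [2, mean + 3 SD]);
2. call rate < 100%;
3. minor allele frequency <= 0.05;
4. Hardy-Weinberg exact p < 1e-6;
5. LD pruning (diversity track only; greedy windowed r^2 > 0.5 removal).

Absent rank-sum annotations pass their rules (they are legitimately missing
for many sites); absent QUAL/FS/QD/MQ fail theirs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (GenotypeMatrix, HaplotypeMatrix, SiteAnnotations,
                   HAP_MISSING, MISSING)

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport", "read_vcf", "hard_filter_sites", "depth_filter",
    "hwe_exact_test", "site_qc", "pairwise_r2", "ld_prune",
    "ibs_sample_filter",
]


@dataclass
class QCReport:
    """Exclusion counts per criterion, in application order."""

    track: str
    n_input: int
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())

    @property
    def n_remaining(self) -> int:
        return self.n_input - self.n_excluded

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("criterion\tn_excluded\n")
            fh.write(f"input\t{self.n_input}\n")
            for k, v in self.excluded.items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"remaining\t{self.n_remaining}\n")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, require_phased: bool = False
             ) -> tuple[GenotypeMatrix, SiteAnnotations, Optional[HaplotypeMatrix]]:
    """Read biallelic SNP records from a VCF.

    Non-SNP and multi-allelic records are dropped (logged with a count).
    Under ``require_phased`` any called-but-unphased genotype raises, and a
    :class:`HaplotypeMatrix` is returned (missing genotypes are coded
    :data:`~sweepscan.core.HAP_MISSING` and must be removed by the call-rate
    rule before haplotype statistics are computed).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)

    dosages, chroms, poss, refs, alts = [], [], [], [], []
    quals, fss, qds, mqs, mqrs, rprs = [], [], [], [], [], []
    dps = []
    haps = [] if require_phased else None
    n_dropped = 0
    for var in vcf:
        if len(var.REF) != 1 or len(var.ALT) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        dose = np.empty(n, dtype=np.int8)
        hrow = np.empty(2 * n, dtype=np.uint8) if require_phased else None
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dose[i] = MISSING
                if require_phased:
                    hrow[2 * i] = HAP_MISSING
                    hrow[2 * i + 1] = HAP_MISSING
                continue
            if require_phased and not g[2]:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS} but phased input required")
            dose[i] = a + b
            if require_phased:
                hrow[2 * i] = a
                hrow[2 * i + 1] = b
        dosages.append(dose)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        quals.append(np.nan if var.QUAL is None else float(var.QUAL))
        fss.append(_info_float(var, "FS"))
        qds.append(_info_float(var, "QD"))
        mqs.append(_info_float(var, "MQ"))
        mqrs.append(_info_float(var, "MQRankSum"))
        rprs.append(_info_float(var, "ReadPosRankSum"))
        d = var.format("DP")
        if d is None:
            dps.append(np.full(n, np.nan))
        else:
            d = d.reshape(n).astype(float)
            d[d < 0] = np.nan  # cyvcf2 missing sentinel
            dps.append(d)
        if require_phased:
            haps.append(hrow)
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    S = len(poss)
    g = GenotypeMatrix(
        np.array(dosages, dtype=np.int8).reshape(S, n).T,
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object), samples)
    ann = SiteAnnotations(
        np.array(quals), np.array(fss), np.array(qds), np.array(mqs),
        np.array(mqrs), np.array(rprs),
        np.array(dps).reshape(S, n).T if S else np.empty((n, 0)))
    hap = None
    if require_phased:
        uchrom = set(map(str, chroms))
        if len(uchrom) > 1:
            raise ValueError("read_vcf returns one HaplotypeMatrix per "
                             "chromosome; split multi-chromosome VCFs first")
        hap = HaplotypeMatrix(
            np.array(haps, dtype=np.uint8).reshape(S, 2 * n).T,
            g.pos, chroms[0] if S else "1")
    return g, ann, hap


def _info_float(var, key: str) -> float:
    v = var.INFO.get(key)
    return np.nan if v is None else float(v)


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------

def hard_filter_sites(ann: SiteAnnotations) -> tuple[np.ndarray, dict[str, int]]:
    """Keep mask + per-rule exclusion counts for the GATK-style hard filters.

    A removed site may count toward several rules.  Absent MQRankSum /
    ReadPosRankSum pass; absent QUAL/FS/QD/MQ fail their rules.
    """
    with np.errstate(invalid="ignore"):
        fails = {
            "FS": ~(ann.fs <= 60.0),            # NaN -> fail
            "QD": ~(ann.qd >= 2.0),
            "MQ": ~(ann.mq >= 40.0),
            "QUAL": ~(ann.qual >= 30.0),
            "MQRankSum": ann.mq_rank < -12.5,   # NaN -> pass
            "ReadPosRankSum": ann.readpos_rank < -8.0,
        }
    any_fail = np.zeros(ann.n_sites, dtype=bool)
    counts = {}
    for rule, f in fails.items():
        counts[rule] = int(f.sum())
        any_fail |= f
    return ~any_fail, counts


def depth_filter(ann: SiteAnnotations) -> np.ndarray:
    """Keep sites whose mean per-sample depth lies in [2, mean + 3 SD].

    Mean and SD are taken over the per-site mean depths of all sites.  If DP
    is absent everywhere the filter is skipped with a warning.
    """
    if ann.dp is None or ann.dp.size == 0 or np.isnan(ann.dp).all():
        logger.warning("depth_filter: DP absent everywhere; filter skipped")
        return np.ones(ann.n_sites, dtype=bool)
    with np.errstate(invalid="ignore"):
        site_mean = np.nanmean(ann.dp, axis=0)
    ok = ~np.isnan(site_mean)
    mu = site_mean[ok].mean()
    sd = site_mean[ok].std(ddof=0)
    keep = ok & (site_mean >= 2.0) & (site_mean <= mu + 3.0 * sd)
    return keep


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Conditions on the minor-allele count; enumerates heterozygote counts of
    matching parity; sums the probabilities of all configurations no more
    likely than the observed one.  Monomorphic sites give p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    x = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)  # minor allele count
    if x == 0:
        return 1.0
    hets = np.arange(x % 2, x + 1, 2)
    # P(h) propto n! / (hom_min! h! hom_maj!) * 2^h, conditioned on (n, x)
    hom_min = (x - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (hets * math.log(2.0)
            - _lgamma_arr(hom_min + 1) - _lgamma_arr(hets + 1)
            - _lgamma_arr(hom_maj + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.searchsorted(hets, min(n_het, x))]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))


def _lgamma_arr(a: np.ndarray) -> np.ndarray:
    return np.array([math.lgamma(float(v)) for v in a])


# ---------------------------------------------------------------------------
# Genotype-level site QC
# ---------------------------------------------------------------------------

def site_qc(g: GenotypeMatrix, track: str = "selection",
            maf_max_excluded: float = 0.05, hwe_p_min: float = 1e-6
            ) -> tuple[np.ndarray, QCReport]:
    """Call-rate, MAF and HWE filters applied in order with exclusive counts.

    Removes sites with any missing genotype, then MAF <= 0.05, then HWE exact
    p < 1e-6.  The criteria are identical for both tracks; LD pruning (the
    diversity-track extra) is a separate step (:func:`ld_prune`).
    """
    if track not in ("diversity", "selection"):
        raise ValueError("track must be 'diversity' or 'selection'")
    report = QCReport(track=track, n_input=g.n_sites)
    keep = np.ones(g.n_sites, dtype=bool)

    miss = (g.dosages == MISSING).any(axis=0)
    report.excluded["call_rate"] = int(miss.sum())
    keep &= ~miss

    maf = g.minor_allele_frequency()
    with np.errstate(invalid="ignore"):
        maf_fail = keep & (maf <= maf_max_excluded)
    report.excluded["maf"] = int(maf_fail.sum())
    keep &= ~maf_fail

    hwe_fail = np.zeros(g.n_sites, dtype=bool)
    for s in np.flatnonzero(keep):
        d = g.dosages[:, s]
        p = hwe_exact_test(int((d == 0).sum()), int((d == 1).sum()),
                           int((d == 2).sum()))
        if p < hwe_p_min:
            hwe_fail[s] = True
    report.excluded["hwe"] = int(hwe_fail.sum())
    keep &= ~hwe_fail
    return keep, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def pairwise_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over joint calls.

    Computed from exact integer sums so that allele-label flips
    (``d -> 2 - d``) give bit-identical results.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    n = int(ok.sum())
    if n < 2:
        logger.warning("pairwise_r2: <2 joint observations; returning 0")
        return 0.0
    x = g_i[ok].astype(np.int64)
    y = g_j[ok].astype(np.int64)
    sx, sy = int(x.sum()), int(y.sum())
    vx = n * int((x * x).sum()) - sx * sx
    vy = n * int((y * y).sum()) - sy * sy
    if vx == 0 or vy == 0:
        return 0.0
    cxy = n * int((x * y).sum()) - sx * sy
    return float(cxy * cxy) / (float(vx) * float(vy))


def _window_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """r^2 between all columns of a dosage submatrix (no missing fast path)."""
    if (dos == MISSING).any():
        m = dos.shape[1]
        out = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = pairwise_r2(dos[:, i], dos[:, j])
        return out
    x = dos.astype(np.int64)
    n = x.shape[0]
    s1 = x.sum(axis=0)
    cross = n * (x.T @ x) - np.outer(s1, s1)
    var = np.diag(cross).astype(np.int64)
    num = cross.astype(float) ** 2
    den = np.outer(var, var).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(g: GenotypeMatrix, window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.5) -> np.ndarray:
    """Greedy windowed LD pruning; returns sorted indices of kept sites.

    Within each ``window_snps``-wide window (fixed grid over the original
    site indices, per chromosome, slid by ``step_snps``), offending pairs
    (r^2 > ``r2_max``) lose their lower-MAF member (tie: the later site).
    The final kept set has no violating pair within any window.
    """
    # MAF from integer allele counts: exact under allele-label flips
    called = g.called_mask()
    n_called = called.sum(axis=0).astype(np.int64)
    alt = np.where(called, g.dosages, 0).sum(axis=0).astype(np.int64)
    minor = np.minimum(alt, 2 * n_called - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_called > 0, minor / (2.0 * n_called), 0.0)
    keep = np.ones(g.n_sites, dtype=bool)
    chrom = g.chrom.astype(str)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        S = idx.size
        for w0 in range(0, max(S - 1, 1), step_snps):
            win = idx[w0: w0 + window_snps]
            alive = win[keep[win]]
            if alive.size < 2:
                continue
            r2 = _window_r2_matrix(g.dosages[:, alive])
            local_alive = np.ones(alive.size, dtype=bool)
            for i in range(alive.size):
                if not local_alive[i]:
                    continue
                for j in range(i + 1, alive.size):
                    if not local_alive[i]:
                        break
                    if not local_alive[j]:
                        continue
                    if r2[i, j] > r2_max:
                        vi, vj = alive[i], alive[j]
                        if maf[vi] < maf[vj]:
                            victim = i
                        elif maf[vj] < maf[vi]:
                            victim = j
                        else:
                            victim = j  # tie: remove the later site
                        local_alive[victim] = False
                        keep[alive[victim]] = False
            if w0 + window_snps >= S:
                break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Sample-level IBS filter
# ---------------------------------------------------------------------------

def ibs_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS similarity: mean over joint calls of (2 - |d_i - d_j|)/2."""
    n = g.n_samples
    out = np.eye(n)
    d = g.dosages
    called = g.called_mask()
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[i] & called[j]
            if not ok.any():
                out[i, j] = out[j, i] = 0.0
                continue
            sim = (2.0 - np.abs(d[i, ok].astype(float) - d[j, ok])) / 2.0
            out[i, j] = out[j, i] = sim.mean()
    return out


def ibs_sample_filter(g: GenotypeMatrix, ibs_max: float = 0.95) -> list[int]:
    """Iteratively drop one member of each IBS >= ``ibs_max`` pair.

    The member with the lower call rate goes (tie: the later sample).
    Returns the kept sample indices, in order.
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    alive = list(range(g.n_samples))
    call_rate = g.called_mask().mean(axis=1)
    while True:
        sub = g.take_samples(alive)
        m = ibs_matrix(sub)
        np.fill_diagonal(m, 0.0)
        if m.max() < ibs_max:
            return alive
        i, j = np.unravel_index(int(m.argmax()), m.shape)
        a, b = alive[i], alive[j]
        if call_rate[a] < call_rate[b]:
            victim = a
        elif call_rate[b] < call_rate[a]:
            victim = b
        else:
            victim = max(a, b)
        alive.remove(victim)
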