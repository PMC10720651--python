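"""Per-window and per-SNP selection statistics on phased haplotypes.

Four statistics on a common sliding-window grid (100 kb windows, 25 kb step,
anchored at coordinate 0, half-open):

* Tajima's D per window;
* nucleotide diversity (pi) per site, averaged per window;
* iHS per SNP (log ratio of integrated EHH for reference/ancestral vs
  alternate/derived allele, physical distance);
* nSL per SNP (same machinery, haplotype lengths counted in sites).

The REF allele is treated as ancestral (no outgroup available); iHS/nSL are
standardized within derived-allele-frequency bins, averaged per window, and
each window column is z-standardized genome-wide over included windows
(>= ``min_snps`` SNPs).  Tajima's D enters the window table as computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid", "make_window_grid", "tajimas_d", "per_site_pi",
    "ehh", "EhhCurve", "ihs", "nsl", "standardize_by_freq",
    "window_aggregate", "build_window_table",
]

WINDOW_BP = 100_000
STEP_BP = 25_000
MIN_SNPS = 10
EHH_CUTOFF = 0.05
MAXGAP_BP = 200_000
MAX_EXTEND_BP = 1_000_000
MAX_EXTEND_SITES = 200


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------

@dataclass
class WindowGrid:
    """Sliding windows, 0-based half-open, anchored at 0, fixed step."""

    chrom: str
    starts: np.ndarray  # (n_windows,)
    size: int
    step: int
    n_snps: np.ndarray  # SNPs per window

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.size

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def site_window_slices(self, pos: np.ndarray) -> list[slice]:
        """Per window, the slice of (sorted, 1-based) ``pos`` it contains."""
        z = pos - 1  # 0-based site coordinates
        lo = np.searchsorted(z, self.starts, side="left")
        hi = np.searchsorted(z, self.ends, side="left")
        return [slice(int(a), int(b)) for a, b in zip(lo, hi)]


def make_window_grid(pos: np.ndarray, chrom_length: int, chrom: str = "1",
                     size: int = WINDOW_BP, step: int = STEP_BP) -> WindowGrid:
    if size % step != 0:
        raise ValueError("step must divide window size")
    starts = np.arange(0, max(int(chrom_length), 1), step, dtype=np.int64)
    grid = WindowGrid(chrom, starts, size, step, np.zeros(starts.size, int))
    grid.n_snps = np.array([s.stop - s.start
                            for s in grid.site_window_slices(pos)])
    return grid


# ---------------------------------------------------------------------------
# Frequency-spectrum statistics
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def per_site_pi(hap: HaplotypeMatrix) -> np.ndarray:
    """Per-site mean pairwise difference: 2 d (n - d) / (n (n - 1))."""
    n = hap.n_hap
    d = hap.derived_counts().astype(float)
    return 2.0 * d * (n - d) / (n * (n - 1.0))


def tajimas_d(hap: HaplotypeMatrix, grid: WindowGrid) -> np.ndarray:
    """Tajima's D per window (NaN where no segregating site)."""
    n = hap.n_hap
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    c = _tajima_constants(n)
    d = hap.derived_counts()
    seg = (d > 0) & (d < n)
    pi = per_site_pi(hap)
    out = np.full(grid.n_windows, np.nan)
    for w, sl in enumerate(grid.site_window_slices(hap.pos)):
        S = int(seg[sl].sum())
        if S == 0:
            continue
        pihat = float(pi[sl].sum())
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        out[w] = (pihat - S / c["a1"]) / np.sqrt(var)
    return out


# ---------------------------------------------------------------------------
# EHH machinery
# ---------------------------------------------------------------------------

def _hh_curve(sub: np.ndarray) -> np.ndarray:
    """Haplotype-homozygosity decay over the columns of ``sub`` (m x T).

    Returns EHH after including columns ``0..t`` for ``t = 0..T-1``
    (pairs of rows identical over those columns / all pairs).
    """
    m, T = sub.shape
    npairs = m * (m - 1) // 2
    if T == 0:
        return np.empty(0)
    order = np.lexsort(sub.T[::-1])
    ss = sub[order]
    neq = ss[:-1] != ss[1:]
    any_neq = neq.any(axis=1)
    # first column where adjacent sorted rows differ (T if identical)
    d = np.where(any_neq, neq.argmax(axis=1), T)
    # interval minima of d over all row pairs, computed as row-wise running
    # minima of an upper-triangular matrix (entry [a, j] = d[j] for j >= a)
    k = d.size
    D2 = np.where(np.arange(k) >= np.arange(k)[:, None], d, T + 1)
    M = np.minimum.accumulate(D2, axis=1)
    pairmins = M[np.triu_indices(k)]
    counts = np.bincount(pairmins, minlength=T + 2)[: T + 1]
    tails = counts[::-1].cumsum()[::-1]  # tails[v] = #pairs with min >= v
    # identical through column t  <=>  pair min > t  <=>  min >= t+1
    return tails[1:] / npairs


def _side_sites(n_sites: int, core: int, direction: int) -> np.ndarray:
    if direction > 0:
        return np.arange(core + 1, n_sites)
    return np.arange(core - 1, -1, -1)


@dataclass
class _SideResult:
    ihh: float
    status: str  # "ok", "edge", "gap", "no_flank"
    sites: np.ndarray
    ehh: np.ndarray


def _integrate_side(alleles: np.ndarray, pos: np.ndarray, core: int,
                    carriers: np.ndarray, direction: int, *,
                    site_scale: bool, cutoff: float,
                    maxgap_bp: Optional[int], max_extend: int) -> _SideResult:
    """Integrate the EHH curve outward from ``core`` in one direction.

    ``site_scale`` switches distances from bp to site counts (nSL mode,
    where ``max_extend`` is in sites and the gap rule is off).
    """
    side = _side_sites(pos.size, core, direction)
    if site_scale:
        side = side[:max_extend]
    else:
        side = side[np.abs(pos[side] - pos[core]) <= max_extend]
    if side.size == 0:
        return _SideResult(0.0, "no_flank", side, np.empty(0))

    T_all = side.size
    T = min(32, T_all)
    while True:
        curve = _hh_curve(alleles[np.ix_(carriers, side[:T])])
        below = np.flatnonzero(curve < cutoff)
        if below.size or T == T_all:
            break
        T = min(4 * T, T_all)

    if below.size:
        stop = int(below[0])  # include the first below-cutoff point
        truncated_by_cutoff = True
    else:
        stop = T - 1
        truncated_by_cutoff = False

    used = side[: stop + 1]
    if site_scale:
        x = np.arange(1, stop + 2, dtype=float)
    else:
        x = np.abs(pos[used] - pos[core]).astype(float)
        if maxgap_bp is not None:
            gaps = np.diff(np.concatenate(([0.0], x)))
            if (gaps > maxgap_bp).any():
                return _SideResult(0.0, "gap", used, curve[: stop + 1])
    if not truncated_by_cutoff:
        # ran out of sites: chromosome edge unless the extension cap stopped us
        hit_cap = T_all < _side_sites(pos.size, core, direction).size
        if not hit_cap:
            return _SideResult(0.0, "edge", used, curve[: stop + 1])

    y = np.concatenate(([1.0], curve[: stop + 1]))
    xx = np.concatenate(([0.0], x))
    ihh = float(np.trapezoid(y, xx))
    return _SideResult(ihh, "ok", used, curve[: stop + 1])


_STATUS = {0: "ok", 1: "edge", 2: "gap", 3: "no_flank"}


def _ihh_side_py(alleles, pos, core, carriers, direction, *, site_scale,
                 cutoff, maxgap_bp, max_extend):
    r = _integrate_side(alleles, pos, core, carriers, direction,
                        site_scale=site_scale, cutoff=cutoff,
                        maxgap_bp=maxgap_bp, max_extend=max_extend)
    return r.ihh, r.status


try:  # compiled fast path; the numpy implementation is the reference
    from numba import njit

    @njit(cache=True)
    def _ihh_side_nb(alleles, pos, core, carriers, direction, site_scale,
                     cutoff, maxgap, max_extend):  # pragma: no cover
        m = carriers.size
        npairs = m * (m - 1) / 2.0
        gid = np.zeros(m, dtype=np.int64)
        n_groups = 1
        prev_x = 0.0
        prev_y = 1.0
        ihh = 0.0
        s = core + direction
        step = 0
        while 0 <= s < pos.size:
            step += 1
            x = float(step) if site_scale else abs(float(pos[s] - pos[core]))
            if x > max_extend:
                return ihh, 0  # extension cap: truncate
            if (not site_scale) and maxgap > 0 and x - prev_x > maxgap:
                return 0.0, 2  # gap before cutoff: skip site
            # split groups by the allele at s
            new_gid = np.empty(m, dtype=np.int64)
            counts = np.zeros(2 * n_groups, dtype=np.int64)
            for i in range(m):
                key = 2 * gid[i] + alleles[carriers[i], s]
                new_gid[i] = key
                counts[key] += 1
            # compact ids and count identical pairs
            remap = np.full(2 * n_groups, -1, dtype=np.int64)
            ng = 0
            pairs = 0.0
            for key in range(2 * n_groups):
                c = counts[key]
                if c > 0:
                    remap[key] = ng
                    ng += 1
                    pairs += c * (c - 1) / 2.0
            for i in range(m):
                new_gid[i] = remap[new_gid[i]]
            gid = new_gid
            n_groups = ng
            y = pairs / npairs
            ihh += (prev_y + y) / 2.0 * (x - prev_x)
            if y < cutoff:
                return ihh, 0
            prev_x = x
            prev_y = y
            s += direction
        if step == 0:
            return 0.0, 3  # no flanking site at all
        return 0.0, 1  # chromosome edge before cutoff: skip site

    def _ihh_side(alleles, pos, core, carriers, direction, *, site_scale,
                  cutoff, maxgap_bp, max_extend):
        ihh, code = _ihh_side_nb(alleles, pos, int(core), carriers,
                                 int(direction), bool(site_scale),
                                 float(cutoff),
                                 float(-1 if maxgap_bp is None else maxgap_bp),
                                 float(max_extend))
        return ihh, _STATUS[code]

except ImportError:  # pragma: no cover
    _ihh_side = _ihh_side_py


@dataclass
class EhhCurve:
    """EHH evaluated outward from a core site (both directions)."""

    core_site: int
    core_allele: int
    sites: np.ndarray   # site indices, ascending, core included
    values: np.ndarray  # EHH aligned with ``sites`` (1.0 at the core)


def ehh(hap: HaplotypeMatrix, core_site: int, core_allele: int,
        maxgap_bp: int = MAXGAP_BP, max_extend_bp: int = MAX_EXTEND_BP
        ) -> EhhCurve:
    """EHH among carriers of ``core_allele`` at each site outward from the core.

    The curve is evaluated until it falls below :data:`EHH_CUTOFF`, the
    extension cap, a gap larger than ``maxgap_bp``, or the chromosome edge —
    whichever comes first (no skipping here; this is the raw curve).
    """
    carriers = np.flatnonzero(hap.alleles[:, core_site] == core_allele)
    if carriers.size < 2:
        raise ValueError("EHH undefined: fewer than 2 carriers of the core allele")
    pieces = {}
    for direction in (-1, +1):
        side = _side_sites(hap.n_sites, core_site, direction)
        side = side[np.abs(hap.pos[side] - hap.pos[core_site]) <= max_extend_bp]
        if maxgap_bp is not None and side.size:
            gaps = np.abs(np.diff(np.concatenate(([hap.pos[core_site]],
                                                  hap.pos[side])).astype(float)))
            bad = np.flatnonzero(gaps > maxgap_bp)
            if bad.size:
                side = side[: bad[0]]
        curve = _hh_curve(hap.alleles[np.ix_(carriers, side)]) if side.size \
            else np.empty(0)
        below = np.flatnonzero(curve < EHH_CUTOFF)
        if below.size:
            side, curve = side[: below[0] + 1], curve[: below[0] + 1]
        pieces[direction] = (side, curve)
    left_sites, left_vals = pieces[-1]
    right_sites, right_vals = pieces[+1]
    sites = np.concatenate((left_sites[::-1], [core_site], right_sites))
    values = np.concatenate((left_vals[::-1], [1.0], right_vals))
    return EhhCurve(core_site, core_allele, sites, values)


# ---------------------------------------------------------------------------
# iHS / nSL
# ---------------------------------------------------------------------------

def _hap_score(hap: HaplotypeMatrix, *, site_scale: bool,
               cutoff: float, maxgap_bp: Optional[int], max_extend: int,
               maf_min: float = 0.05) -> pd.DataFrame:
    n = hap.n_hap
    d = hap.derived_counts()
    freq = d / float(n)
    rows = []
    for s in range(hap.n_sites):
        rec = {"site": s, "pos": int(hap.pos[s]), "freq": float(freq[s]),
               "ihh_a": np.nan, "ihh_d": np.nan, "score": np.nan,
               "reason": ""}
        maf = min(freq[s], 1.0 - freq[s])
        if maf < maf_min:
            rec["reason"] = "maf"
            rows.append(rec)
            continue
        anc = np.flatnonzero(hap.alleles[:, s] == 0)
        der = np.flatnonzero(hap.alleles[:, s] == 1)
        if anc.size < 2 or der.size < 2:
            rec["reason"] = "carriers"
            rows.append(rec)
            continue
        sides = {}
        failed = None
        for name, carriers in (("a", anc), ("d", der)):
            tot = 0.0
            for direction in (-1, +1):
                ihh_val, status = _ihh_side(
                    hap.alleles, hap.pos, s, carriers, direction,
                    site_scale=site_scale, cutoff=cutoff,
                    maxgap_bp=maxgap_bp, max_extend=max_extend)
                if status != "ok":
                    failed = status
                    break
                tot += ihh_val
            if failed:
                break
            sides[name] = tot
        if failed:
            rec["reason"] = failed
            rows.append(rec)
            continue
        if sides["a"] <= 0.0 or sides["d"] <= 0.0:
            rec["reason"] = "zero_integral"
            rows.append(rec)
            continue
        rec["ihh_a"] = sides["a"]
        rec["ihh_d"] = sides["d"]
        rec["score"] = float(np.log(sides["a"] / sides["d"]))
        rows.append(rec)
    return pd.DataFrame(rows)


def ihs(hap: HaplotypeMatrix, maxgap_bp: int = MAXGAP_BP,
        max_extend_bp: int = MAX_EXTEND_BP, cutoff: float = EHH_CUTOFF,
        maf_min: float = 0.05) -> pd.DataFrame:
    """Unstandardized iHS per SNP: ln(iHH_ancestral / iHH_derived).

    Integrals are trapezoidal over physical distance, truncated where EHH
    drops below ``cutoff``; sites are skipped (NaN score + reason code) when
    a chromosome edge or a gap > ``maxgap_bp`` intervenes first.
    """
    return _hap_score(hap, site_scale=False, cutoff=cutoff,
                      maxgap_bp=maxgap_bp, max_extend=max_extend_bp,
                      maf_min=maf_min)


def nsl(hap: HaplotypeMatrix, max_extend_sites: int = MAX_EXTEND_SITES,
        cutoff: float = EHH_CUTOFF, maf_min: float = 0.05) -> pd.DataFrame:
    """Unstandardized nSL per SNP: haplotype lengths in site counts, no gap rule."""
    return _hap_score(hap, site_scale=True, cutoff=cutoff, maxgap_bp=None,
                      max_extend=max_extend_sites, maf_min=maf_min)


def standardize_by_freq(scores: np.ndarray, freqs: np.ndarray,
                        n_bins: int = 50) -> np.ndarray:
    """Z-standardize scores within equal-width derived-frequency bins.

    Bins with fewer than 2 scored sites are merged with their neighbor
    (greedy, left to right).  NaN scores stay NaN; a zero-SD bin gives z = 0.
    """
    scores = np.asarray(scores, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out = np.full_like(scores, np.nan)
    ok = ~np.isnan(scores)
    if not ok.any():
        return out
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    raw_bin = np.clip(np.digitize(freqs, edges[1:-1]), 0, n_bins - 1)

    # greedily merge consecutive raw bins until each group has >= 2 sites
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_count = 0
    for b in range(n_bins):
        cnt = int((ok & (raw_bin == b)).sum())
        cur.append(b)
        cur_count += cnt
        if cur_count >= 2:
            groups.append(cur)
            cur, cur_count = [], 0
    if cur:
        if groups and cur_count < 2:
            groups[-1].extend(cur)
        elif cur_count > 0:
            groups.append(cur)
    gid = np.empty(n_bins, dtype=int)
    for gi, bs in enumerate(groups):
        for b in bs:
            gid[b] = gi
    site_gid = gid[raw_bin]
    for gi in range(len(groups)):
        m = ok & (site_gid == gi)
        if not m.any():
            continue
        mu = scores[m].mean()
        sd = scores[m].std(ddof=0)
        out[m] = 0.0 if sd == 0.0 else (scores[m] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# Window aggregation
# ---------------------------------------------------------------------------

def window_aggregate(values: np.ndarray, pos: np.ndarray,
                     grid: WindowGrid) -> np.ndarray:
    """Mean of per-site values per window (NaN-aware; empty window -> NaN)."""
    values = np.asarray(values, dtype=float)
    out = np.full(grid.n_windows, np.nan)
    for w, sl in enumerate(grid.site_window_slices(pos)):
        v = values[sl]
        v = v[~np.isnan(v)]
        if v.size:
            out[w] = v.mean()
    return out


def _zcol(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full_like(x, np.nan, dtype=float)
    v = x[mask]
    sd = v.std(ddof=0)
    if v.size and sd > 0:
        out[mask] = (v - v.mean()) / sd
    elif v.size:
        out[mask] = 0.0
    return out


def build_window_table(hap: HaplotypeMatrix, chrom_length: int,
                       window_bp: int = WINDOW_BP, step_bp: int = STEP_BP,
                       min_snps: int = MIN_SNPS,
                       ihs_df: Optional[pd.DataFrame] = None,
                       nsl_df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Compute the four statistics on the common grid for one chromosome.

    Returns a per-window frame with raw values, the windows' SNP counts and
    an ``included`` flag (>= ``min_snps`` SNPs and all four statistics
    defined).  Standardization across windows happens genome-wide in
    :func:`standardize_windows` once all chromosomes are assembled.
    """
    grid = make_window_grid(hap.pos, chrom_length, hap.chrom,
                            window_bp, step_bp)
    if ihs_df is None:
        ihs_df = ihs(hap)
    if nsl_df is None:
        nsl_df = nsl(hap)
    ihs_z = standardize_by_freq(ihs_df["score"].to_numpy(),
                                ihs_df["freq"].to_numpy())
    nsl_z = standardize_by_freq(nsl_df["score"].to_numpy(),
                                nsl_df["freq"].to_numpy())
    df = pd.DataFrame({
        "chrom": hap.chrom,
        "start": grid.starts,
        "end": grid.ends,
        "n_snps": grid.n_snps,
        "tajima_d": tajimas_d(hap, grid),
        "pi": window_aggregate(per_site_pi(hap), hap.pos, grid),
        "ihs": window_aggregate(ihs_z, hap.pos, grid),
        "nsl": window_aggregate(nsl_z, hap.pos, grid),
    })
    stat_ok = df[["tajima_d", "pi", "ihs", "nsl"]].notna().all(axis=1)
    df["included"] = (df["n_snps"] >= min_snps) & stat_ok
    return df


def standardize_windows(table: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide z-standardization of the pi/iHS/nSL window columns.

    Tajima's D is carried through as computed (the downstream rank transform
    is invariant to monotone rescaling anyway).
    """
    df = table.copy()
    mask = df["included"].to_numpy()
    for col in ("pi", "ihs", "nsl"):
        df[f"{col}_z"] = _zcol(df[col].to_numpy(dtype=float), mask)
    return df
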