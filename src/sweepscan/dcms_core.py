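"""De-correlated composite of multiple signals (DCMS).

Window statistics are converted to fractional-rank p-values (left-tailed for
Tajima's D and pi, two-tailed i.e. magnitude-ranked for iHS and nSL), their
redundancy is measured by a robust (minimum covariance determinant)
correlation matrix across windows, and the composite is the weighted sum of
logit-transformed p-values

    DCMS_j = sum_i ln((1 - p_ij) / p_ij) / sum_k |r_ik|

so that duplicated (perfectly correlated) statistics collapse to a single
contribution.  A normal distribution fitted to the genome-wide DCMS scores
gives upper-tail p-values; windows with -log10 p >= 4 are candidates, and
overlapping candidate windows merge into candidate regions.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .core import CandidateRegion

logger = logging.getLogger(__name__)

__all__ = [
    "stat_to_pvalue", "mcd_correlation", "mcd_covariance", "dcms",
    "dcms_pvalues", "call_and_merge",
]

DEFAULT_TAILS = {"tajima_d": "left", "pi": "left", "ihs": "two", "nsl": "two"}


def stat_to_pvalue(values: np.ndarray, tail: Literal["left", "two"]
                   ) -> np.ndarray:
    """Fractional-rank p-values, ties sharing mean rank; p in (0, 1).

    ``left``: rank ascending, p = rank/(n+1) (most negative -> smallest p).
    ``two``: rank |v| descending, p = rank/(n+1) (largest magnitude ->
    smallest p).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    n = v.size
    if np.all(v == v[0]):
        return np.full(n, 0.5)
    if tail == "left":
        r = rankdata(v, method="average")
    elif tail == "two":
        r = n + 1 - rankdata(np.abs(v), method="average")
    else:
        raise ValueError("tail must be 'left' or 'two'")
    return r / (n + 1.0)


# ---------------------------------------------------------------------------
# FAST-MCD robust covariance / correlation
# ---------------------------------------------------------------------------

def _cov_det(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / x.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    det = math.exp(logdet) if sign > 0 else 0.0
    return mean, cov, det


def _mahalanobis_sq(x: np.ndarray, mean: np.ndarray, cov: np.ndarray
                    ) -> np.ndarray:
    xc = x - mean
    try:
        sol = np.linalg.solve(cov, xc.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(cov) @ xc.T
    return np.einsum("ij,ji->i", xc, sol)


def _c_step(x: np.ndarray, mean: np.ndarray, cov: np.ndarray, h: int
            ) -> np.ndarray:
    d2 = _mahalanobis_sq(x, mean, cov)
    return np.argsort(d2, kind="stable")[:h]


def mcd_covariance(x: np.ndarray, alpha: float = 0.75, nsamp: int = 50_000,
                   seed: int | None = 0) -> tuple[np.ndarray, np.ndarray]:
    """FAST-MCD covariance: the h-subset (h = ceil(alpha n)) of minimal
    covariance determinant, found from ``nsamp`` random (d+1)-point starts
    refined by concentration steps; the standard consistency factor is
    applied.  Returns ``(location, covariance)``.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if n < d * (d + 1):
        raise ValueError(f"need >= {d * (d + 1)} rows for d={d}")
    if (x.std(axis=0) == 0).any():
        raise ValueError("constant column: covariance is singular")
    if not 0.5 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0.5, 1]")
    h = int(math.ceil(alpha * n))
    rng = np.random.default_rng(seed)

    n_comb = math.comb(n, d + 1)
    if n_comb <= nsamp:
        starts: Sequence = list(itertools.combinations(range(n), d + 1))
    else:
        starts = [rng.choice(n, size=d + 1, replace=False)
                  for _ in range(nsamp)]

    candidates = []  # (det, subset-indices) after two concentration steps
    for st in starts:
        sub = np.fromiter(st, dtype=int) if not isinstance(st, np.ndarray) \
            else st
        mean, cov, det = _cov_det(x[sub])
        # extend singular starts with extra random points
        tries = 0
        while det <= 0.0 and sub.size < h and tries < n:
            extra = rng.choice(n)
            if extra not in sub:
                sub = np.append(sub, extra)
                mean, cov, det = _cov_det(x[sub])
            tries += 1
        for _ in range(2):
            sub = _c_step(x, mean, cov, h)
            mean, cov, det = _cov_det(x[sub])
            if det == 0.0:
                break
        candidates.append((det, sub))
    candidates.sort(key=lambda t: t[0])

    best_det, best_mean, best_cov = np.inf, None, None
    for det, sub in candidates[:10]:
        mean, cov, det = _cov_det(x[sub])
        while True:
            new_sub = _c_step(x, mean, cov, h)
            new_mean, new_cov, new_det = _cov_det(x[new_sub])
            if new_det >= det or np.array_equal(np.sort(new_sub),
                                                np.sort(sub)):
                break
            sub, mean, cov, det = new_sub, new_mean, new_cov, new_det
            if det == 0.0:
                break
        if det < best_det:
            best_det, best_mean, best_cov = det, mean, cov

    # consistency factor for the truncated normal
    q = h / n
    factor = q / stats.chi2.cdf(stats.chi2.ppf(q, d), d + 2)
    return best_mean, best_cov * factor


def mcd_correlation(x: np.ndarray, alpha: float = 0.75, nsamp: int = 50_000,
                    seed: int | None = 0) -> np.ndarray:
    """Robust correlation matrix from the FAST-MCD covariance."""
    _, cov = mcd_covariance(x, alpha=alpha, nsamp=nsamp, seed=seed)
    sd = np.sqrt(np.diag(cov))
    if (sd == 0).any():
        raise ValueError("zero robust variance: correlation undefined")
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Composite score and p-values
# ---------------------------------------------------------------------------

def dcms(pmat: np.ndarray, corr: np.ndarray,
         log_base: float = math.e) -> np.ndarray:
    """Weighted logit sum: sum_i log((1-p_ij)/p_ij) / sum_k |r_ik|."""
    pmat = np.asarray(pmat, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if pmat.ndim != 2 or corr.shape != (pmat.shape[1], pmat.shape[1]):
        raise ValueError("pmat columns must align with corr rows")
    if ((pmat <= 0) | (pmat >= 1)).any():
        raise ValueError("p-values must lie strictly in (0, 1)")
    weights = np.abs(corr).sum(axis=1)
    logits = np.log((1.0 - pmat) / pmat) / math.log(log_base)
    return (logits / weights).sum(axis=1)


def dcms_pvalues(scores: np.ndarray,
                 fit: Literal["mean_sd", "median_mad"] = "mean_sd"
                 ) -> tuple[np.ndarray, dict[str, float]]:
    """Upper-tail normal p-values from a genome-wide fit to the scores.

    ``mean_sd`` fits by mean and SD; ``median_mad`` by median and
    1.4826 * MAD (robust to the right skew selection induces).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 30:
        raise ValueError("need >= 30 scores to fit the null")
    if fit == "mean_sd":
        mu, sigma = float(s.mean()), float(s.std(ddof=0))
    elif fit == "median_mad":
        mu = float(np.median(s))
        sigma = float(1.4826 * np.median(np.abs(s - mu)))
    else:
        raise ValueError("fit must be 'mean_sd' or 'median_mad'")
    if sigma == 0.0:
        raise ValueError("zero scale: cannot fit null distribution")
    p = stats.norm.sf(s, loc=mu, scale=sigma)
    return p, {"mu": mu, "sigma": sigma}


def call_and_merge(windows: pd.DataFrame, threshold_logp: float = 4.0
                   ) -> list[CandidateRegion]:
    """Flag windows with -log10 p >= threshold and merge overlapping ones.

    ``windows`` needs columns chrom/start/end/neg_log10_p.  Merging is by
    strict interval overlap (half-open), per chromosome; each region reports
    its peak -log10 p and member window count.
    """
    req = {"chrom", "start", "end", "neg_log10_p"}
    if not req.issubset(windows.columns):
        raise ValueError(f"windows frame must have columns {sorted(req)}")
    flagged = windows[windows["neg_log10_p"] >= threshold_logp]
    regions: list[CandidateRegion] = []
    for chrom, grp in flagged.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_peak, cur_n = -np.inf, 0
        for _, row in grp.iterrows():
            if cur_start is None or row["start"] >= cur_end:
                if cur_start is not None:
                    regions.append(CandidateRegion(str(chrom), int(cur_start),
                                                   int(cur_end),
                                                   float(cur_peak), cur_n))
                cur_start, cur_end = row["start"], row["end"]
                cur_peak, cur_n = row["neg_log10_p"], 1
            else:
                cur_end = max(cur_end, row["end"])
                cur_peak = max(cur_peak, row["neg_log10_p"])
                cur_n += 1
        if cur_start is not None:
            regions.append(CandidateRegion(str(chrom), int(cur_start),
                                           int(cur_end), float(cur_peak),
                                           cur_n))
    return regions
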