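"""Genetic-diversity summaries: homozygosity, inbreeding F, rank tests, PCA."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, MISSING

__all__ = ["observed_homozygosity", "inbreeding_f", "rank_tests", "pca"]


def _require_complete(g: GenotypeMatrix) -> None:
    if (g.dosages == MISSING).any():
        raise ValueError("matrix contains missing genotypes; run site QC first")


def observed_homozygosity(g: GenotypeMatrix,
                          groups: Optional[Mapping[str, Sequence[int]]] = None
                          ) -> tuple[pd.Series, pd.Series]:
    """Per-individual fraction of homozygous sites, plus group means."""
    _require_complete(g)
    hom = ((g.dosages == 0) | (g.dosages == 2)).mean(axis=1)
    per_ind = pd.Series(hom, index=g.sample_ids, name="homozygosity")
    if groups is None:
        groups = {"all": list(range(g.n_samples))}
    means = {}
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {name!r} is empty")
        means[name] = float(per_ind.iloc[list(members)].mean())
    return per_ind, pd.Series(means, name="homozygosity")


def inbreeding_f(g: GenotypeMatrix) -> pd.Series:
    """Per-individual F = (O_i - E) / (L - E).

    ``O_i``: observed homozygous-site count; ``E = sum_s (1 - 2 p q)``: the
    expected homozygous count from sample allele frequencies; ``L``: number
    of sites.  No small-sample correction.
    """
    _require_complete(g)
    p = g.alt_frequency()
    e_hom = float((1.0 - 2.0 * p * (1.0 - p)).sum())
    L = g.n_sites
    if L == e_hom:
        raise ValueError("all sites monomorphic: F undefined")
    obs = ((g.dosages == 0) | (g.dosages == 2)).sum(axis=1).astype(float)
    f = (obs - e_hom) / (L - e_hom)
    return pd.Series(f, index=g.sample_ids, name="F")


def rank_tests(x: Sequence[float], y: Optional[Sequence[float]] = None,
               mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided nonparametric location test.

    Two-sample: Mann-Whitney U (exact when both n <= 25 and there are no
    ties, normal approximation with continuity/tie correction otherwise).
    One-sample (``y is None``): Wilcoxon signed-rank of ``x - mu0``.
    Returns ``(statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        d = x - mu0
        if np.all(d == 0):
            return 0.0, 1.0
        n = d.size
        exact = n <= 25 and np.unique(np.abs(d[d != 0])).size == \
            np.count_nonzero(d)
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided",
                             method="exact" if exact else "approx")
        return float(res.statistic), float(min(res.pvalue, 1.0))
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = (max(x.size, y.size) <= 25
             and np.unique(pooled).size == pooled.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pca(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the column-centered dosage matrix (no variance scaling).

    Returns ``(scores, variance_fractions)``; scores are samples x
    components.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    _require_complete(g)
    if g.n_sites < 2:
        raise ValueError("need >= 2 sites for PCA")
    X = g.dosages.astype(float)
    X -= X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for k in range(s.size):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    return scores, frac
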