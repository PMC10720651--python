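"""Gene overlap of candidate regions, variant counts, and the full pipeline.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) and VCF positions (1-based) are converted at the boundary, BED
passes through.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dcms_core, diversity, sel_stats, sim_data, vcf_qc
from .core import CandidateRegion, GenotypeMatrix, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneInterval", "read_genes", "overlap_genes", "count_region_variants",
    "run_pipeline", "scan_and_call",
]


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene interval must satisfy start < end")


def read_genes(path: str | Path, fmt: Optional[str] = None) -> list[GeneInterval]:
    """Read gene intervals from GFF3 (1-based inclusive) or BED (half-open)."""
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "gff3":
                if f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
                genes.append(GeneInterval(f[0], int(f[3]) - 1, int(f[4]),
                                          gid, attrs.get("Name", gid)))
            else:
                gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                genes.append(GeneInterval(f[0], int(f[1]), int(f[2]), gid, gid))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def overlap_genes(regions: Sequence[CandidateRegion],
                  genes: Sequence[GeneInterval]
                  ) -> tuple[list[list[str]], int]:
    """Per-region overlapping gene IDs (>= 1 bp, half-open) + distinct count."""
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if regions and genes and not (region_chroms & gene_chroms):
        logger.warning("overlap_genes: no shared chromosome names "
                       "(regions: %s; genes: %s)",
                       sorted(region_chroms), sorted(gene_chroms))
    per_region: list[list[str]] = []
    distinct: set[str] = set()
    for r in regions:
        hits = [g.gene_id for g in genes
                if g.chrom == r.chrom and g.start < r.end and r.start < g.end]
        per_region.append(hits)
        distinct.update(hits)
    return per_region, len(distinct)


def count_region_variants(chrom: np.ndarray, pos: np.ndarray,
                          regions: Sequence[CandidateRegion]) -> list[int]:
    """Number of sites (1-based ``pos``) inside each half-open region."""
    chrom = np.asarray(chrom).astype(str)
    z = np.asarray(pos, dtype=np.int64) - 1
    out = []
    for r in regions:
        m = (chrom == r.chrom) & (z >= r.start) & (z < r.end)
        out.append(int(m.sum()))
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_DEFAULT_WINDOWS = {"size": 100_000, "step": 25_000, "min_snps": 10}
_DEFAULT_DCMS = {"alpha": 0.75, "nsamp": 50_000, "fit": "mean_sd",
                 "threshold_logp": 4.0}


def scan_and_call(haps: Sequence[HaplotypeMatrix],
                  chrom_lengths: Sequence[int],
                  window_bp: int = 100_000, step_bp: int = 25_000,
                  min_snps: int = 10, alpha: float = 0.75,
                  nsamp: int = 50_000, fit: str = "mean_sd",
                  threshold_logp: float = 4.0, seed: int = 0
                  ) -> tuple[pd.DataFrame, list[CandidateRegion], dict]:
    """Selection scan + DCMS on post-QC phased haplotypes.

    Returns the genome-wide window table (with p-values and DCMS columns),
    the merged candidate regions, and a fit-report dict.
    """
    tables, snp_tables = [], []
    for h, L in zip(haps, chrom_lengths, strict=True):
        ihs_df = sel_stats.ihs(h)
        nsl_df = sel_stats.nsl(h)
        tables.append(sel_stats.build_window_table(
            h, L, window_bp, step_bp, min_snps, ihs_df=ihs_df, nsl_df=nsl_df))
        snp = ihs_df.rename(columns={c: f"ihs_{c}" for c in
                                     ("ihh_a", "ihh_d", "score", "reason")})
        snp[["nsl_score", "nsl_reason"]] = nsl_df[["score", "reason"]]
        snp.insert(0, "chrom", h.chrom)
        snp_tables.append(snp)
    table = sel_stats.standardize_windows(
        pd.concat(tables, ignore_index=True))
    inc = table["included"].to_numpy()
    stat_cols = {"tajima_d": "tajima_d", "pi": "pi_z", "ihs": "ihs_z",
                 "nsl": "nsl_z"}
    X = table.loc[inc, [stat_cols[k] for k in stat_cols]].to_numpy(float)
    pmat = np.column_stack([
        dcms_core.stat_to_pvalue(X[:, i], dcms_core.DEFAULT_TAILS[k])
        for i, k in enumerate(stat_cols)])
    corr = dcms_core.mcd_correlation(X, alpha=alpha, nsamp=nsamp, seed=seed)
    scores = dcms_core.dcms(pmat, corr)
    p, fit_rep = dcms_core.dcms_pvalues(scores, fit=fit)

    for i, k in enumerate(stat_cols):
        table.loc[inc, f"p_{k}"] = pmat[:, i]
    table.loc[inc, "dcms"] = scores
    table.loc[inc, "p_dcms"] = p
    table.loc[inc, "neg_log10_p"] = -np.log10(p)
    regions = dcms_core.call_and_merge(
        table[inc & table["neg_log10_p"].notna()], threshold_logp)
    fit_rep = dict(fit_rep)
    fit_rep["correlation"] = corr.tolist()
    fit_rep["per_snp"] = pd.concat(snp_tables, ignore_index=True)
    return table, regions, fit_rep


def _as_sim_config(block: dict, seed: int, chrom: str) -> sim_data.SimConfig:
    sweep = None
    sw = block.get("sweep")
    if sw and str(sw.get("chrom", "1")) == chrom:
        sweep = sim_data.SweepSpec(int(sw["focal_pos"]),
                                   float(sw["carrier_fraction"]),
                                   int(sw["core_halfwidth_bp"]))
    return sim_data.SimConfig(
        n_individuals=int(block["n_individuals"]),
        chrom_length_bp=int(block["chrom_length_bp"]),
        target_snp_count=block.get("target_snp_count"),
        theta=float(block.get("theta", 0.001)),
        ld_block_bp=float(block.get("ld_block_bp", 50_000)),
        missing_rate=float(block.get("missing_rate", 0.0)),
        bad_site_fraction=float(block.get("bad_site_fraction", 0.0)),
        dp_mean=float(block.get("dp_mean", 12.0)),
        sweep=sweep, seed=seed, chrom=chrom)


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: Optional[int] = None) -> dict:
    """Run sim (optional) -> QC -> diversity -> scan -> DCMS -> annotation.

    Writes every intermediate table under ``out_dir`` and returns the summary
    dict (also written as ``summary.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    log_lines = [f"seed={seed}"]

    # ---- inputs: simulate or load ----
    vcf_paths: list[Path]
    gene_path: Optional[Path] = None
    gene_fmt = None
    if "simulate" in config:
        sim = config["simulate"]
        n_chrom = int(sim.get("n_chromosomes", 1))
        vcf_paths = []
        for c in range(1, n_chrom + 1):
            chrom = str(c)
            cfg_c = _as_sim_config(sim, seed + c, chrom)
            hap = sim_data.simulate_neutral_haplotypes(cfg_c)
            if cfg_c.sweep is not None:
                hap = sim_data.apply_sweep(hap, cfg_c.sweep, seed=seed + 1000 + c)
            p = out / f"sim_chr{chrom}.vcf"
            sim_data.write_simulated_vcf(hap, cfg_c, p)
            vcf_paths.append(p)
            log_lines.append(f"simulated chrom {chrom}: {hap.n_sites} sites")
        n_genes = int(sim.get("n_genes", 0))
        if n_genes:
            gene_path = out / "sim_genes.gff3"
            sim_data.make_gene_annotation(int(sim["chrom_length_bp"]), n_genes,
                                          seed + 77, gene_path, chrom="1")
            gene_fmt = "gff3"
    elif "input" in config:
        vv = config["input"]["vcf"]
        vcf_paths = [Path(p) for p in (vv if isinstance(vv, list) else [vv])]
        if config["input"].get("genes"):
            gene_path = Path(config["input"]["genes"])
            gene_fmt = config["input"].get("genes_format")
    else:
        raise ValueError("config needs a 'simulate' or 'input' section")

    # ---- read + hard filters, per chromosome ----
    gmats, anns, haps, lengths = [], [], [], []
    hard_counts_total: dict[str, int] = {}
    n_hard_removed = 0
    for p in vcf_paths:
        g, ann, hap = vcf_qc.read_vcf(p, require_phased=True)
        hard_keep, hard_counts = vcf_qc.hard_filter_sites(ann)
        depth_keep = vcf_qc.depth_filter(ann)
        keep = hard_keep & depth_keep
        hard_counts["depth"] = int((~depth_keep).sum())
        for k, v in hard_counts.items():
            hard_counts_total[k] = hard_counts_total.get(k, 0) + v
        n_hard_removed += int((~keep).sum())
        idx = np.flatnonzero(keep)
        gmats.append(g.take_sites(idx))
        anns.append(ann.take_sites(idx))
        haps.append(hap.take_sites(idx))
        lengths.append(int(config.get("simulate", {}).get(
            "chrom_length_bp", int(g.pos.max()) if g.n_sites else 1)))
    log_lines.append(f"hard/depth filters removed {n_hard_removed} sites "
                     f"({hard_counts_total})")

    g_all = _concat_genotypes(gmats)

    # ---- sample filter + site QC ----
    kept_samples = vcf_qc.ibs_sample_filter(g_all)
    if len(kept_samples) < g_all.n_samples:
        log_lines.append(f"IBS filter removed "
                         f"{g_all.n_samples - len(kept_samples)} samples")
        g_all = g_all.take_samples(kept_samples)
        gmats = [g.take_samples(kept_samples) for g in gmats]
        hap_rows = sorted([2 * i for i in kept_samples]
                          + [2 * i + 1 for i in kept_samples])
        haps = [HaplotypeMatrix(h.alleles[hap_rows], h.pos, h.chrom)
                for h in haps]

    sel_keep, sel_report = vcf_qc.site_qc(g_all, track="selection")
    div_keep, div_report = vcf_qc.site_qc(g_all, track="diversity")
    g_sel = g_all.take_sites(np.flatnonzero(sel_keep))
    g_div = g_all.take_sites(np.flatnonzero(div_keep))
    pruned_idx = vcf_qc.ld_prune(g_div)
    div_report.excluded["ld"] = g_div.n_sites - pruned_idx.size
    g_div = g_div.take_sites(pruned_idx)
    sel_report.to_tsv(out / "qc_report_selection.tsv")
    div_report.to_tsv(out / "qc_report_diversity.tsv")
    log_lines.append(f"site QC: selection {g_sel.n_sites}, "
                     f"diversity {g_div.n_sites} sites remain")

    # per-chromosome haplotype matrices restricted to selection-track sites
    haps_sel = []
    offset = 0
    for hap, g in zip(haps, gmats):
        local = sel_keep[offset: offset + g.n_sites]
        haps_sel.append(hap.take_sites(np.flatnonzero(local)))
        offset += g.n_sites

    # ---- diversity ----
    groups = {k: list(v) for k, v in config.get("groups", {}).items()} or None
    hom, hom_means = diversity.observed_homozygosity(g_div, groups)
    f = diversity.inbreeding_f(g_div)
    pd.DataFrame({"homozygosity": hom, "F": f}).to_csv(
        out / "diversity_individuals.tsv", sep="\t")
    if groups:
        f_means = {k: float(f.iloc[list(v)].mean()) for k, v in groups.items()}
        pd.DataFrame({"homozygosity": hom_means,
                      "F": pd.Series(f_means)}).to_csv(
            out / "diversity_groups.tsv", sep="\t")
    scores, frac = diversity.pca(g_div)
    pca_df = pd.DataFrame(scores[:, : min(10, scores.shape[1])],
                          index=g_div.sample_ids)
    pca_df.columns = [f"PC{i + 1}" for i in range(pca_df.shape[1])]
    pca_df.to_csv(out / "pca_scores.tsv", sep="\t")

    # ---- scan + DCMS ----
    dc = {**_DEFAULT_DCMS, **config.get("dcms", {})}
    wn = {**_DEFAULT_WINDOWS, **config.get("windows", {})}
    table, regions, fit_rep = scan_and_call(
        haps_sel, lengths, window_bp=int(wn["size"]), step_bp=int(wn["step"]),
        min_snps=int(wn["min_snps"]), alpha=float(dc["alpha"]),
        nsamp=int(dc["nsamp"]), fit=str(dc["fit"]),
        threshold_logp=float(dc["threshold_logp"]), seed=seed)
    table.to_csv(out / "windows.tsv", sep="\t", index=False)
    fit_rep.pop("per_snp").to_csv(out / "snp_scores.tsv", sep="\t",
                                  index=False)
    log_lines.append(f"DCMS fit: mu={fit_rep['mu']:.6g} "
                     f"sigma={fit_rep['sigma']:.6g}")

    # ---- regions + genes ----
    with open(out / "regions.bed", "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.peak_neglogp:.4f}\t{r.n_windows}\n")
    genes = read_genes(gene_path, gene_fmt) if gene_path else []
    per_region_genes, n_distinct = overlap_genes(regions, genes)
    var_counts = count_region_variants(g_sel.chrom, g_sel.pos, regions)
    with open(out / "region_genes.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tpeak_neg_log10_p\tn_windows\t"
                 "n_variants\tgenes\n")
        for r, gl, vc in zip(regions, per_region_genes, var_counts):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_neglogp:.4f}\t"
                     f"{r.n_windows}\t{vc}\t{','.join(gl) if gl else '.'}\n")

    if config.get("plots"):
        _manhattan(table, out / "manhattan.png",
                   threshold=float(dc["threshold_logp"]))

    sizes = [r.size for r in regions]
    summary = {
        "n_samples": g_all.n_samples,
        "n_sites_selection": int(g_sel.n_sites),
        "n_sites_diversity": int(g_div.n_sites),
        "n_windows": int(len(table)),
        "n_windows_included": int(table["included"].sum()),
        "n_candidate_windows": int(sum(r.n_windows for r in regions)),
        "n_regions": len(regions),
        "region_size_mean": float(np.mean(sizes)) if sizes else 0.0,
        "region_size_sd": float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0,
        "n_distinct_genes": n_distinct,
        "dcms_fit": {"mu": fit_rep["mu"], "sigma": fit_rep["sigma"]},
        "seed": seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def _concat_genotypes(gmats: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    if len(gmats) == 1:
        return gmats[0]
    return GenotypeMatrix(
        np.concatenate([g.dosages for g in gmats], axis=1),
        np.concatenate([g.chrom for g in gmats]),
        np.concatenate([g.pos for g in gmats]),
        np.concatenate([g.ref for g in gmats]),
        np.concatenate([g.alt for g in gmats]),
        list(gmats[0].sample_ids))


def _manhattan(table: pd.DataFrame, path: Path, threshold: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table[table["included"] & table["neg_log10_p"].notna()]
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
        x = (grp["start"] + grp["end"]) / 2 + offset
        ax.scatter(x, grp["neg_log10_p"], s=6,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        offset += grp["end"].max()
    ax.axhline(threshold, color="red", lw=0.8)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
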