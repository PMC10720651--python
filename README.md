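# sweepscan

A tested, reusable selection-signature genome-scan pipeline for diploid
populations:

1. **SNP quality control** (`sweepscan.vcf_qc`) — GATK-style hard filters
   (FS > 60, QD < 2, MQ < 40, QUAL < 30, MQRankSum < −12.5,
   ReadPosRankSum < −8), a depth filter (mean per-site DP in
   [2, μ + 3σ]), 100% call-rate / MAF > 5% / HWE exact-test (p ≥ 1e-6)
   site filters, greedy windowed LD pruning (50 SNPs / step 10 / r² > 0.5,
   diversity track only) and a pairwise-IBS (≥ 0.95) sample filter.
2. **Diversity summaries** (`sweepscan.diversity`) — per-individual observed
   homozygosity and inbreeding F, exact Mann–Whitney / Wilcoxon rank tests,
   and PCA of centered dosages.
3. **Selection statistics** (`sweepscan.sel_stats`) — Tajima's D and mean
   per-site nucleotide diversity in sliding 100 kb windows (25 kb step),
   per-SNP iHS and nSL from extended-haplotype-homozygosity integrals
   (frequency-bin standardized), aggregated on the common window grid
   (windows with < 10 SNPs excluded).
4. **Composite score** (`sweepscan.dcms_core`) — fractional-rank p-values
   (left-tailed for D and pi, magnitude-ranked for iHS/nSL), a FAST-MCD
   robust correlation matrix (α = 0.75) to de-correlate the statistics, the
   weighted logit-sum composite, upper-tail normal p-values, candidate
   windows at −log₁₀ p ≥ 4 and merging into candidate regions.
5. **Annotation** (`sweepscan.annotate`) — gene-interval overlap (GFF3/BED),
   per-region variant counts, and the end-to-end pipeline driver.
6. **Synthetic data** (`sweepscan.sim_data`) — seeded phased-haplotype
   simulator with a neutral site-frequency spectrum, tunable LD decay,
   optional hard sweeps (shared core haplotype), planted hard-filter
   violations and missingness (with truth tables), VCF 4.2 + GFF3 output.

## CLI

```sh
# full pipeline from a YAML config (simulation block or input VCF paths)
sweepscan run --config config.yaml --out-dir out/

# individual stages
sweepscan simulate --n-individuals 20 --chrom-length-bp 2000000 \
    --snps 4000 --sweep 1000000 0.6 150000 --seed 1 --out sim.vcf
sweepscan qc --vcf sim.vcf --track selection --out-dir qc/
sweepscan diversity --vcf pruned.vcf --out-dir div/
sweepscan scan --vcf phased.vcf --chrom-length 2000000 --out windows.tsv
sweepscan dcms --windows windows.tsv --out-dir dcms/
sweepscan annotate --regions dcms/regions.bed --genes genes.gff3 --out genes.tsv
```

Example config:

```yaml
seed: 1
simulate:
  n_individuals: 20
  n_chromosomes: 4
  chrom_length_bp: 2000000
  target_snp_count: 4000
  ld_block_bp: 50000
  missing_rate: 0.01
  bad_site_fraction: 0.05
  n_genes: 40
  sweep: {chrom: "1", focal_pos: 1000000, carrier_fraction: 0.6,
          core_halfwidth_bp: 150000}
windows: {size: 100000, step: 25000, min_snps: 10}
dcms: {alpha: 0.75, nsamp: 50000, fit: mean_sd, threshold_logp: 4.0}
```

`run` writes QC reports, per-individual diversity tables, PCA scores, the
genome-wide window table, candidate-region BED/TSV (with overlapping genes
and variant counts), a run log and `summary.json` — byte-identical when
rerun with the same config and seed.

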