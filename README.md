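# sswgwas

Weighted single-step GWAS (WssGWAS) in Python: from a pedigree, SNP
genotypes and phenotypes to variance components, genomic breeding values,
back-solved SNP effects, iteratively re-weighted genomic relationship
matrices and 30-SNP window variance percentages that flag candidate
genomic regions.

## What it does

1. **Genotype QC** — call rate, parent–progeny (opposing-homozygote)
   conflicts, minor allele frequency, Hardy–Weinberg equilibrium, LD
   pruning, then naive mean-dosage imputation.
2. **Relationship matrices** — inbreeding-aware sparse A⁻¹ (Henderson
   rules), tabular A and A₂₂, weighted VanRaden G = ZDZ′/(2Σpq), the
   blend G\* = αG + (1−α)A₂₂ and the single-step
   H⁻¹ = A⁻¹ + [0 0; 0 (G\*)⁻¹ − A₂₂⁻¹].
3. **Variance components** — single-trait animal model
   y = Xb + Zu + e with u ~ N(0, Hσ²ᵤ) via AI-REML (average-information
   updates, EM fallback, SEs from the inverse AI matrix).
4. **GEBVs and SNP effects** — Henderson mixed-model equations for all
   pedigree animals; û = λDZ′(G\*)⁻¹â back-solving for genotyped animals.
5. **Weighted iterations** — SNP weights d = û²·2pq (normalized), G
   rebuilt and the evaluation repeated (default twice) at fixed variance
   components.
6. **Windows and regions** — non-overlapping windows of 30 adjacent SNPs
   per chromosome scored as var(Z_w û_w)/σ²ₐ × 100; windows above 0.5 %
   are reported as candidate regions, with a Manhattan-ready table.
7. **Synthetic data** — multi-generation pedigree simulation, gene
   dropping with Haldane recombination, QTL + polygenic architectures,
   period/season fixed effects, and a "degrader" that plants QC
   violations with an exact record of what was planted.

## CLI

```bash
# simulate a dataset (pedigree.csv, genotypes.vcf, phenotypes.csv, truth.tsv)
sswgwas simulate --config sim.yaml --out data/

# QC only
sswgwas qc --pedigree data/pedigree.csv --vcf data/genotypes.vcf --out qc/

# variance components (AI-REML under the single-step model)
sswgwas varcomp --pedigree data/pedigree.csv --vcf data/genotypes.vcf \
    --phenotypes data/phenotypes.csv --trait trait \
    --factor period --factor season --out vc/

# full weighted single-step GWAS
sswgwas gwas --pedigree data/pedigree.csv --vcf data/genotypes.vcf \
    --phenotypes data/phenotypes.csv --trait trait \
    --factor period --factor season --config run.yaml --out results/

# Manhattan table (and optional PNG)
sswgwas report --windows results/windows.tsv --out results/manhattan.tsv \
    --png results/manhattan.png
```

`run.yaml` mirrors `RunConfig` field names (maf_min, call_rate_min,
hwe_alpha, mendel_conflict_max, ld_r2_max, alpha_blend, window_size,
region_threshold_pct, n_weight_iterations, outlier_sd, seed, …); all
fields are optional and default to the study settings (MAF < 0.05, call
rate ≥ 90 %, HWE p < 10⁻⁶, α = 0.95, 30-SNP windows, 0.5 % threshold,
two weighting iterations).

## Package layout

| module | contents |
|---|---|
| `sswgwas.pedigree` | `Pedigree`, tabular A, inbreeding, sparse A⁻¹, A₂₂ |
| `sswgwas.genotypes` | `GenotypeMatrix`, QC filters, imputation, centered Z |
| `sswgwas.kinship` | `MarkerWeights`, G, blending, `Hinverse` |
| `sswgwas.mme` | phenotype prep, Sturges classes, design matrices, AI-REML, MME solver |
| `sswgwas.wssgwas` | back-solving, weight updates, weighted iterations, windows, regions, Manhattan table |
| `sswgwas.synthetic` | pedigree/genotype/phenotype simulation, QC-violation planting |
| `sswgwas.data_io` | `RunConfig`, pedigree/phenotype CSV, VCF, results TSVs |
| `sswgwas.pipeline` | end-to-end orchestration |
| `sswgwas.cli` | `sswgwas simulate\|qc\|varcomp\|gwas\|report` |
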