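# invadepop

Population-genomic inference pipeline for repeated freshwater-invasion
scenarios, built around nine lake/estuary populations (DT, PY, NY, LA, CH,
TH, HZ, GY, SH). Everything runs from seeded synthetic coalescent data — no
external downloads.

Components:

- **io_formats** — VCF 4.2 / population-map / SFS-text readers and writers,
  missingness filtering, one-SNP-per-locus thinning.
- **coalescent** — structured-coalescent simulation (msprime-backed) over
  declarative demographic models: per-population sizes, timed fusions, size
  changes, per-epoch backward migration matrices; infinite-sites mutations
  over fixed-length capture regions.
- **presets** — four built-in invasion scenarios (`model1`–`model4`:
  single split, common resident ancestor, two independent invasions, two
  invasions plus adjacent-population migration), every parameter overridable.
- **sfs** — joint site-frequency spectra: construction from genotypes,
  folding on total minor-allele count, outgroup polarisation, hypergeometric
  projection, pairwise marginals.
- **stats** — nucleotide diversity, multi-locus Weir–Cockerham Fst with
  permutation p-values, three-level AMOVA, PCA coordinates.
- **fit** — simulation-based composite-likelihood fitting of demographic
  models to an observed joint SFS, AIC ranking, Bayes-factor arithmetic.
- **abc** — ABC parameter estimation: reference tables, PLS summary
  reduction, rejection sampling, local-linear (or neural-net) regression
  adjustment, 95% HPD intervals.
- **fdist** — Fst-outlier scanning against a migration-tuned island-model
  coalescent null, with He-conditioned p-values and disruptive/balancing
  classification.
- **synth** — seeded VCF + popmap + truth-JSON fixtures emulating the target
  data shape (≈4.6 SNPs per variable 214 bp region at full scale), with
  optional spiked outlier loci.
- **pipeline / cli** — `invade` entry point chaining the stages with YAML
  config, derived per-stage seeds and a JSON run manifest.

## CLI

```sh
# simulate a desk-scale fixture (VCF + popmap + truth JSON)
invade simulate --preset model3 --scale 0.05 --seed 1 --outdir runs/fx

# descriptive statistics (Pi, pairwise Fst, AMOVA, PCA)
invade stats --vcf runs/fx/fixture.vcf --popmap runs/fx/popmap.tsv \
    --outdir runs/fx

# pairwise folded/unfolded SFS files
invade sfs --vcf runs/fx/fixture.vcf --popmap runs/fx/popmap.tsv \
    --pops DT,CH,SH --outdir runs/fx

# composite-likelihood model comparison, ranked by AIC
invade fit --vcf runs/fx/fixture.vcf --popmap runs/fx/popmap.tsv \
    --models model1,model2,model3 --pops DT,CH,SH --outdir runs/fx

# ABC estimation of invasion-time parameters
invade abc --vcf runs/fx/fixture.vcf --popmap runs/fx/popmap.tsv \
    --model model3 --pops CH,SH --nsims 1000 --naccept 100 --outdir runs/fx

# Fst-outlier scan
invade fdist --vcf runs/fx/fixture.vcf --popmap runs/fx/popmap.tsv \
    --pops DT,SH --nsims 20000 --outdir runs/fx

# whole chain from one YAML config, with a JSON manifest
invade run --config examples/run.yaml --seed 1
invade report runs/fx
```

A run config lists `stages` (ordered subset of
`simulate sfs stats fit abc fdist report`), a master `seed`, an `outdir`,
and one optional parameter block per stage; one master seed derives every
stage seed, so reruns reproduce all numerical outputs bit for bit.

## Conventions

- Time runs backward in generations; sizes are haploid gene copies;
  `migration[i][j]` is the backward probability a lineage in `i` came from
  `j`. Conversion to years uses the configurable `generation_time`.
- VCF coordinates stay 1-based; missing genotypes are `./.`; half-calls are
  treated as missing.
- SFS text dialect: header `#dims n1+1 n2+1 ... folded|unfolded`, then
  whitespace-separated counts in row-major order.
- Permutation p-values are `(count >= observed + 1) / (n_perm + 1)`.
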