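# staygreen

Analysis pipeline for winter-wheat cultivar panels: senescence-curve
canopy traits, mixed-model adjusted means and heritability, sliding-window
quantification of breeding progress, and a kinship-adjusted marker–trait
association scan — exercised end-to-end on synthetic panels with known
ground truth.

## What it does

- **`staygreen.synthetic_data`** — simulates cultivar × season × replicate
  phenotype panels (plot values decompose into cultivar, season,
  cultivar×season, season×rep, season×rep×subgroup and residual terms,
  each with its own seeded random stream), green-leaf senescence time
  courses, daily weather, and structured biallelic genotypes (subpopulation
  allele-frequency divergence, planted missingness, optional causal region
  whose per-cultivar value can be added to a trait).
- **`staygreen.canopy_traits`** — thermal time (base 0 °C, negative daily
  means truncated), least-squares fit of the two-parameter logistic power
  senescence curve `y = 1/(1 + (TT/GLA50)^s)`, green canopy duration
  (GLA50 − TT at heading), leaf area duration (integral of the curve from
  heading to harvest × LAI_max), grain-filling duration, and
  yield-component identities (HI, biomass, grains/m², yield).
- **`staygreen.mixed_model`** — average-information REML for the crossed
  random terms (exactly reproducing expected-mean-squares estimates on
  balanced data), GLS adjusted cultivar means (BLUEs) with equal season
  weights, broad-sense heritability
  `H² = σ²C / (σ²C + σ²CY/n + σ²e/(n·r))`, and sequential F-tests for
  cultivar, season and interaction.
- **`staygreen.breeding_progress`** — overlapping 10-cultivar sliding
  windows over the release-year ordering, OLS of window means (absolute
  progress per year), percent superiority of the 2010 vs 1970 predictions
  (relative progress), continuous two-phase segmented regression with
  exhaustive breakpoint search, and Pearson trait correlations.
- **`staygreen.association`** — marker QC (monomorphic, >10 % missing,
  MAF < 5 %), VanRaden kinship, PCA + k-means structure covariates, an
  exact one-random-effect mixed-model scan (single spectral decomposition,
  per-marker GLS at the null variance ratio), Bonferroni and
  Benjamini–Hochberg thresholds, pairwise LD r², and minor-allele burden
  summaries with an additivity diagnostic.
- **`staygreen.io` / `staygreen.pipeline` / `staygreen.cli`** — CSV/TSV
  (and minimal VCF) readers/writers with validation, a YAML-configured
  stage driver writing a run manifest, and the `staygreen` command line.

## Command line

```bash
staygreen simulate --out demo --seed 1 --n-cultivars 60 --n-markers 800
staygreen blues --phenotypes demo/phenotypes.csv --out demo/blues.csv --vc-out demo/vc.csv
staygreen progress --blues demo/blues.csv --trait yield --window 10 --segmented
staygreen gwas --blues demo/blues.csv --genotypes demo/genotypes.tsv \
    --map demo/genotypes_map.csv --trait gcd --alpha 0.05 --fdr 0.10 --k-groups 5
staygreen run --config pipeline.yaml          # full chain from a YAML config
```

`staygreen run` executes the enabled stages (simulate → canopy → blues →
progress → gwas) in dependency order and writes a `manifest.json`
recording inputs, parameters, seed and version; deterministic stages are
bit-identical on rerun.

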