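# ailepi

Epistasis analysis for advanced intercross lines (AILs): two-locus
interaction scans, genotype-stratified effect estimation, model-free and
orthogonal parametric genotype-phenotype (GP) maps, k-level multi-locus
effect decomposition, and the R_p plane-variance statistic for detecting
third-order capacitating epistasis — together with a synthetic AIL
generator so that the whole pipeline runs end-to-end without external data.

## What's inside

| module | purpose |
| --- | --- |
| `ailepi.synthetic_ail` | AIL pedigree builder, gene-dropping line-origin genotypes (Haldane recombination), configurable epistatic architectures, phenotype simulation |
| `ailepi.genotype_strata` | contrast discretization (±0.4 thresholds), sex×generation residualization, conditioning-locus HH/LL strata |
| `ailepi.scan_engine` | two-locus epistatic model with nested F-tests, 2D marker-selection scans, 1D additive scans, bootstrap-averaged profiles, max-statistic permutation thresholds |
| `ailepi.effect_estimation` | stratified additive effects ± SE, one-sided strata comparison, network summaries (stratum sums / ratio / % of line difference), k-level decomposition |
| `ailepi.gp_map` | 10-class model-free GP map, orthogonal (statistical-scaling) genetic-effect fits, effect↔genotype-value transformation, higher-order indicator |
| `ailepi.triplet_rp` | pair/triplet genotype-class means, plane extraction, within-plane variances, R_p ratio, exhaustive triplet scans |
| `ailepi.cli_io` | dataset I/O + validation, YAML config, deterministic full pipeline with run manifest |

## CLI

```sh
# simulate an AIL with a capacitated radial network architecture
ailepi simulate --preset radial_network --noise-sd 127 --seed 1 --out-dir data/

# individual stages
ailepi scan2d data/ --out selected.csv
ailepi scan1d data/ --perms 1000 --bootstrap 200 --out profile.csv
ailepi strata-effects data/ --loci Growth9_m1,Growth4_m1,Growth12_m1 --out effects.csv
ailepi gpmap data/ --mode compare --hub Growth9_m1 \
    --radial Growth1_m1,Growth2_m1,Growth3_m1,Growth4_m1 --out gpmap.csv
ailepi triplets data/ --loci Growth9_m1,Growth4_m1,Growth12_m1,Growth1_m1 --out rp.csv

# the whole pipeline with a manifest
ailepi run-all data/ --seed 1 --out-dir report/
```

Input formats are plain CSV: a contrast matrix (rows = individuals,
columns = marker ids, values in [−1, 1]), a phenotype table
(`id,weight56,sex,generation`), a pedigree (`id,sire,dam,generation,sex`)
and a marker map (`segment,marker,marker_id,mb,cm`).

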