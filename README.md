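# genodim

Simulation pipeline linking the *dimensionality of genomic information* —
the number of largest eigenvalues of a genomic relationship matrix (GRM)
explaining x% of its variance — to GWAS sample size, causal-variant
discovery, and single-step GBLUP (ssGBLUP) prediction accuracy with
preselected variants.

The pipeline has six stages, one module each:

| module                  | role |
| ----------------------- | ---- |
| `genodim.simpop`         | forward-in-time simulator: historical drift population, recent breeding population (sires/dams, age-based replacement), MAF-filtered SNP/QTN genome map, gamma QTN effects scaled to an exact additive variance, phenotypes |
| `genodim.panels`         | sequence panel (SNPs + QTN), systematic chip panel (every 10th SNP), panel augmentation with top-p or Bonferroni-significant GWAS variants |
| `genodim.dimensionality` | VanRaden and mean-centered GRMs, eigen-profiles, EIGx eigen counts, Ne-based dimensionality heuristics (Me = 4·Ne·L), nested discovery/training/test subsets |
| `genodim.gwas`           | EMMAX-style mixed-model scan (spectral REML of the null model + per-variant GLS with fixed covariance), Bonferroni thresholds, per-QTN variance-explained accounting (2pqβ²/σu²), loess-based inverse sample-size estimation |
| `genodim.predict`        | pedigree A matrix (tabular method), blended G, combined H⁻¹, mixed-model-equation solver, ssGBLUP / PBLUP evaluation scenarios |
| `genodim.evaluate`       | accuracy (corr(TBV, GEBV)), dispersion b1, gain %, replicated scenario-grid orchestration with per-stage child seeds |

All sizes are configurable, so the full-scale design (29 chromosomes /
23.19 Morgans, 500k SNPs, 15,000 dams, 315k animals) and desk-scale runs
(seconds to minutes) use the same code paths.

## CLI

```bash
genodim simulate   --config cfg.yaml --seed 1 --out simdir       # write pedigree / PLINK / VCF / phenotypes
genodim dimension  --grm grm.npz --levels 50,90,98 --out dims.tsv
genodim gwas       --pheno simdir/phenotypes.tsv --geno simdir/genotypes --out assoc.tsv
genodim predict    --pedigree ped.txt --geno prefix --panel panel.txt \
                   --pheno phen.tsv --train-set train.txt --test-set test.txt \
                   --model ssgblup --out gebv.tsv
genodim experiment --config grid.yaml --replicates 3 --seed 1 --out outdir
```

`simulate` configs are YAML key/value files mirroring
`genodim.simpop.SimConfig` (see its docstring for every field).
`experiment` grids take a `base` config plus a list of `scenarios`, each
with `name`, config overrides, `eigx_levels`, `topv`, and `models`.

## Library example

```python
from genodim import SimConfig, simulate
from genodim.evaluate import ScenarioSpec, run_experiment

cfg = SimConfig(n_chromosomes=2, total_length=2.0, n_snp_target=1500,
                n_qtn_target=80, hist_schedule=((-80, 80), (-40, 300), (0, 220)),
                n_sires=30, n_dams=100, h2=0.9)
spec = ScenarioSpec(name="demo", config=cfg, eigx_levels=(90, 95), topv=(10, 50))
metrics = run_experiment([spec], n_replicates=3, seed=1, out_dir="out")
print(metrics.aggregate())
```
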