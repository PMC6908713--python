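# cpgclock

Maximum-lifespan prediction for vertebrate species from genome sequence
alone, using the CpG density of a selected set of gene promoters.

Maximum lifespan is a central life-history trait, yet it is unknown or
unreliable for most wild species: it usually comes from a handful of captive
records, and for extinct species it cannot be observed at all. CpG
dinucleotides in promoters are the substrate of DNA methylation, and their
density in a subset of promoters scales with species lifespan across
vertebrates. `cpgclock` turns that observation into a reusable pipeline for
comparative genomicists, conservation biologists and fisheries scientists:
from promoter homology hits and genome FASTA to a trained "lifespan clock",
and from a VCF of ancient-genome variants to a lifespan estimate for an
extinct species.

## The model

For each species *s* and promoter *i*, the feature is the CpG density of
the promoter's single best homology hit (identity > 70%, strict):

    d_i = (# CpG sites in the hit interval) / (hit alignment length),

with d_i = 0 when no qualifying hit exists. The clock is a two-stage
regression on the natural-log lifespan:

1. **Elastic net** (mixing parameter α = 0.5, penalty λ chosen at the
   10-fold cross-validation MSE minimum) fits
   ln *L* ≈ w₀ + Σᵢ wᵢ d_i on a class-stratified 70/30 training split,
   selecting a sparse set of "lifespan loci". The linear predictor
   x = w₀ + Σᵢ wᵢ d_i is the *raw score*.
2. **Phylogenetic GLS calibration** regresses ln *L* on x under a
   Brownian-motion trait covariance V built from divergence times
   (V_ij = shared evolutionary time), with vertebrate-class offsets:

       ln(maximum lifespan) = c₀ + c₁·x + a·x + b,

   where (a, b) depend on the vertebrate class and the reference class
   uses a = b = 0. The published clock's constants, c₀ = −4.38996 and
   c₁ = 2.57328 with per-class (a, b) for Aves, Fish, Mammalia and
   Reptilia, ship with the package (`load_published_clock()`).

For extinct species, called SNPs are substituted into the reference
genome's lifespan-locus intervals, CpG densities are recomputed on the
edited sequences, and the same formula is applied.

Because the full-scale inputs (252 reference genomes, curated lifespan
records, divergence times) are external downloads, the package includes a
first-class synthetic-data generator: an ultrametric Yule tree, a Brownian
ln-lifespan trait with classes confounded with clades, promoter densities
linearly coupled to ln lifespan for a causal subset, and genome/promoter
sequences realizing those densities exactly — so every stage, from tabular
homology parsing to ancient-genome prediction, is testable end to end.

## Worked example

```python
from cpgclock import (SimulationConfig, TrainingConfig, simulate_panel,
                      train_clock, predict_lifespan, score_predictions)

panel = simulate_panel(SimulationConfig(seed=7))          # 250 species, 500 promoters
model, train_ids, test_ids = train_clock(
    panel.density_matrix, panel.records, panel.tree, TrainingConfig(seed=7))
print(f"selected {len(model.promoter_weights)} promoters "
      f"at lambda = {model.selected_lambda:.4f}")

preds = [predict_lifespan(model, panel.density_matrix.row(s),
                          panel.classes[s], species_id=s) for s in test_ids]
report = score_predictions({s: panel.lifespans[s] for s in test_ids}, preds)
print(report.summary())
```

prints

```
selected 60 promoters at lambda = 0.0435
ln-scale R^2 (Pearson^2): 0.9514
median absolute error:    3.27 years
max relative error:       94.2%
  Amphibia: R^2 = 0.901 (p = 0.0507)
  Aves: R^2 = 0.517 (p = 0.00169)
  Fish: R^2 = 0.768 (p = 8.45e-06)
  Mammalia: R^2 = 0.815 (p = 9.21e-12)
  Reptilia: R^2 = 0.361 (p = 0.153)
class-effect ANCOVA p:    0.1134
```

The elastic net recovered a sparse locus set (60 of 500 promoters, most of
them planted causal ones), and the held-out test set shows a strong
ln-scale fit (R² = 0.95) with a median absolute error of about 3 years.
Per-class R² varies — smaller classes (Reptilia, Amphibia in the test
split) are noisier — and the relative error is largest for the
shortest-lived species, where a small absolute miss is a large fraction of
a 1–2-year lifespan.

The same steps are available from the shell:

```sh
cpgclock simulate --n-species 250 --causal 40 --null 460 --seed 7 --out demo/
cpgclock train --densities demo/densities.csv --species demo/species.csv \
    --divergence demo/tree.nwk --seed 7 --out demo/model.json
cpgclock evaluate --model demo/model.json --densities demo/densities.csv \
    --species demo/species.csv --split demo/model.split.json
cpgclock predict-ancient --model demo/model.json --reference ref.fa \
    --loci loci.bed --vcf calls.vcf --class Mammalia
```

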