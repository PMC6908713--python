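# Methods

## Feature definition

A promoter's CpG density in a species is defined on its single best
homology hit: the number of CpG dinucleotides in the hit's genomic interval
divided by the hit's alignment length. The alignment length is the
aligned-column count from 12-column tabular search output, which may exceed
the subject-interval width when the alignment is gapped; we use it as the
denominator because it is the natural reading of "hit length" for tabular
output, while the numerator counts CpGs in the subject interval. Promoters
with no hit above the identity threshold (strictly greater than 70%)
contribute density 0. At most one hit is kept per (species, promoter):
highest bitscore, ties broken by lowest e-value, then input order — the
ranking a search tool itself would apply. High-scoring pairs are never
merged.

Coordinates are 0-based half-open internally; tabular 1-based inclusive
subject coordinates are converted on parse, with subject start > end
marking a minus-strand hit. Minus-strand hits use the forward-strand slice
for counting: CpG is reverse-complement symmetric, so the count is
identical and no reverse complementation is needed. Any dinucleotide
containing a non-ACGT character is not a CpG; N bases are excluded from
both terms of genome GC content. Counting is case-insensitive.

The built-in seed-and-extend aligner (exact 11-mer seeds, ungapped
extension while running identity stays above the threshold, best match
count wins) exists so synthetic fixtures can be aligned without an external
search binary. It is deliberately minimal — no gaps, no HSP chaining, no
e-value model — and is not intended for real genome-scale searches.

## The two-stage clock

Known maximum lifespans are natural-log transformed. Species are split
70/30 into training and testing sets, stratified within each vertebrate
class (round(0.7·n) per class to training, drawn uniformly with a seeded
generator; a single-member class goes to training with a warning).

**Stage 1 — elastic net.** The training rows of the density matrix are
standardized (population SD; constant columns pass through) and fit with
the objective

    (1/(2n))·Σ(y − w₀ − Xw)² + λ·(α·Σ|wᵢ| + ((1−α)/2)·Σwᵢ²),

α = 0.5 by default. λ is chosen at the minimum mean-squared error of
k-fold cross-validation (k = 10) over a descending λ path (lambda-min, not
the 1-SE rule). Weights are mapped back to the original density scale and
only nonzero weights are stored. This parametrization makes λ directly
comparable with the widely used R implementation of the same estimator.
The response is not standardized. The raw score of a sample is
x = w₀ + Σ wᵢ dᵢ with absent densities treated as 0.

**Stage 2 — PGLS calibration.** The raw scores of the training species are
regressed on ln lifespan by generalized least squares,
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, on the design [1, x, class indicators, class·x
interactions]. The covariance V assumes Brownian trait evolution:
from a pairwise divergence-time matrix, V_ij = max(0, T − t_ij) with
V_ii = T = max t_ij (an ultrametric molecular-clock assumption); from a
tree with branch lengths, V_ij is the root-to-MRCA path length, which also
covers non-ultrametric trees. No Pagel's-λ or Ornstein-Uhlenbeck
transformation is estimated — pure Brownian motion is the common default
of the comparative-methods packages this stage mirrors. The reference
class is Amphibia (absorbed into the global intercept and slope), so
classes absent from the calibration — including any unknown class at
prediction time — use a = b = 0; this reproduces the published formula's
behaviour, whose class table lists only Aves, Fish, Mammalia and Reptilia.
Classes with fewer than two members are excluded from calibration with a
warning. If the reference class itself has fewer than two training
members, the global intercept and slope become exactly collinear with the
full set of class dummies; the fit then re-references to the largest class
(which takes a = b = 0) and warns, rather than failing. Body-trait covariates are deliberately not part of the model.

Prediction is ln L = c₀ + c₁·x + a·x + b, lifespan in years = exp(ln L).
Humans receive no special casing; the curation question of what counts as
the human maximum lifespan is a data decision upstream of the model.

## Ancient-genome path

Variant calling is out of scope; the contract boundary is a VCF of
biallelic SNPs against the reference of a close extant relative. Each
lifespan locus (BED interval on the reference) is sliced, passing SNPs
inside the interval are substituted (REF-base mismatches raise an error,
guarding against genome-version mix-ups; indels and multiallelic records
are skipped with a logged count; genotype fields are ignored, as
ancient-DNA pipelines emit consensus-style calls), and the density is
recomputed with the locus interval width as denominator. The interval
width — not a homology alignment length — keeps edited and reference
densities directly comparable on the same intervals.

## Evaluation battery

- R² on the ln scale is the squared Pearson correlation between known and
  predicted ln lifespan. The simple-regression R² is reported alongside;
  for a univariate linear fit the two coincide, and both the correlation
  and its square are exposed because published accuracy figures are
  sometimes quoted as r and sometimes as r².
- MAE is the **median** absolute error in years; relative error is
  |pred − known| / known per species.
- Group error comparisons (training vs testing, captive-record vs
  wild-record species) use Welch's unequal-variance t-test on absolute
  errors.
- The vertebrate-class effect is tested by ANCOVA on
  known ~ predicted + class with sequential sums of squares, covariate
  first. The F statistic is computed from the SSR drop between nested OLS
  fits rather than `anova_lm(typ=1)`, because the formula machinery orders
  categorical terms before the covariate, which silently reverses the
  sequential order (verified to miscalibrate the null).
- PCA standardizes columns (correlation PCA, population SD), dropping
  zero-variance promoters with a warning.
- Per-promoter Pearson correlations with ln lifespan flag and exclude
  zero-variance columns instead of erroring.
- TSS-flank profiles cut ±5 kb around each annotated TSS into 500-bp bins
  ordered 5'→3' along the gene (mirrored for minus-strand genes), drop
  bins truncated by contig edges, and average per-bin CpG density over
  TSSs; profiles are compared with a two-sample Kolmogorov–Smirnov test.
  Cluster-count selection over profile shapes is out of scope.

## Synthetic-data generator

The generator emulates the study design the clock targets, so that the
full pipeline can be exercised and its recovery properties measured
without downloads.

- **Tree**: a pure-birth (Yule) tree, crown-rooted and scaled to 500 MY
  depth, so every root-to-tip path spans the full depth; leaves sp0001….
- **Trait**: ln lifespan evolves by Brownian motion (default
  σ = 0.02 ln-years/√MY) around class-specific means; the five vertebrate
  classes are assigned to contiguous clades (not at random), so class and
  phylogeny are confounded as in real data; values are min-max rescaled
  into ln(1.1)…ln(205) years, the span of the real panel.
- **Panel**: 250 species by default (the study scale), class proportions
  dominated by mammals (0.40/0.22/0.22/0.10/0.06 for Mammalia, Aves, Fish,
  Reptilia, Amphibia), record provenance drawn 151:84:17
  captivity:wild:unknown.
- **Densities**: 40 causal promoters among 500 follow
  d = clip(base + slope·ln years + ε, 0, 0.4), with per-promoter signed
  slopes (≈ 22:12 positive:negative, matching the empirical split of
  individually significant loci) of magnitude 0.03·U(0.5, 1.5) density
  units per ln-year and noise SD 0.04; null promoters are noise around a
  random base. The 0.4 cap keeps densities realizable as non-overlapping
  CpG dinucleotides.
- **Sequences**: each species × promoter density is realized exactly as a
  600-bp sequence (the promoter-database window −499..+100) containing
  round(d·600) CpGs, embedded in a synthetic genome with CpG-free spacers;
  companion hit tables, BED loci and VCFs are emitted so file-level code
  paths are covered. Recomputed densities round-trip within the rounding
  quantum 1/600.
- **Ancient variants**: SNPs that each provably change a locus's CpG count
  by exactly ±1 (C→T at a CpG; X→G after a lone C), position-disjoint by
  construction.

Everything is bit-reproducible given the seed.

### Calibration of the defaults, and what passing does not show

The effect/noise defaults were chosen so the pipeline operates in the
regime the clock was reported in at n ≈ 250. A property worth knowing
emerged while setting them: because stage 2 is GLS under Brownian
covariance, it effectively regresses on phylogenetic contrasts, and
closely related species contribute contrasts whose trait difference is
tiny while their density noise is undiminished — with too little
per-promoter signal the within-class calibration slopes attenuate toward
zero and held-out accuracy collapses. The shipped defaults put test-set
ln-scale R² around 0.88–0.97 across seeds, somewhat above the ≈ 0.76 of
the real study, trading realism for robust recovery across seeds.

The generator's simplifications mean a passing suite shows algorithmic
correctness, not field performance: synthetic genomes have no repeats,
isochores or assembly artefacts; homology is planted at identity 100
rather than degrading with divergence (the real signal decays with
distance from the query species); density noise is Gaussian and
independent across promoters, while real promoter densities co-vary; and
lifespan records carry no observation error. Accuracy numbers from
synthetic runs therefore overstate what real genomes would give.

## Numerical notes

- Elastic-net coordinate descent runs at tol 1e-10 / 100k iterations when
  λ is pinned (the λ = 0 limit must meet the normal equations to 1e-6);
  the CV path uses looser, faster settings.
- The stratified split uses floor(x + 0.5) rounding, avoiding banker's
  rounding surprises; with class sizes (100, 80, 40, 20, 12) and fraction
  0.7 this yields the 176/76 partition of the 252-species design.
- GLS errors on a singular design (e.g. a class with constant raw score)
  name the offending class; a non-invertible V raises rather than being
  regularized.
- Model JSON serialization uses repr-exact floats, so save → load → save
  is byte-identical.
- Hit filtering is idempotent; the degenerate inputs (empty search output,
  empty weight map, constant response, fewer rows than folds) raise or
  return empty values as documented on each function.

## Known limitations

- The published 42-promoter weight set is not redistributable at full
  precision, so the shipped published-clock fixture carries the global
  constants and class table with an empty weight map: it can evaluate the
  printed formula from a raw score but cannot recompute raw scores for
  real genomes. Refitting it requires the original genome panel.
- The seed-and-extend aligner is for fixtures, not discovery; use a real
  search tool and feed its tabular output.
- Predictions carry no uncertainty intervals (none are defined for the
  published clock), and the model is calibrated for vertebrates only —
  invertebrate genomes fall outside its validity, as the original
  evaluation found.
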