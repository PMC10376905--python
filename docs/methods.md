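# Methods

## Problem and model

`myeloboost` classifies somatic variants called on a 24-gene myeloid
amplicon panel as pathogenic or benign. Each annotated variant is
mapped to a fixed 14-dimensional numeric vector
(f: R^14 -> {benign, pathogenic}) and scored by a gradient-boosted tree
ensemble (XGBoost, binary logistic objective). The model's probability
output is additionally mapped to five ordered reporting tiers
(Benign < Likely benign < Uncertain < Likely pathogenic < Pathogenic)
with cut-points 0.001 / 0.05 / 0.95 / 0.99, implemented as contiguous
half-open intervals so every score in [0, 1] receives a tier (0.99
itself falls in "Likely pathogenic").

## Feature encoding

The encoder is total on its declared token sets and raises on anything
else. Fields and codes:

| feature | content |
|---|---|
| chr | chromosome as integer, X -> 23, Y -> 24 |
| POS | genomic position (opaque numeric; no interval arithmetic) |
| TypeBin | SNV 0 / MNV 1 / INDEL 2 |
| Exon | exon ordinal, 0 = intronic |
| Freq | variant allele fraction in [0, 1] |
| MAFbin | population minor allele frequency, -1 if absent |
| Coverage | read depth (raw; optional 0/1 binarization at a threshold) |
| Protbin | p.? 0 / p.(=) 1 / amino-acid change 2 |
| aarefbin | reference residue ordinal 1-21 (Arg 1 ... Cys 21, Sec 11) |
| aamutbin | mutant residue ordinal 1-21, fs/Ter/del/dup -> 22 |
| aarefChemical / aamutChemicalVal | side-chain polarity code (apolar 1.x, uncharged 2.x, negative 3.x, positive 4.x, non-residue 0.0) |
| Grantham | substitution distance 5-215, 0 identical, -1 not applicable |
| varEffectBin | synonymous 0 / missense 1 / nonsense 2 / frameshift 3 / unknown -1 |

Sentinel policy: records without a residue on one side (intronic,
synonymous, frameshift/stop/indel outcomes) carry ordinal 0, polarity
0.0 and Grantham -1 on that side. A synonymous change written with an
explicit residue (`p.Leu422=`) keeps its reference-residue codes.

Grantham distances come from the published 1974 matrix embedded as
constants (symmetric, zero diagonal, off-diagonal range exactly
[5, 215]); they are not re-derived from the composition/polarity/volume
formula, whose printed form under-specifies the scaling constants.

The coverage column is passed through as raw depth by default; a
`binarize_coverage` switch exposes a 0/1 encoding at a configurable
bound (300x is the panel's QC floor) because depth can serve either as a
quality covariate or as a pass/fail flag depending on laboratory
practice.

HGVS `p.` parsing accepts 1- and 3-letter residue codes, substitutions,
stop gains (`Ter`/`*`), frameshifts (`fs...`), deletions, duplications,
ranges and `delins` (folded into the deletion class), plus the `p.?`
and `p.(=)` forms; anything else is a parse error rather than a silent
sentinel. `dup` is coded 22 in `aamutbin` like the other non-residue
outcomes; only fs/Ter/del are fixed by the encoding table, so the dup
assignment is a documented choice.

## Class imbalance

Cohorts are ~15:1 benign:pathogenic. Training uses a smoothed bootstrap
of the minority class: resample minority rows with replacement, add
zero-mean Gaussian noise (bandwidth = Silverman's rule per feature x a
configurable factor, default 1) to the continuous features (POS, Freq,
MAFbin when present, Coverage), then snap each jittered value to the
nearest value observed among the minority donors. The snapping step is
deliberate: panel data is quantized (positions sit on amplicon loci,
frequencies are reported at fixed resolution), and unconstrained
Gaussian noise would place every synthetic row off the data's support,
letting the learner identify synthetic rows by "impossible" values and
biasing both the fit and the feature-importance ranking. Snapping
preserves the neighbor-mixing effect of smoothing while keeping
synthetic rows valid. With factor 0 the synthetic rows are exact
copies. Sentinels (-1) and categorical codes are never perturbed;
majority rows are never touched.

The default pipeline order is split first (stratified 70/30), then
oversample the training side only, so the test set keeps the original
imbalance. A `before_split` stage exists for reproducing workflows that
balance the whole table first; balancing before the split leaks
synthetic copies of test-set variants into training and inflates test
metrics, which is why it is not the default.

## Tuning objective

The fitness of a hyperparameter candidate is mean held-out accuracy
under stratified k-fold cross-validation repeated r times (defaults
k = 10, r = 3) on the balanced training table, partitioned directly
(folds are not re-balanced per fold). The table is canonically sorted
before partitioning, so fitness is invariant to input row order and
fully determined by (candidate, table contents, CV seed).

Seven controls are searched; integer-valued ones are continuous during
the search and rounded at decode time:

| control | box | notes |
|---|---|---|
| nrounds | [100, 600] int | boosting iterations |
| eta_exponent | [-5, 0] | learning rate = 10^x |
| max_depth | [2, 6] int | tree depth |
| gamma | [0, 1] | min split-loss reduction |
| colsample_bytree | [0.4, 1] | feature fraction per tree |
| min_child_weight | [1, 3] int | min leaf weight |
| subsample | [0.5, 1] | row fraction per round |

The learning rate is searched as a base-10 exponent. The default
exponent interval is [-5, 0]; a narrower [-5, -3] can be requested but
excludes the region (around 10^-1) where tuned optima typically land,
so it is not the default.

## Optimizers

All four metaheuristics maximize over the box with clipping projection,
a fixed iteration budget, and one seeded generator per run
(bit-reproducible). Best-so-far traces are recorded per iteration.

* **Differential evolution** - DE/rand/1/bin: mutant
  `x_r1 + F (x_r2 - x_r3)` with F = 0.5, binomial crossover CR = 0.9
  with one guaranteed-inherited coordinate, greedy one-to-one selection,
  equal-fitness ties broken by a fair coin. Defaults NP = 10,
  10 generations.
* **Particle swarm** - velocity
  `omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x)` with fresh uniform
  draws per component and term; omega = 0.5, c1 = c2 = 2.05; velocities
  start at zero and are clamped to the box width; positions projected.
* **Genetic algorithm** - rank-weighted parent selection (linear
  weights), one-point crossover at a uniform cut, per-gene mutation by
  uniform resampling; elitism 0.3 and random admission 0.1 of the
  population survive per generation with their fitness cached.
  Defaults: population 10, 10 generations, mutation rate 0.5.
* **Simulated annealing** - one chain; per-coordinate perturbation
  `x + delta * width * r` with r ~ U[-1, 1] and delta a fraction of
  each dimension's box width (default 0.1; a single absolute step
  cannot serve dimensions whose ranges differ by three orders of
  magnitude); Metropolis acceptance exp(dF/T) for non-improving moves;
  geometric cooling T <- 0.95 T; 100 iterations default; the best state
  ever visited is returned, not the final one.

Evaluation budgets: DE and PSO spend `pop x (iterations + 1)`
evaluations, SA `iterations + 1`, the GA
`pop + generations x (pop - elites - random admits)`.

## Evaluation

Confusion matrices are oriented rows-are-predicted. Metrics: accuracy,
precision, recall/sensitivity, specificity, error rate (= 1 -
accuracy), F1 (= TP / (TP + (FN+FP)/2)), Matthews correlation, Cohen's
kappa (marginal-product expected agreement), and trapezoidal ROC AUC
from a threshold sweep over unique scores with ties stepped together.
Zero-denominator rates are reported as 0 with a warning; MCC is 0 when
a marginal is empty; kappa of a degenerate (pe = 1) matrix is 1 for
perfect agreement, else 0. Kappa bands: <0.21 none, <0.40 minimal,
<0.60 weak, <0.80 moderate (the 0.60-0.79 interval is absent from the
published banding and filled with the conventional label), <=0.90
strong, above almost perfect.

Feature importance is reported by the split-count ("weight") method:
the number of times each feature is used to split, across all trees,
normalized to sum to one (plus a 0-100 rescaling for plotting). A
total-gain share variant is available via `feature_importance(model,
method="total_gain")`. Split counts on data with high-cardinality
identifier-like columns (e.g. raw genomic positions) can reward
memorization rather than signal; the synthetic generator's quantized
positions and the support-snapping oversampler keep this effect in
check, but importance rankings between features of similar strength
remain seed-sensitive.

## Synthetic cohorts

The study cohort is private, so the generator emulates its published
structure: 15,977 variants (13,221 SNV / 73 MNV / 2,683 INDEL), 14,957
benign vs 1,020 pathogenic, a 24-gene panel. Cohorts are built
catalogue-first: distinct variants (recurrence ~12x benign, ~8x
pathogenic) carry fixed attributes - position on one of 8 amplicon
anchors per gene, protein change, population MAF, typical allele
fraction, amplicon depth - and each observation adds per-patient VAF
noise and QC-binned depth (nearest 100x, floor 300x). Class-conditional
structure:

* MAF present w.p. 0.97 (benign, Beta(1.3, 10)) vs 0.40 (pathogenic,
  Beta(1.05, 40)): absence from population databases, or a tiny
  frequency, is the dominant pathogenicity cue, as in the real panel.
* VAF: benign variants look germline (heterozygous peak at ~0.5,
  homozygous peak at ~0.97), pathogenic variants span a broad
  subclonal-to-clonal band (per-variant means 0.08-0.60).
* Effect classes: pathogenic rows enriched for missense/nonsense/
  frameshift, benign rows for synonymous/intronic; missense partners
  are drawn with exp(+-Grantham/60) weights so pathogenic substitutions
  skew to larger physico-chemical distances.
* Label noise (default 0.005) operates at the catalogue level: a noisy
  variant keeps its label but draws features from the opposite class,
  so configured class counts stay exact while the feature->label map
  stays probabilistic.

What the generator does not model: real transcript coordinates,
per-gene mutation spectra, the real cohort's feature correlation
matrix, sequencing artifacts. Passing tests on synthetic cohorts
demonstrates that the pipeline's machinery (encoding, balancing,
tuning, evaluation) behaves correctly and recovers planted structure;
it does not certify the published headline accuracy on the private
clinical data.

## Problem sizes in the test suite

Unit tests run on 500-600-row cohorts. The parameter-recovery check
uses the full-scale default cohort (15,977 rows), a 2,000-row subsample
of the balanced training table, 3-fold x 1 CV fitness, a DE budget of
6 x 5 and a 200-point random-search baseline; these sizes keep the
whole recovery under a few minutes on one CPU while still exercising
every pipeline stage at study-like imbalance.

## Known limitations

* The Grantham matrix excludes selenocysteine; Sec-containing
  substitutions return the -1 sentinel and have no polarity code.
* The tier cut-points are fixed reporting conventions, not calibrated
  probabilities; no probability calibration is performed.
* The evaluation module is strictly binary; no multi-class metrics, no
  AUC confidence intervals.
* Single-threaded deterministic training is the default; multi-threaded
  training is faster but may break bit-reproducibility of model files.
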