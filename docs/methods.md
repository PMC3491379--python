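# Methods

`girewire` models the number of negative genetic interactions (GI degree) a
gene participates in as a function of sixteen physiological and
evolutionary gene features, transfers that model between two yeast-like
species, and tests gene modules for cross-species rewiring of their network
connectivity.  This note records the models, the defaults and why, and what
the synthetic world does and does not establish.

## The degree model

Each species' model is a bag of `n_trees = 100` CART regression trees.  A
tree is grown on a bootstrap sample (drawn with replacement, same size as
the training set, so each tree sees ~63.2% of genes) by greedily choosing,
at every node, the (feature, threshold) pair that minimizes the summed
squared error of the two children.  Candidate thresholds are midpoints
between consecutive distinct observed values.  Leaves predict the mean
training degree of their node — the standard form of an MSE-impurity tree.

- **min_split = 10**: nodes with fewer samples become leaves.  This is the
  long-standing default of the classic CART implementations of this model
  family; no deeper tuning is attempted (this is bagging, not a random
  forest — every split sees every feature).
- **Missing features**: a candidate split's impurity is computed over the
  samples with that feature observed.  Once a split is fixed, samples (and
  prediction-time genes) missing the feature are routed to the child that
  received more training samples, tie toward the left.  Surrogate splits
  were considered and rejected as complexity without a stated benefit.
- **Tie-breaks**: among equally good splits (within a 1e-9 relative
  tolerance, so float summation order cannot flip a tie), the lowest
  feature index in the canonical order wins, then the smallest threshold.
  This makes fits bit-reproducible given a seed.

**Out-of-bag prediction.**  The within-species prediction for a gene is
the *median* over exactly the trees whose bootstrap sample excluded it; a
gene drawn into every tree gets a missing prediction.  This yields honest
held-out predictions without a test split.  Cross-species prediction
applies all 100 trees to the other species' feature table and takes the
median — no gene of that species was ever trained on.

**Evaluation.**  Predictive ability is the Pearson correlation between
predicted and observed degrees, repeated over `n_repeats = 25` refits with
fresh bootstrap seeds and reported as mean ± sd.  Within- and cross-species
correlations are computed from the same 25 refits (`evaluate_paired`),
which halves the cost without changing either statistic.

**Ablations.**  Because single-mutant fitness defect dominates, two
variants quantify what the other 15 features add: a model trained without
the fitness column, and a residual model — fit a fitness-only ensemble,
subtract its out-of-bag predictions from the observed degrees, and fit the
15 remaining features to those residuals.

## Degrees from screens

Negative interactions are called at epsilon ≤ −0.08 with p < 0.05 (strict
variant −0.12), or S-score ≤ −2.5 for screens on that scale.  A passing
record counts toward both pair members; `array_side_only` restricts degrees
to the arrayed genes for fixed-query-panel screens.  Relaxing a cutoff can
only add interactions, so degrees are monotone in the thresholds.

## Rewiring test

Degrees are compared on the percentile scale (midrank, `(rank − 0.5)/n`):
observed-degree percentiles in species 1 versus predicted-degree
percentiles over *all* species-2 genes.  For a module the statistic is
Δ = median₁ − median₂, assessed two-sided via |Δ| against an empirical null
of random ortholog groups: draw as many species-1 genes as the module has
scored members such that exactly the module's number of ortholog-mapped
members map to scored species-2 genes.  Sampling conditional on that count
factorizes into independent uniform draws from the mapped and unmapped
strata, which is how it is implemented (no rejection loop).  Backgrounds
are cached per size pair; `background_samples = 10,000` per key; p-values
use the add-one convention (never exactly 0).  No multiple-testing
correction is applied beyond reporting the expected false-positive count
⌊α·n⌋ — matching the analysis this package reproduces.

GO-derived groups use terms annotated to >3 and <50 genes in the seeding
species, need ≥2 species-1 genes of known degree and ≥2 species-2 genes of
known fitness, and pass a greedy overlap filter (≤50% of either group's
members against every already-kept group), processed largest-first for
determinism.  Protein-complex groups skip the size filter.

A within-species control reruns the identical machinery on (observed,
predicted) percentiles of species 1 with the identity mapping: modules
significant there are systematically mispredicted, and are annotated
`suspect` in the cross-species results rather than trusted as rewiring.

## Co-expression conservation

Both species' weighted co-expression networks are restricted to one-to-one
orthologs non-essential in both species, then sparsified to the top 5% of
pair weights (cutoff at the 95th percentile; ties at the cutoff drop, so
realized density never exceeds the target and the edge set is invariant to
monotone weight transforms).  Ortholog pairs are labeled rewired when
|predicted₂ − observed₁| degree difference exceeds τ ∈ {30, 55, 80, 105},
non-rewired below 30, and unlabeled in between.  Union edges are classified
NN/NR/RR by endpoint labels; the conservation rate is intersection/union
per class with a Wald binomial 95% CI (Wilson available), and RR vs NN is
compared by the two-sided Fisher exact test.  Chance conservation is
estimated by degree-preserving randomization of the species-1 network:
20×|E| *attempted* double-edge swaps (rejected swaps — self-loops or
duplicate edges — consume an attempt; this is the terminating convention,
switchable).

## The synthetic world

The generator emulates the published setting so every stage runs without
downloads; where the source analysis prints a value, the default is
calibrated to it once and frozen:

- 2,000 genes per species, 55% in one-to-one ortholog pairs (~1,100 pairs);
- per-feature Gaussian-copula latents, cross-species correlation 0.2 for
  physiological features (the fitness-defect ortholog correlation), ~0.7–0.9
  for sequence-derived ones; monotone marginal transforms give each feature
  a realistic shape (binomial counts for conservation, lognormal lengths,
  unit-interval percentiles);
- degree ~ negative binomial with mean exp(a₀ + a·z) over the latent
  features, shared coefficients across species (the conserved-rules
  premise), coefficient signs following the observed feature–degree
  correlations and fitness dominant.  Dispersion 8 puts the within-species
  out-of-bag correlation near the published ~0.8 regime (measured ~0.74);
- screens: 8 query strains × all array genes; planted per-gene query
  degrees are realized exactly by construction (interacting pairs get
  epsilon below the cutoff with significant p; near-zero scores that dip
  below the cutoff by chance get non-significant p), so thresholding
  round-trips exactly;
- co-expression: 832 ortholog genes in 20 latent modules; pair scores are
  cross-species-correlated latents plus a same-module boost; the top 5% by
  rank are the planted edges and the weights are rank-normalized so
  percentile sparsification recovers them.  `module_strength = 1.5`,
  `edge_correlation = 0.1` reproduce the published conservation regime
  (overall ≈ 7.5% vs 9.2% printed; non-rewired ≈ 10.2% vs 10.1%).  Planted
  rewired genes have their module membership reassigned in species 2 with
  probability `conservation_deficit = 0.8`, lowering their edge
  conservation;
- group catalogs: random groups over ortholog-mapped genes; under the null
  the paired percentiles are strongly conserved (copula correlation 0.9) —
  the regime in which a median-shift of 0.4 on groups of 8 is detectable —
  and planted rewired groups lower their species-2 percentiles by that
  shift (clipped to [0, 1]).

What a green test does *not* establish: the generator has no real
expression matrices, sequences or colony sizes; features are independent
within a species (real features co-vary); essentiality is a flag on the
fitness tail, not a biological call; and the published headline
correlations (within 0.80, cross 0.51, screen 0.40) depend on the study's
real tables, which are deliberately out of reach here — the synthetic
checks establish that the machinery recovers planted structure at
comparable scale, not the published numbers themselves.

## Numerical conventions

Percentiles are midrank over non-missing values; medians of even counts are
the mean of the middle two; the sparsification cutoff uses the linearly
interpolated quantile with a strictly-above rule; empirical p-values are
add-one; Fisher CIs use the z = 1.96 normal quantile.  All randomness flows
from a single integer seed: the pipeline hashes the stage name into a
per-stage substream, and every generator and fit is reproducible bit for
bit given its seed.

## Known limitations

The degree model does not implement leaf-level linear regressions (constant
leaves are the standard MSE-tree form; the alternative reading of the
source description is noted as switchable-by-design but not built).  The
background sampler requires the requested group sizes to be reachable from
the scored universe and raises otherwise rather than approximating.
Networks are held dense in memory (fine to a few thousand genes; not meant
for genome-scale co-expression matrices beyond that).
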