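# Methods

## Scope and design

`grnimpact` evaluates the effect of scRNA-seq imputation on gene-regulatory
network (GRN) reconstruction under controlled conditions.  Because real
benchmark corpora (GEO expression sets, STRING / ChIP-seq references, the
published imputation and inference tools) are external resources, the
package supplies its own simulator as the source of ground truth and
mechanism-level imputation stand-ins, while remaining read-compatible with
externally produced matrices (genes × cells CSV) and ranked edge lists
(`Gene1  Gene2  EdgeWeight` TSV), which is the intended route for
evaluating the real tools.

## Synthetic data generator

The simulator emulates the statistical structure the evaluation depends
on, not any particular experiment.

**Network.**  Each gene receives Poisson(`edges_per_gene`) regulators
(default 2.0), drawn without replacement from the TFs with probability
proportional to a Pareto(1.5) per-TF propensity; this produces hub TFs and
a heavy-tailed out-degree distribution.  TFs may regulate other TFs.
Degenerate draws are repaired so at least one TF→TF and one TF→target edge
exist.

**Expression.**  TFs follow smooth programs over pseudotime — sigmoid
switches or Gaussian pulses with random midpoints and widths — so that a
smooth additive fit has true positives to find.  A target's log-rate is its
baseline plus `effect_size` (default 2.0) times the sign-weighted,
√in-degree-normalized sum of its regulators' standardized programs; the
exponential link keeps rates positive and monotone in the regulatory
input.  Counts are gamma-Poisson (negative binomial) with shape
1/`dispersion` (default dispersion 0.3), scaled by log-normal per-cell
library factors (σ = 0.35) so depth normalization is non-trivial.
Technical dropout adds zeros with probability exp(−`dropout_strength` ×
mean) (default 0.3), i.e. low-expression entries are preferentially lost.
The latent (noise-free) rate matrix is attached to the dataset for
diagnostics.

Defaults were fixed once for testability — clear regulatory signal, ~50%
zeros, realistic overdispersion — not to match any real dataset's moments.
The generator does not model transcriptional bursting kinetics, batch
effects, cell-cycle structure, or doublets; passing tests therefore speak
to the correctness and calibration of the evaluation machinery and to the
qualitative behaviour of smoothing on dropout-type noise, not to
performance on real tissue.

**Downsampling.**  The low-quality stress test replaces each count with a
Binomial(count, fraction) draw (default fraction 0.6), which thins the
total depth to the fraction in expectation and never increases an entry.

## Preprocessing

Normalization scales each cell to the median library size and applies
log1p; all-zero cells are rejected.  "Variable across pseudotime" is
operationalized as the deviance explained by an unpenalized cubic
regression spline of expression on pseudotime (six quantile knots,
intercept included, one basis column dropped for identifiability), with
significance from the exact F test against the intercept-only model.  An
unpenalized spline was chosen over a penalized (GCV-ridge) smooth because
the F test is then exactly calibrated: null p-values are uniform (KS
p = 0.41 on 2000 white-noise genes in the test suite) and the Bonferroni
family-wise error over TFs stays at its nominal bound.  The gene universe
is the union of the top-N genes by deviance explained (N = 500 in typical
use; smaller in the desk-scale tests) and the TFs with Bonferroni-corrected
p < 0.01 (correction over the TF family only).  The identical universe is
applied to every imputation layer of a dataset.

## Imputation operators

Three mechanism families, deliberately named by mechanism rather than
after published tools, each on its native substrate:

- **Neighbor aggregation** (raw counts): stepwise doubling schedule; at
  step s each cell pools raw counts with its min(2^s, k) nearest
  neighbors, distances taken on median-depth-scaled, square-root
  (variance-stabilized) partial aggregates; output rescaled to original
  depth.  k = 0 is the identity.
- **Graph diffusion** (normalized layer): adaptive Gaussian kernel on the
  top principal components (bandwidth = distance to the knn-th neighbor),
  symmetrized and row-normalized into a Markov matrix M; expression is
  propagated t steps (default knn 15, t 3).  t = 0 is the identity; large
  t collapses every gene to its stationary-weighted mean.
- **Rate shrinkage** (raw counts): counts are modelled as Poisson(size
  factor × rate) with a gamma prior centered on a cross-gene ridge
  prediction of each gene from all others; the posterior-mean rate
  (count + a·μ)/(s + a) interpolates between normalized raw counts (a → 0)
  and the predictions (a → ∞).  Default prior strength 1.

The identity operator (`noimp`) is the mandatory baseline; log2 ratios are
always taken against it.  None of the stand-ins claims numerical
equivalence to any released tool — externally imputed matrices are the
fidelity route and pass the same shape/identity validation.

## Network inference

Four scoring families over TF → gene candidates, all emitting
competition-ranked edge lists (ties share the smallest rank of their
block):

- **Random-forest importance**: per-target forest on all TF expressions
  (the target excluded from its own predictors); weight = impurity
  importance × target variance, so per-target scores pool into one global
  ranking without letting high-variance hubs be forced.
- **Gradient-boosted importance**: same contract, boosted trees with early
  stopping on a held-out fold.
- **Mutual information with context normalization**: equal-frequency
  discretization (8 bins), pairwise MI in bits, weight = mean of the two
  endpoint z-scores of that MI within each endpoint's own MI distribution.
  This is a surrogate for partial-information-decomposition scoring, which
  is out of scope; genuine output from such tools can be imported.
- **Regularized partial correlation**: Ledoit-Wolf precision matrix,
  weight = |pcor|, kept only strictly above an absolute threshold
  (default 0.1).

Undirected families emit each kept pair as two opposing directed records
sharing one rank.  Tree methods are seeded per target so results are
reproducible.

## Evaluation

Harmonization restricts prediction and reference to the selection
universe, expands undirected edges, drops self-loops and non-TF-sourced
edges (which also implements the "bidirectional pairs count once unless
TF↔TF" convention), and recomputes competition ranks from the surviving
weights — closing the rank gaps left by filtered edges so the top-k cut
still selects ~k edges; a collapsed duplicate keeps its larger weight and
hence its better rank.  k defaults to the positive-edge count of the
harmonized reference.  EP uses the *reported* top-k size as denominator
(ties can push it above k).  Density uses
numEdges/((numGenes × numTFs) − numTFs); the −numTFs term encodes that
self-edges are outside the universe, and predicted self-loops are dropped
accordingly.  The EPR of a uniformly random ranking is 1 in expectation by
construction; the test suite verifies this to Monte-Carlo error and
verifies by brute force on ≤5-node toys that 1/density is the attainable
maximum.

## Structure and motif analyses

Model similarity is the Jaccard index of top-500 edge sets (both-empty
pairs defined as 1, flagged); models are clustered by average-linkage
agglomeration on 1 − Jaccard, and cluster purity against the imputation or
method annotation is scored with the adjusted Rand index.  The variance
decomposition compares, per dataset, the variance of log2 EPR ratios
across imputations (method fixed) with the converse, via a two-sided
Wilcoxon rank-sum test, plus a per-dataset two-way ANOVA on the ratios
with sequential (type-I) sums of squares in the order (method,
imputation); because the grid is balanced the order is immaterial in
practice, and the noimp rows (ratio ≡ 0) are excluded from the
decomposition.

The correlation-class analysis takes each imputed model's own top-k
TP/FP/FN classes, computes each classified edge's absolute Pearson
correlation on the pre- and post-imputation layers, and fits one OLS line
per class; absolute values are used on both axes because per-class lines
are ill-defined under anti-correlation (a signed-after variant would be a
trivial extension).  Edges touching a constant gene are excluded and
reported.  Rank shifts report, for each baseline true positive, its rank
in an imputed model's full ranking, with missing edges assigned
universe + 1 and flagged.

Motif analysis enumerates ordered triples X→Y→Z: a *chain* lacks the
shortcut X→Z, a *feed-forward loop* has it.  Against the reference,
predicted chains that are reference chains are TP, predicted chains that
are reference loops are FP, predicted loops that are reference chains are
FN; TPR = TP/(TP+FN), FDR = FP/(TP+FP).  Triples whose backbone is absent
from the reference are unclassifiable and reported as a fourth count
rather than folded into FP (which would bias FDR upward); zero-denominator
rates are reported as missing, never as 0.

## Orchestration and reproducibility

`run_experiment` executes the full (datasets × imputations × methods)
grid, persists every intermediate as plain text, and derives each cell's
seed as CRC32(master seed, dataset, imputation, method), so adding a cell
never perturbs another.  Failed cells are recorded in `failures.csv` and
skipped, never silently dropped.  `report` regenerates all summary tables
from the persisted artifacts alone and is idempotent.  Reruns with the
same configuration are byte-identical.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is statistically decidable: 1000
Monte-Carlo replicates for the random-predictor calibration (3-standard-
error band), 60–100 genes × 150–200 cells for simulation-based checks,
20 seeds for the sign tests on correlation inflation, 200 synthetic grids
for the ANOVA factor-recovery check, and ≥10⁶ total counts for the
downsampling depth ratio (±1 percentage point).  Ties in gene selection
break lexicographically; ties in edge weights share competition ranks;
near-constant genes collapse to one discretization bin and score zero MI
by convention.

## Known limitations

- The imputation operators are qualitative stand-ins; conclusions about a
  specific published tool require importing that tool's output.
- The MI scorer is a context-normalized surrogate, not a partial-
  information decomposition.
- The simulator's single pseudotime axis induces stronger background
  gene-gene correlation than typical real data; absolute correlation
  levels are therefore not comparable to real tissues, only contrasts
  (edges vs non-edges, before vs after imputation) are meaningful.
- No AUROC/AUPRC: evaluation is early-precision only, by design.
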