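# Methods

This note documents the models and procedures implemented in `protect`, the
choices made where the design was genuinely open, and what the synthetic
test-bed does and does not demonstrate.

## Problem and model

Given a cell-type's enhancer annotations, gene TSSs, TAD boundaries, per-TF
ChIP-seq peak sets, a weighted PPI network, and a gold standard of significant
chromatin loops, the package learns to classify enhancer-promoter (E-P)
pairs as interacting or not, and then scores all candidate pairs genome-wide.
The core hypothesis is mechanistic: a loop between an enhancer and a promoter
is stabilized by a physical protein-protein interaction between a TF bound at
the enhancer and a TF bound at the promoter.  The feature set therefore
consists of directional TF-PPI indicators ("TFa bound in the enhancer AND TFb
bound in the promoter AND TFa-TFb is a PPI"), aggregated to network-module
level, alongside enhancer activity, gene expression, their cross-cell-type
correlation, and the raw genomic distance.

## Pipeline stages

### Input model (`genome_io`)

All coordinates are 0-based half-open.  Promoters are symmetric TSS +/- 1 kb
windows, clipped at the chromosome start and not strand-shifted.  Overlap
always means >= 1 bp intersection.  PPI edges are retained when their
confidence score is strictly greater than the threshold (default 100,
STRING-"Experiments"-like scale); edges whose two endpoints belong to the
same excluded dimerizing family (NR, bHLH, bZIP by default) are removed,
because intratypic dimers co-bind locally rather than bridging distal
elements.  Duplicate edges collapse keeping the maximum score.

### Training set (`training_set`)

Positives are intra-TAD E-P pairs whose enhancer overlaps one anchor of a
gold-standard loop and whose promoter overlaps the other anchor (cross-TAD
matches are dropped; loop quality degrades across TAD boundaries).  Negatives
control three confounders:

1. intra-TAD only;
2. per 50-kb distance bin, exactly as many negatives as positives, drawn
   uniformly without replacement (distance is enhancer midpoint to TSS);
3. negatives restricted to genes with nonzero expression (RPKM > 0) in the
   cell-type, reflecting the lower false-negative rate of contact assays in
   active chromatin.  Positives are not expression-filtered.

When a bin lacks candidates the sampler takes all available and logs the
deficit; `strict_balance` optionally drops excess positives to restore exact
per-bin balance.

### PPI modules (`ppi_modules`)

The walk runs on the full network including non-TF proteins (they mediate
indirect TF-TF connectivity).  With weighted adjacency `W` and degrees
`D_ii = sum_j W_ij`, the p-step transition matrix is `T = (D^-1 W)^p`
(default p = 20, computed by repeated multiplication), `G = T T^t`, and the
TF-TF distance is `R_ij = G_ii + G_jj - 2 G_ij` — the squared Euclidean
distance between p-step visiting profiles.  Isolated nodes cannot host a walk
and get singleton modules.

Ward linkage on `R` gives a dendrogram; every level is a candidate cut whose
"maximum module size" is its largest cluster.  Weighted Newman modularity
`Q = (1/2m) sum_ij (W_ij - k_i k_j / 2m) delta(c_i, c_j)` — evaluated on the
TF subgraph, the graph whose nodes were clustered — scores each cut.  The
S-module cut maximizes Q (ties toward smaller size, then the finer cut); the
L-module cut is the elbow (maximum perpendicular distance to the chord,
first index on ties) of the Q-vs-size curve over cuts at or above the S cut,
so S-modules nest inside L-modules by construction.

The feature catalog has one un-directional intra-module feature per S/L
module containing an internal TF-TF PPI, and two directional inter-module
features per module pair bridged by a PPI.  Each feature records its
constituent ordered TF pairs.

### Features (`feature_matrix`)

TF-level indicators are binary; module-level values take the maximum over
constituents (a logical OR for binaries), so module positivity never loses a
TF-level hit.  Activity correlation is Pearson's r across the shared
cell-type panel (>= 3 cell-types required); degenerate series yield 0 with a
warning.  Distance enters untransformed — it is distance-matched between
classes at training, so only residual within-bin effects remain for the model
to absorb.

### Classifier and feature selection (`predictor`)

A random forest (default 500 trees, seeded, single-threaded) is the
classifier.  Backward elimination recursively drops the least-important
module-level feature (activity/distance columns are exempt) and returns the
smallest feature set whose bin-split CV AUC is within `tolerance` (default
0.005) of the best seen.

Directional merging asks, independently for each (a->b, b->a) feature pair
and against the otherwise-full model, whether replacing the two columns with
their elementwise maximum lowers a relaxed AIC:

    AIC = -2 l_m + 2 GDF + GDF (GDF + 1) / (N - GDF - 1)

GDF (generalized degrees of freedom) is estimated by flipping the labels of a
random 20% of rows, refitting, and summing `(yhat'_i - yhat_i)/(y'_i - y_i)`
over the perturbed rows; the estimate averages 10 draws by default, with the
same draws used for both variants so the comparison is paired.  Fitted values
are forest probabilities; a label-independent predictor has GDF 0 and a
label-memorizer has GDF equal to the number of perturbed rows.

`l_m` is the out-of-fold Bernoulli log-likelihood summed over the five CV
folds, with forest probabilities Laplace-smoothed (`(pT + 0.5)/(T + 1)`).
A goodness-of-fit bounded in [0, 1] (such as a squared correlation, available
via `goodness="r2"`) cannot be commensurable with a GDF of order N/10: the
decision would then be driven entirely by GDF estimation noise and by the
fact that a worse-fitting model responds less to label flips, which
systematically (and wrongly) favors merging.  The log-likelihood scale makes
fit differences and complexity differences comparable, and with it the
procedure recovers planted directional asymmetry while merging planted
symmetric pairs (the acceptance suite measures both rates).

### Evaluation (`evaluation`)

Cross-validation splits consecutive 1-Mb genomic bins — not samples — into
five folds; a pair is used only in the fold owning both its enhancer's and
its promoter's bin, and fold-straddling pairs are dropped with a count.  This
removes the leakage between spatially proximal pairs that inflates randomly
split CV.  Pooled held-out AUC is the headline; per-fold values are kept.
Cumulative odds-ratio curves down the ranked predictions use the
Haldane-Anscombe +0.5 correction whenever a contingency cell is zero.  The
PPI ablation rewires the network by degree-preserving double edge swaps
(default 10x the edge count, weights travel with edges, optional restriction
to TF-TF edges) and re-runs the entire pipeline.

### Genome-wide calling (`genomewide`)

All same-chromosome pairs with midpoint-TSS distance strictly below 2 Mb are
scored (no TAD restriction).  The null distribution permutes every feature
column independently across pairs — preserving each feature's marginal
abundance — and p-values use the add-one right-tail estimator with ties
counted as exceedances.  Distance-aware q-values follow the pFDR estimator

    q(P) = inf_{gamma >= P} pi_i * gamma / Pr_hat(P <= gamma)

with the empirical `Pr_hat` over all candidates, the infimum over observed
p-values, a cumulative-minimum pass enforcing within-bin monotonicity, and
priors per 20-kb bin: the first populated bin gets 0.05, bin i gets
`0.05 * count_i / count_1` capped at 1, where counts are gold-standard loops
per bin.  Empty bins get the maximally conservative prior 1 — because the
prior multiplies the q-value, a small prior would make distances never seen
among gold loops the easiest to call, inverting the intent.  Significance is
q <= 0.05 inclusive.

Two structural properties of this estimator deserve emphasis.  First, it is
only meaningful when the gold-standard loop distance distribution has a
rising short-range front (as real loop calls do — ultra-short loops are not
callable), so that `count_1` is small relative to mid-range bins and most
priors are large.  Second, any populated bin whose count does not exceed
`count_1` has `pi_i <= 0.05`, and every candidate in it is called regardless
of its p-value; the estimator is therefore not a calibrated FDR estimator in
sparse-tail bins, and the null-calibration acceptance check documents the
resulting empirical FDR honestly (see the decisions in the test suite).

### Interpretation and enrichment (`interpretation`)

Module-level importance is decoded to TF level by abundance: the fraction of
significant predictions whose indicator for the ordered TF pair is 1 (top 5
per module feature by default, lexicographic tie-break).  Per-feature gene
sets keep significant predictions carrying one of the feature's top TF pairs,
sort by q-value, and collect distinct genes (up to 1000).  cis-eQTL support
means the SNP lies in the enhancer and the eQTL gene matches; enrichment is
compared against random re-pairings within 2 Mb and against 50-kb
distance-matched re-pairings (1000 samples each, add-one empirical p).
SNP-to-summit distances are normalized by peak length and compared between
prioritized-TF peaks and background peaks by two-sample KS.  Trans analysis
emits (TF, gene) pairs mediated by prioritized features with the TF on the
enhancer side, removes genes whose own promoter the TF binds, intersects
with trans-eQTLs whose SNP lies in the TF gene body extended 10 kb upstream
of the TSS (strand-aware), and tests enrichment hypergeometrically with
population = prioritized TFs x testable genes, against nearest-gene and
random-gene-within-2-Mb controls.

## Synthetic test-bed (`synthetic_fixtures`)

The generator produces the study conditions used throughout the tests; all
randomness flows from one seed through named substreams, so adding a step
never perturbs earlier draws.  Defaults: 2 chromosomes of 10 Mb tiled by five
2-Mb TADs; 200 enhancers of 1 kb and 100 genes placed uniformly within TADs;
24 TFs and 12 non-TF proteins in a stochastic block model with 4 planted
modules (within/between edge probability 0.9/0.05, weights uniform on
(100, 1000]); each enhancer and promoter receives each TF's peak
independently with probability 0.2; 12 pseudo cell-types with log-normal
activity and expression.

Physical contacts follow
`expit(logit(base * 2^(-d/halflife)) + log(multiplier) * causal)` with base
0.15, half-life 250 kb and multiplier 20, where `causal` means some planted
causal PPI (TFa, TFb) has TFa bound in the enhancer and TFb in the promoter.
A contact is emitted as a called loop with probability `1 - 2^(-d/100kb)`,
emulating the inability of loop callers to call ultra-short-range loops; this
gives the loop set the rising-then-decaying distance profile the pFDR priors
require.  Contacted pairs receive weakly correlated activity/expression
(rho = 0.05 on the log scale) — calibrated to the observation that
activity-based features alone are only mildly predictive of loops — injected
after contacts are drawn, since the correlated pairs are only known then.

What the generator does not emulate: sequence, peak-width variation and
summit offsets within elements, correlated TF binding (every TF binds
independently), non-TF protein expression variation, cross-TAD loops, and
Hi-C count noise.  Two consequences matter for interpreting green tests.
First, because TF binding is independent across TFs, constituents of one
module feature are conditionally exchangeable given the module indicator, so
TF-level abundance decoding can separate the causal pair from its
module-mates only through the truly-contacted fraction of the calls; recovery
rates measured by the acceptance suite are bounded by call precision in a way
that real data (with correlated binding) may not be.  Second, planted-module
recovery on a clean SBM is easier than on a real PPI network.

## Numerical choices

- Transition rows sum to 1 within 1e-12; `R` is symmetrized, its diagonal
  zeroed, and negative entries (magnitude < 1e-10) clipped to 0.
- Modularity ties during cut selection are broken after rounding Q to 12
  decimals, toward smaller maximum size, then toward the finer cut.
- Pearson correlations with zero variance in either series are set to 0.
- The GDF plugged into the AIC penalty is clipped to [0, N-2] so the
  denominator stays positive.
- Score ties in ranked lists keep stable input order; abundance ties break
  lexicographically; q-value ties in gene collection break by gene id.
- Degenerate inputs raise: empty contact sets for priors, single-class
  labels, fewer than 2 TFs for clustering, empty KS samples.

## Problem sizes used by the tests

The acceptance suite runs the ablation on a 4-chromosome fixture yielding
more than 4000 labeled pairs, null calibration on roughly 8000 genome-wide
candidates, module recovery on a 48-TF SBM, and the interpretation
recoveries over 20 seeded pipeline runs (one planted causal PPI each) plus
20 + 20 merge fixtures of 600 rows; the whole suite and the acceptance
script each finish in minutes on one CPU.
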