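# protect

Cell-type-specific prediction of long-range enhancer-promoter interactions
from protein-protein interactions (PPIs) between transcription factors.

## The problem

Enhancers regulate genes across hundreds of kilobases through chromatin
loops, and which enhancer talks to which promoter differs between
cell-types.  Activity-based predictors (enhancer signal, gene expression,
their correlation across cell-types) capture surprisingly little of this
once the dominant confounders — genomic distance, TAD structure, expression
level — are controlled.  This package implements a supervised predictor
built on a mechanistic feature family instead: a loop is favored when a TF
bound at the enhancer physically interacts with a TF bound at the promoter.
For an enhancer-promoter pair, the directional feature TFa-TFb is 1 when
TFa has a ChIP-seq peak in the enhancer, TFb has one in the promoter
(TSS +/- 1 kb), and TFa-TFb is a high-confidence PPI.

The pipeline:

1. **Confounder-controlled training set.**  Positives are intra-TAD pairs
   matching the two anchors of significant chromatin loops (Hi-C-like BEDPE);
   negatives are sampled per 50-kb distance bin to match the positive
   distance distribution exactly, restricted to intra-TAD pairs of expressed
   genes (RPKM > 0).
2. **Graph-based dimension reduction.**  The thousands of TF-level PPI
   features are grouped by community detection on the PPI network: with
   transition matrix `T = (D^-1 W)^p` (p = 20), TF pairwise distances
   `R = diag(G) 1^t + 1 diag(G)^t - 2G`, `G = T T^t`, are Ward-clustered;
   dendrogram cuts are scored by modularity
   `Q = (1/2m) sum_ij (W_ij - k_i k_j/2m) delta(c_i, c_j)`.  The Q-maximizing
   cut defines small S-modules (protein complexes), the elbow of the Q curve
   defines large L-modules, and features aggregate to module level (max over
   constituents).
3. **Random forest + feature selection.**  Backward elimination of
   module-level features, and a relaxed-AIC test
   `AIC = -2 l_m + 2 GDF + GDF(GDF+1)/(N-GDF-1)` — with GDF estimated by
   perturbing 20% of labels — decides for each directional feature pair
   (module_a -> module_b vs module_b -> module_a) whether the direction
   carries signal or the pair should merge.
4. **Leakage-free evaluation.**  Cross-validation splits 1-Mb genomic bins,
   not samples, so spatially proximal pairs never span train and test; a
   degree-preserving PPI shuffle quantifies how much accuracy the PPI
   features themselves contribute.
5. **Genome-wide calling.**  All pairs within 2 Mb are scored; p-values come
   from a column-permutation null, and q-values from a distance-aware pFDR
   with priors proportional to loop frequency per 20-kb distance bin
   (pi_1 = 0.05).  Calls are q <= 0.05.
6. **Interpretation.**  Module-level importance is decoded to ranked TF-level
   PPIs by abundance among the calls, and predictions are validated against
   cis-eQTLs (distance-matched controls), SNP-to-peak-summit distances (KS
   test), and trans-eQTLs over enhancer-mediated TF-gene pairs
   (hypergeometric test).

A fully seeded synthetic-data generator (`protect.synthetic_fixtures`)
produces a toy genome, a planted-module PPI network, and loops whose odds
are multiplied when a planted "causal" TF PPI bridges the pair — so every
stage is testable against known ground truth without downloads.

## Worked example

```python
from protect.synthetic_fixtures import SimulationConfig, simulate_dataset
from protect.training_set import make_training_table
from protect.ppi_modules import detect_modules
from protect.feature_matrix import build_feature_matrix
from protect.evaluation import make_bin_split, cross_validate
from protect.predictor import fit
from protect.genomewide import enumerate_candidates, genome_wide_predict

config = SimulationConfig(seed=1, n_chroms=2, n_enhancers=700, n_genes=300)
data = simulate_dataset(config)
print(f"called loops: {len(data.contacts)}   planted causal PPIs: {len(data.truth.causal_ppis)}")

table = make_training_table(data.genome, data.contacts,
                            data.genome.expression, "CT00", seed=1)
print(f"training pairs: {len(table)} ({int((table.label == 1).sum())} positive)")

assignment, catalog = detect_modules(data.network)
print(f"S_max={assignment.S_max}  L_max={assignment.L_max}  "
      f"module-level features: {len(catalog.features)}")

X, tf_matrix = build_feature_matrix(table, data.genome, data.network, catalog, "CT00")
print(f"feature matrix: {X.shape[0]} x {X.shape[1]} "
      f"(TF-level PPI columns before reduction: {tf_matrix.shape[1]})")

split = make_bin_split(table, data.genome, seed=1)
cv = cross_validate(X, table["label"].to_numpy(), split, n_trees=200, seed=1)
print(f"bin-split CV AUC: {cv.pooled_auc:.3f}")

bundle = fit(X, table["label"].to_numpy(), n_trees=200, seed=1)
candidates = enumerate_candidates(data.genome)
Xc, _ = build_feature_matrix(candidates, data.genome, data.network, catalog, "CT00")
preds = genome_wide_predict(candidates, Xc, bundle, data.contacts, n_null=10_000, seed=1)
sig = preds[preds["significant"]]
print(f"genome-wide: {len(sig)} significant of {len(preds)} candidates "
      f"(median call distance {sig.distance_bp.median()/1000:.0f} kb)")
```

Output:

```
called loops: 1695   planted causal PPIs: 4
training pairs: 3962 (1981 positive)
S_max=6  L_max=12  module-level features: 25
feature matrix: 3962 x 29 (TF-level PPI columns before reduction: 138)
bin-split CV AUC: 0.657
genome-wide: 14392 significant of 37407 candidates (median call distance 1193 kb)
```

Reading the numbers: 1695 gold-standard loops give a balanced table of 3962
labeled pairs whose distance histograms match per 50-kb bin.  The 138
directional TF-level PPI columns collapse to 25 module-level features (4
activity/distance columns + 25 = 29).  Held-out AUC of 0.657 under the
strict genomic-bin split is what the PPI features buy on this fixture —
the activity-only baseline sits near chance here, since distance and
expression are controlled by design.  Genome-wide, the distance-aware pFDR
calls 14392 of 37407 candidate pairs at q <= 0.05.

The same pipeline is scriptable from a shell:

```
protect simulate --config sim.json --out-dir fixtures/
protect make-training --genome-dir fixtures/ --contacts fixtures/contacts.bedpe \
    --cell-type CT00 --seed 1 --out pairs.tsv
protect modules --ppi fixtures/ppi_edges.tsv --genome-dir fixtures/ --out modules.json
protect train --genome-dir fixtures/ --contacts fixtures/contacts.bedpe \
    --ppi fixtures/ppi_edges.tsv --cell-type CT00 --seed 1 \
    --model-out model.bundle --report cv.json
protect predict --genome-dir fixtures/ --contacts fixtures/contacts.bedpe \
    --ppi fixtures/ppi_edges.tsv --cell-type CT00 --model model.bundle \
    --seed 1 --out predictions.tsv
```

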