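"""Leakage-free genomic-bin-split cross-validation and evaluation statistics.

Random per-sample CV splits leak information between spatially proximal
enhancer-promoter pairs, whose TF-binding profiles are strongly correlated.
The bin split instead partitions consecutive 1 Mb genomic bins into folds;
a pair is tested only in the fold owning both its enhancer's and its
promoter's bin, so no bin ever feeds both training and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .genome_io import GenomeAnnotation, PPINetwork
from .predictor import fit, predict_scores

logger = logging.getLogger(__name__)

DEFAULT_CV_BIN_SIZE = 1_000_000


@dataclass
class BinSplit:
    """Fold assignment of genomic bins and of the pairs they contain."""

    bin_size_bp: int
    k: int
    seed: int
    fold_of_bin: dict[tuple[str, int], int]
    fold_of_pair: pd.Series  # pair index -> fold; straddling pairs absent
    n_dropped_straddling: int = 0

    def split(self, features: pd.DataFrame, labels=None):
        """Yield (train_positions, test_positions) per fold, sklearn-style."""
        index = features.index
        folds = self.fold_of_pair.reindex(index)
        positions = np.arange(len(index))
        for f in range(self.k):
            test = positions[(folds == f).to_numpy()]
            train = positions[(folds != f) & folds.notna()]
            if len(test) and len(train):
                yield train, test


def make_bin_split(
    pairs: pd.DataFrame,
    genome: GenomeAnnotation,
    bin_size_bp: int = DEFAULT_CV_BIN_SIZE,
    k: int = 5,
    seed: int = 0,
) -> BinSplit:
    """Assign genomic bins to folds and derive each pair's fold.

    Bins are partitioned exhaustively into ``k`` folds uniformly at random.
    A pair whose enhancer bin and promoter bin land in different folds is
    dropped (counted), enforcing zero leakage.
    """
    enh_bin = {}
    prom_bin = {}
    for eid in pairs["enhancer_id"].unique():
        e = genome.enhancer_by_id(eid)
        enh_bin[eid] = (e.chrom, e.midpoint // bin_size_bp)
    for gid in pairs["gene_id"].unique():
        g = genome.gene_by_id(gid)
        prom_bin[gid] = (g.chrom, g.tss // bin_size_bp)
    bins = sorted(set(enh_bin.values()) | set(prom_bin.values()))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bins))
    fold_of_bin = {bins[j]: int(i % k) for i, j in enumerate(order)}

    fold_vals = {}
    n_dropped = 0
    for idx, row in pairs.iterrows():
        fe = fold_of_bin[enh_bin[row["enhancer_id"]]]
        fp = fold_of_bin[prom_bin[row["gene_id"]]]
        if fe == fp:
            fold_vals[idx] = fe
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("make_bin_split: dropped %d fold-straddling pairs", n_dropped)
    return BinSplit(
        bin_size_bp=bin_size_bp, k=k, seed=seed, fold_of_bin=fold_of_bin,
        fold_of_pair=pd.Series(fold_vals, dtype=float),
        n_dropped_straddling=n_dropped,
    )


@dataclass
class CVResult:
    pooled_auc: float
    pooled_auprc: float
    fold_aucs: list[float]
    scores: pd.Series       # held-out score per retained pair
    labels: pd.Series
    n_dropped: int = 0
    skipped_folds: list[int] = field(default_factory=list)


def cross_validate(
    features: pd.DataFrame,
    labels,
    split: BinSplit,
    n_trees: int = 100,
    seed: int = 0,
) -> CVResult:
    """Refit per fold on training bins only; report pooled and per-fold AUC."""
    y = pd.Series(np.asarray(labels), index=features.index)
    all_scores: dict = {}
    fold_aucs = []
    skipped = []
    for f, (train, test) in enumerate(split.split(features)):
        y_tr = y.iloc[train]
        y_te = y.iloc[test]
        if y_tr.nunique() < 2 or y_te.nunique() < 2:
            logger.warning("cross_validate: fold %d has a single class; skipped", f)
            skipped.append(f)
            continue
        bundle = fit(features.iloc[train], y_tr.to_numpy(), n_trees=n_trees, seed=seed)
        scores = predict_scores(bundle, features.iloc[test])
        fold_aucs.append(float(roc_auc_score(y_te, scores)))
        for idx, s in zip(features.index[test], scores):
            all_scores[idx] = s
    held = pd.Series(all_scores)
    y_held = y.loc[held.index]
    pooled_auc = float(roc_auc_score(y_held, held)) if y_held.nunique() > 1 else float("nan")
    pooled_pr = float(average_precision_score(y_held, held)) if y_held.nunique() > 1 else float("nan")
    return CVResult(
        pooled_auc=pooled_auc, pooled_auprc=pooled_pr, fold_aucs=fold_aucs,
        scores=held, labels=y_held, n_dropped=split.n_dropped_straddling,
        skipped_folds=skipped,
    )


def cumulative_odds_ratio_curve(scores, labels) -> list[tuple[int, float]]:
    """Cumulative odds ratio of true positives down the ranked prediction list.

    At each rank k: ``OR_k = (TP_k * TN_rest) / (FP_k * FN_rest)``; when any
    cell is zero all four receive the Haldane-Anscombe +0.5 correction.  Score
    ties keep stable input order.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    curve = []
    tp = 0
    for k in range(1, len(y) + 1):
        tp += int(y_sorted[k - 1])
        fp = k - tp
        fn = n_pos - tp
        tn = n_neg - fp
        cells = [tp, fp, fn, tn]
        if min(cells) == 0:
            cells = [c + 0.5 for c in cells]
        tp_c, fp_c, fn_c, tn_c = cells
        curve.append((k, (tp_c * tn_c) / (fp_c * fn_c)))
    return curve


def shuffle_ppi_degree_preserving(
    network: PPINetwork,
    n_swaps: int | None = None,
    seed: int = 0,
    nodes: list[str] | None = None,
) -> PPINetwork:
    """Degree-preserving double-edge-swap null of the PPI network.

    Repeatedly pick two edges (u,v),(x,y) and rewire to (u,x),(v,y) when that
    introduces neither a self-loop nor a multi-edge; weights travel with the
    rewired edges.  With ``nodes`` given, only edges internal to that node set
    are swapped (e.g. TF-TF connections only).  The degree sequence and the
    edge count are exactly preserved.
    """
    graph = network.graph.copy()
    swappable = [
        (u, v) for u, v in graph.edges
        if nodes is None or (u in set(nodes) and v in set(nodes))
    ]
    if len(swappable) < 2:
        return PPINetwork(graph=graph, excluded_families=network.excluded_families)
    if n_swaps is None:
        n_swaps = 10 * len(swappable)
    rng = np.random.default_rng(seed)
    edge_list = list(swappable)
    accepted = 0
    attempts = 0
    max_attempts = 100 * max(n_swaps, 1)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(len(edge_list), size=2)
        if i == j:
            continue
        u, v = edge_list[int(i)]
        x, y = edge_list[int(j)]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u, x), (v, y)
        if len({u, v, x, y}) < 4:
            continue
        if graph.has_edge(u, x) or graph.has_edge(v, y):
            continue
        w_uv = graph[u][v]["weight"]
        w_xy = graph[x][y]["weight"]
        graph.remove_edge(u, v)
        graph.remove_edge(x, y)
        graph.add_edge(u, x, weight=w_uv)
        graph.add_edge(v, y, weight=w_xy)
        edge_list[int(i)] = (u, x)
        edge_list[int(j)] = (v, y)
        accepted += 1
    if accepted < n_swaps:
        logger.warning("shuffle: only %d/%d swaps accepted", accepted, n_swaps)
    return PPINetwork(graph=graph, excluded_families=network.excluded_families)
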