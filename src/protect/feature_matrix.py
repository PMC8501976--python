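"""Per-pair feature assembly: activity, distance, and module-level PPI features.

Column order is fixed: the activity triple, the raw genomic distance, then
module-level features in catalog order.  TF-level PPI indicators are binary;
module aggregation takes the maximum over constituents, which for binary
indicators is a logical OR, so module-level positivity is never lost.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome_io import GenomeAnnotation, PPINetwork
from .ppi_modules import ModuleFeatureCatalog

logger = logging.getLogger(__name__)

ACTIVITY_COLUMNS = ["enhancer_activity", "gene_expression", "activity_correlation"]
BASE_COLUMNS = ACTIVITY_COLUMNS + ["distance_bp"]


def activity_features(
    pairs: pd.DataFrame,
    activity: pd.DataFrame,
    expression: pd.DataFrame,
    cell_type: str,
) -> pd.DataFrame:
    """Cell-type activity, expression, and cross-panel activity correlation.

    The correlation is Pearson's r between the enhancer's activity vector and
    the gene's expression vector across the shared cell-type panel; a
    degenerate (constant or missing) series yields 0 with a warning.
    """
    shared = [c for c in activity.columns if c in expression.columns]
    if len(shared) < 3:
        raise ValueError(f"shared cell-type panel too small ({len(shared)} < 3)")
    if cell_type not in shared:
        raise ValueError(f"cell type {cell_type!r} absent from both tables")

    missing_e = set(pairs["enhancer_id"]) - set(activity.index)
    missing_g = set(pairs["gene_id"]) - set(expression.index)
    if missing_e or missing_g:
        raise KeyError(
            f"rows missing from tables: enhancers {sorted(missing_e)[:3]}, "
            f"genes {sorted(missing_g)[:3]}"
        )

    act_panel = activity.loc[pairs["enhancer_id"], shared].to_numpy(dtype=float)
    expr_panel = expression.loc[pairs["gene_id"], shared].to_numpy(dtype=float)
    a = act_panel - act_panel.mean(axis=1, keepdims=True)
    e = expr_panel - expr_panel.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (e**2).sum(axis=1))
    corr = np.zeros(len(pairs))
    ok = denom > 0
    corr[ok] = (a * e).sum(axis=1)[ok] / denom[ok]
    if (~ok).any():
        logger.warning("activity_features: %d degenerate correlations set to 0",
                       int((~ok).sum()))
    return pd.DataFrame(
        {
            "enhancer_activity": activity.loc[pairs["enhancer_id"], cell_type].to_numpy(),
            "gene_expression": expression.loc[pairs["gene_id"], cell_type].to_numpy(),
            "activity_correlation": corr,
        },
        index=pairs.index,
    )


def _binding_tables(
    pairs: pd.DataFrame, genome: GenomeAnnotation, tfs: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean (pair x TF) tables: TF bound in enhancer / bound in promoter."""
    enh_ids = pairs["enhancer_id"].unique()
    gene_ids = pairs["gene_id"].unique()
    from .genome_io import overlap_any

    bound_e = pd.DataFrame(False, index=enh_ids, columns=tfs)
    bound_p = pd.DataFrame(False, index=gene_ids, columns=tfs)
    enh_by_id = {eid: genome.enhancer_by_id(eid) for eid in enh_ids}
    prom_by_id = {gid: genome.gene_by_id(gid).promoter for gid in gene_ids}
    chroms = sorted({iv.chrom for iv in enh_by_id.values()}
                    | {iv.chrom for iv in prom_by_id.values()})
    for tf in tfs:
        peaks = genome.peaks.get(tf)
        if peaks is None:
            continue
        for c in chroms:
            pk_s = np.array([p.start for p in peaks.peaks if p.chrom == c])
            pk_e = np.array([p.end for p in peaks.peaks if p.chrom == c])
            eids = [eid for eid, iv in enh_by_id.items() if iv.chrom == c]
            if eids:
                hits = overlap_any([enh_by_id[i].start for i in eids],
                                   [enh_by_id[i].end for i in eids], pk_s, pk_e)
                bound_e.loc[eids, tf] = hits
            gids = [gid for gid, iv in prom_by_id.items() if iv.chrom == c]
            if gids:
                hits = overlap_any([prom_by_id[i].start for i in gids],
                                   [prom_by_id[i].end for i in gids], pk_s, pk_e)
                bound_p.loc[gids, tf] = hits
    return (
        bound_e.loc[pairs["enhancer_id"]].set_index(pairs.index),
        bound_p.loc[pairs["gene_id"]].set_index(pairs.index),
    )


def tf_ppi_indicators(
    pairs: pd.DataFrame, genome: GenomeAnnotation, network: PPINetwork
) -> pd.DataFrame:
    """Binary directional TF-level PPI indicator matrix.

    A column ``TFa|TFb`` exists for every retained PPI edge between TFs that
    both have peak sets in this cell-type; the indicator is 1 iff >=1 peak of
    TFa overlaps the enhancer and >=1 peak of TFb overlaps the promoter.
    """
    tfs = sorted(t for t in network.tf_nodes() if t in genome.peaks)
    tf_set = set(tfs)
    columns: list[tuple[str, str]] = []
    for a, b in network.graph.edges:
        if a in tf_set and b in tf_set:
            if a == b:
                columns.append((a, a))
            else:
                columns.extend([(a, b), (b, a)])
    columns = sorted(set(columns))
    bound_e, bound_p = _binding_tables(pairs, genome, tfs)
    data = {
        f"{a}|{b}": (bound_e[a].to_numpy() & bound_p[b].to_numpy()).astype(np.int8)
        for a, b in columns
    }
    return pd.DataFrame(data, index=pairs.index)


def aggregate_to_modules(
    tf_matrix: pd.DataFrame, catalog: ModuleFeatureCatalog
) -> pd.DataFrame:
    """Module-level columns: maximum over constituent TF-level indicators."""
    known_pairs = {c for f in catalog.features for c in f.constituents}
    for col in tf_matrix.columns:
        a, b = col.split("|")
        if catalog.assignment.s_module_of.get(a) is None or (
            catalog.assignment.s_module_of.get(b) is None
        ):
            raise ValueError(f"TF-level column {col} has unassigned TFs")
        if (a, b) not in known_pairs:
            raise ValueError(f"TF-level column {col} maps to no catalog feature")
    out = {}
    for f in catalog.features:
        cols = [f"{a}|{b}" for a, b in f.constituents if f"{a}|{b}" in tf_matrix.columns]
        if cols:
            out[f.feature_id] = tf_matrix[cols].to_numpy().max(axis=1)
        else:
            out[f.feature_id] = np.zeros(len(tf_matrix), dtype=np.int8)
    return pd.DataFrame(out, index=tf_matrix.index, columns=catalog.feature_ids)


def assemble(
    pairs: pd.DataFrame,
    activity_cols: pd.DataFrame,
    module_cols: pd.DataFrame,
) -> pd.DataFrame:
    """Full feature matrix: activity triple, distance, then catalog columns."""
    if not (pairs.index.equals(activity_cols.index) and pairs.index.equals(module_cols.index)):
        raise ValueError("row sets of pairs, activity and module features differ")
    X = pd.concat(
        [activity_cols[ACTIVITY_COLUMNS],
         pairs[["distance_bp"]].astype(float),
         module_cols],
        axis=1,
    )
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values after assembly")
    return X


def build_feature_matrix(
    pairs: pd.DataFrame,
    genome: GenomeAnnotation,
    network: PPINetwork,
    catalog: ModuleFeatureCatalog,
    cell_type: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (assembled matrix, TF-level indicator matrix) for pairs."""
    act = activity_features(pairs, genome.activity, genome.expression, cell_type)
    tf_mat = tf_ppi_indicators(pairs, genome, network)
    mod = aggregate_to_modules(tf_mat, catalog)
    return assemble(pairs, act, mod), tf_mat
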