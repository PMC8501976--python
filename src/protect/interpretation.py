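"""TF-level decoding of module features and eQTL enrichment statistics.

Module-level importance is decoded back to individual TF pairs by their
abundance -- the fraction of significant genome-wide predictions whose
enhancer/promoter carry the specific ordered TF PPI.  Orthogonal validation
statistics compare predictions against cis-eQTL SNP-gene pairs (with random
and distance-matched pairing controls), SNP-to-peak-summit distances
(Kolmogorov-Smirnov), and trans-eQTLs over enhancer-mediated TF-gene pairs
(hypergeometric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ks_2samp

from .genome_io import Gene, GenomeAnnotation
from .ppi_modules import ModuleFeatureCatalog

logger = logging.getLogger(__name__)


@dataclass
class TFLevelRanking:
    module_feature_id: str
    ranking: list[tuple[str, str, float]]  # (tf_enh, tf_prom, abundance), descending


def rank_tf_level(
    sig_tf_matrix: pd.DataFrame,
    catalog: ModuleFeatureCatalog,
    module_feature: str,
    top_k: int = 5,
) -> TFLevelRanking:
    """Rank a module feature's constituent TF PPIs by abundance.

    Abundance is the fraction of significant predictions whose TF-level
    indicator for the ordered pair equals 1.  Ties break lexicographically.
    """
    if len(sig_tf_matrix) == 0:
        raise ValueError("no significant predictions to rank over")
    feature = catalog.by_id(module_feature)
    entries = []
    for a, b in feature.constituents:
        col = f"{a}|{b}"
        abundance = float(sig_tf_matrix[col].mean()) if col in sig_tf_matrix else 0.0
        entries.append((a, b, abundance))
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return TFLevelRanking(module_feature_id=module_feature, ranking=entries[:top_k])


def top_module_features(
    bundle, catalog: ModuleFeatureCatalog, top_n: int = 5
) -> list[str]:
    """Module-level feature ids ranked by forest importance (merged columns
    credit both parents)."""
    from .predictor import feature_importances

    imp = feature_importances(bundle)
    catalog_ids = set(catalog.feature_ids)
    scores: dict[str, float] = {}
    for name, v in imp.items():
        parts = name.split("~") if "~" in name else [name]
        for part in parts:
            if part in catalog_ids:
                scores[part] = max(scores.get(part, 0.0), float(v))
    ranked = sorted(scores, key=lambda f: (-scores[f], f))
    return ranked[:top_n]


def gene_sets_by_feature(
    predictions: pd.DataFrame,
    sig_tf_matrix: pd.DataFrame,
    catalog: ModuleFeatureCatalog,
    top_features: list[str],
    tf_top_k: int = 5,
    n_genes: int = 1000,
) -> dict[str, list[str]]:
    """Top regulated genes per module feature.

    For each feature: keep significant predictions containing >=1 of its
    top-k TF-level PPIs, sort ascending by q-value (gene id breaks ties),
    and collect distinct genes up to ``n_genes``.
    """
    sig = predictions[predictions["significant"]]
    out: dict[str, list[str]] = {}
    for fid in top_features:
        ranking = rank_tf_level(sig_tf_matrix.loc[sig.index], catalog, fid,
                                top_k=tf_top_k)
        cols = [f"{a}|{b}" for a, b, _ in ranking.ranking
                if f"{a}|{b}" in sig_tf_matrix.columns]
        if not cols:
            out[fid] = []
            continue
        has_feature = sig_tf_matrix.loc[sig.index, cols].to_numpy().max(axis=1) > 0
        subset = sig[has_feature].sort_values(["q_value", "gene_id"])
        genes: list[str] = []
        seen = set()
        for gid in subset["gene_id"]:
            if gid not in seen:
                seen.add(gid)
                genes.append(gid)
            if len(genes) >= n_genes:
                break
        if len(genes) < n_genes:
            logger.info("gene_sets_by_feature(%s): only %d genes available", fid, len(genes))
        out[fid] = genes
    return out


# ---------------------------------------------------------------------------
# cis-eQTL enrichment


@dataclass
class EnrichmentResult:
    observed_fraction: float
    control_fractions_random: np.ndarray
    control_fractions_matched: np.ndarray
    p_vs_random: float
    p_vs_matched: float


def _supported_mask(
    pairs: pd.DataFrame, qtls: pd.DataFrame, genome: GenomeAnnotation
) -> np.ndarray:
    """True where the enhancer contains a QTL SNP whose target is the gene."""
    snps_by_gene: dict[str, list[tuple[str, int]]] = {}
    for row in qtls.itertuples():
        snps_by_gene.setdefault(str(row.gene_id), []).append((str(row.chrom), int(row.pos)))
    mask = np.zeros(len(pairs), dtype=bool)
    for i, row in enumerate(pairs.itertuples()):
        e = genome.enhancer_by_id(row.enhancer_id)
        for chrom, pos in snps_by_gene.get(row.gene_id, ()):
            if chrom == e.chrom and e.start <= pos < e.end:
                mask[i] = True
                break
    return mask


def cis_qtl_enrichment(
    predictions: pd.DataFrame,
    qtls: pd.DataFrame,
    genome: GenomeAnnotation,
    n_random: int = 1000,
    seed: int = 0,
    max_distance: int = 2_000_000,
    hist_bin_bp: int = 50_000,
) -> EnrichmentResult:
    """Fraction of significant predictions supported by cis-eQTLs vs controls.

    Control 1 pairs enhancers with promoters at random within ``max_distance``;
    control 2 additionally matches the predictions' distance histogram at
    ``hist_bin_bp`` resolution.  Empirical p-values use the add-one estimator.
    """
    from .genomewide import enumerate_candidates

    sig = predictions[predictions["significant"]]
    if len(sig) == 0:
        raise ValueError("no significant predictions")
    observed = float(_supported_mask(sig, qtls, genome).mean())

    pool = enumerate_candidates(genome, max_distance=max_distance)
    pool_supported = _supported_mask(pool, qtls, genome)
    pool_bins = pool["distance_bp"].to_numpy() // hist_bin_bp
    sig_bins = sig["distance_bp"].to_numpy() // hist_bin_bp
    want_by_bin = pd.Series(sig_bins).value_counts().to_dict()
    bin_indices = {b: np.flatnonzero(pool_bins == b) for b in want_by_bin}

    rng = np.random.default_rng(seed)
    n = len(sig)
    frac_random = np.empty(n_random)
    frac_matched = np.empty(n_random)
    for s in range(n_random):
        idx = rng.choice(len(pool), size=n, replace=True)
        frac_random[s] = pool_supported[idx].mean()
        picks = []
        for b, want in want_by_bin.items():
            cand = bin_indices[b]
            if len(cand) == 0:
                continue
            picks.append(rng.choice(cand, size=want, replace=True))
        all_picks = np.concatenate(picks) if picks else np.array([], dtype=int)
        frac_matched[s] = pool_supported[all_picks].mean() if len(all_picks) else 0.0
    p_rand = (1.0 + np.sum(frac_random >= observed)) / (1.0 + n_random)
    p_match = (1.0 + np.sum(frac_matched >= observed)) / (1.0 + n_random)
    return EnrichmentResult(
        observed_fraction=observed,
        control_fractions_random=frac_random,
        control_fractions_matched=frac_matched,
        p_vs_random=p_rand,
        p_vs_matched=p_match,
    )


# ---------------------------------------------------------------------------
# SNP-to-summit distances


@dataclass
class SummitDistanceResult:
    foreground: np.ndarray
    background: np.ndarray
    ks_statistic: float
    p_value: float


def snp_summit_distance_test(
    snp_enhancers: list[tuple[str, int, str]],
    genome: GenomeAnnotation,
    prioritized_tfs: list[str],
    background_tfs: list[str] | None = None,
) -> SummitDistanceResult:
    """Peak-size-normalized SNP-to-summit distances, foreground vs background.

    ``snp_enhancers`` holds (chrom, snp_pos, enhancer_id) for eQTL SNPs inside
    predicted enhancers.  For every peak overlapping the enhancer the relative
    distance ``|snp - summit| / peak_length`` is collected; foreground uses
    peaks of prioritized TFs, background uses ``background_tfs`` (default: all
    other TFs with peaks in the same enhancers).  Two-sample KS test.
    """
    prioritized = set(prioritized_tfs)
    if background_tfs is None:
        background = set(genome.peaks) - prioritized
    else:
        background = set(background_tfs)

    def distances(tf_names: set[str]) -> list[float]:
        vals = []
        for chrom, pos, eid in snp_enhancers:
            e = genome.enhancer_by_id(eid)
            for tf in sorted(tf_names):
                ps = genome.peaks.get(tf)
                if ps is None:
                    continue
                for pk in ps.peaks:
                    if pk.chrom == chrom and pk.overlaps(e):
                        summit_abs = pk.start + (pk.summit if pk.summit is not None
                                                 else pk.length // 2)
                        vals.append(abs(pos - summit_abs) / pk.length)
        return vals

    fg = np.array(distances(prioritized))
    bg = np.array(distances(background))
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("empty foreground or background distance sample")
    stat, p = ks_2samp(fg, bg)
    return SummitDistanceResult(foreground=fg, background=bg,
                                ks_statistic=float(stat), p_value=float(p))


# ---------------------------------------------------------------------------
# trans-eQTL enrichment


@dataclass
class TransPairRecord:
    tf: str
    enhancer_id: str
    gene_id: str


def trans_pairs(
    predictions: pd.DataFrame,
    sig_tf_matrix: pd.DataFrame,
    catalog: ModuleFeatureCatalog,
    prioritized_features: list[str],
    genome: GenomeAnnotation,
) -> tuple[set[tuple[str, str]], list[TransPairRecord]]:
    """Enhancer-mediated (TF, target gene) pairs.

    A pair is emitted when a significant prediction carries a TF-level PPI of
    a prioritized module feature with that TF on the enhancer side.  Genes
    whose promoter is itself bound by the TF are removed (those could be
    promoter-mediated).
    """
    sig = predictions[predictions["significant"]]
    records: list[TransPairRecord] = []
    for fid in prioritized_features:
        feature = catalog.by_id(fid)
        for a, b in feature.constituents:
            col = f"{a}|{b}"
            if col not in sig_tf_matrix.columns:
                continue
            hits = sig_tf_matrix.loc[sig.index, col] > 0
            for idx in sig.index[hits]:
                records.append(TransPairRecord(
                    tf=a,
                    enhancer_id=sig.at[idx, "enhancer_id"],
                    gene_id=sig.at[idx, "gene_id"],
                ))
    # drop pairs where the TF also binds the gene's own promoter
    kept: list[TransPairRecord] = []
    promoter_bound_cache: dict[tuple[str, str], bool] = {}
    for r in records:
        key = (r.tf, r.gene_id)
        if key not in promoter_bound_cache:
            prom = genome.gene_by_id(r.gene_id).promoter
            ps = genome.peaks.get(r.tf)
            promoter_bound_cache[key] = bool(ps) and any(
                pk.overlaps(prom) for pk in ps.peaks
            )
        if not promoter_bound_cache[key]:
            kept.append(r)
    pairs = {(r.tf, r.gene_id) for r in kept}
    return pairs, kept


def _tf_gene_body_window(row, upstream_bp: int) -> tuple[str, int, int]:
    """Strand-aware gene-body interval extended upstream of the TSS."""
    if row.strand == "+":
        return (row.chrom, max(0, int(row.start) - upstream_bp), int(row.end))
    return (row.chrom, int(row.start), int(row.end) + upstream_bp)


@dataclass
class TransQTLResult:
    p_value: float
    n_overlap: int
    n_pairs: int
    population: int
    successes: int
    control_nearest_p: float
    control_random_ps: np.ndarray = field(default_factory=lambda: np.array([]))


def trans_qtl_test(
    records: list[TransPairRecord],
    trans_qtls: pd.DataFrame,
    tf_gene_bodies: pd.DataFrame,
    genome: GenomeAnnotation,
    upstream_bp: int = 10_000,
    n_random: int = 1000,
    seed: int = 0,
    max_distance: int = 2_000_000,
) -> TransQTLResult:
    """Hypergeometric enrichment of trans-eQTL support among TF-gene pairs.

    A pair (TF, gene) overlaps a trans-eQTL when the SNP lies in the TF's
    gene body (extended ``upstream_bp`` upstream of the TSS, strand-aware)
    and the eQTL target matches the gene.  Population = prioritized TFs x
    testable genes; successes = trans-eQTL-supported combinations; draws =
    the predicted pairs.  Controls reassign target genes as the enhancer's
    nearest gene (deterministic) or a random gene within ``max_distance``
    (``n_random`` samples).
    """
    windows = {
        str(row.tf): _tf_gene_body_window(row, upstream_bp)
        for row in tf_gene_bodies.itertuples()
    }
    testable_genes = {g.gene_id for g in genome.genes}
    supported: set[tuple[str, str]] = set()
    for row in trans_qtls.itertuples():
        gid = str(row.gene_id)
        if gid not in testable_genes:
            continue
        for tf, (chrom, start, end) in windows.items():
            if str(row.chrom) == chrom and start <= int(row.pos) < end:
                supported.add((tf, gid))

    tfs = sorted({r.tf for r in records})
    population = len(tfs) * len(testable_genes)
    successes = sum(1 for (tf, g) in supported if tf in set(tfs))

    def hyper_p(pair_set: set[tuple[str, str]]) -> float:
        hits = len(pair_set & supported)
        return float(hypergeom.sf(hits - 1, population, successes, len(pair_set)))

    foreground = {(r.tf, r.gene_id) for r in records}
    p_obs = hyper_p(foreground)

    # control 1: nearest gene to each enhancer as target
    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    nearest_pairs = set()
    for r in records:
        e = genome.enhancer_by_id(r.enhancer_id)
        cands = genes_by_chrom.get(e.chrom, [])
        if cands:
            nearest = min(cands, key=lambda g: (abs(g.tss - e.midpoint), g.gene_id))
            nearest_pairs.add((r.tf, nearest.gene_id))
    p_nearest = hyper_p(nearest_pairs)

    # control 2: random genes within 2 Mb of each enhancer
    rng = np.random.default_rng(seed)
    within: dict[str, list[str]] = {}
    for r in records:
        if r.enhancer_id not in within:
            e = genome.enhancer_by_id(r.enhancer_id)
            within[r.enhancer_id] = [
                g.gene_id for g in genes_by_chrom.get(e.chrom, [])
                if abs(g.tss - e.midpoint) < max_distance
            ]
    random_ps = np.empty(n_random)
    for s in range(n_random):
        pairs_s = set()
        for r in records:
            cands = within[r.enhancer_id]
            if cands:
                pairs_s.add((r.tf, cands[int(rng.integers(len(cands)))]))
        random_ps[s] = hyper_p(pairs_s)
    return TransQTLResult(
        p_value=p_obs,
        n_overlap=len(foreground & supported),
        n_pairs=len(foreground),
        population=population,
        successes=successes,
        control_nearest_p=p_nearest,
        control_random_ps=random_ps,
    )
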