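"""Confounder-controlled labeled enhancer-promoter pair construction.

Positives are intra-TAD enhancer-promoter pairs whose elements overlap the
two opposite anchors of a gold-standard contact.  Negatives are sampled to
control three confounders: they are intra-TAD, they match the positives'
genomic-distance distribution per 50 kb bin, and they are restricted to
expressed genes (RPKM > 0), reflecting the lower false-negative rate of
contact assays in transcriptionally active regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ContactSet, GenomeAnnotation
from .synthetic_fixtures import intra_tad_pairs

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 50_000

PAIR_COLUMNS = ["enhancer_id", "gene_id", "chrom", "distance_bp", "tad_id", "label"]


@dataclass(frozen=True)
class EPPair:
    enhancer_id: str
    gene_id: str
    chrom: str
    distance_bp: int
    tad_id: str
    label: int  # 1 positive, 0 negative

    def key(self) -> tuple[str, str]:
        return (self.enhancer_id, self.gene_id)


def _pair_distance(genome: GenomeAnnotation, enhancer_id: str, gene_id: str) -> int:
    e = genome.enhancer_by_id(enhancer_id)
    g = genome.gene_by_id(gene_id)
    return abs(e.midpoint - g.tss)


def _candidate_pairs(genome: GenomeAnnotation) -> list[tuple[str, str, str, int]]:
    """(enhancer_id, gene_id, tad_id, distance) for every intra-TAD pair."""
    return [
        (e.id, g.gene_id, tad, abs(e.midpoint - g.tss))
        for e, g, tad in intra_tad_pairs(genome)
    ]


def label_positives(genome: GenomeAnnotation, contacts: ContactSet) -> set[EPPair]:
    """Positive pairs: enhancer on one contact anchor, promoter on the other.

    A pair is positive iff, for some contact, the enhancer interval overlaps
    anchor i and the promoter overlaps anchor j with i != j (>= 1 bp each).
    Cross-TAD matches are removed; elements outside any TAD are skipped and
    counted.
    """
    import numpy as np

    positives: dict[tuple[str, str], EPPair] = {}
    n_skipped_no_tad = 0
    chroms = sorted({a1.chrom for a1, _ in contacts.anchors})
    enh_by_chrom = {c: [e for e in genome.enhancers if e.chrom == c] for c in chroms}
    gene_by_chrom = {c: [g for g in genome.genes if g.chrom == c] for c in chroms}
    arr = {}
    for c in chroms:
        enh = enh_by_chrom[c]
        genes = gene_by_chrom[c]
        arr[c] = (
            np.array([e.start for e in enh]), np.array([e.end for e in enh]),
            np.array([g.promoter.start for g in genes]),
            np.array([g.promoter.end for g in genes]),
        )

    def overlapping(starts, ends, anchor):
        if len(starts) == 0:
            return np.zeros(0, dtype=bool)
        return (starts < anchor.end) & (ends > anchor.start)

    for a1, a2 in contacts.anchors:
        c = a1.chrom
        enh = enh_by_chrom.get(c, [])
        genes = gene_by_chrom.get(c, [])
        if not enh or not genes:
            continue
        es, ee, ps, pe = arr[c]
        for anchor_e, anchor_p in ((a1, a2), (a2, a1)):
            e_hits = np.flatnonzero(overlapping(es, ee, anchor_e))
            p_hits = np.flatnonzero(overlapping(ps, pe, anchor_p))
            for ei in e_hits:
                e = enh[int(ei)]
                tad_e = genome.tad_of(e.chrom, e.midpoint)
                for gi in p_hits:
                    g = genes[int(gi)]
                    tad_g = genome.tad_of(g.chrom, g.tss)
                    if tad_e is None or tad_g is None:
                        n_skipped_no_tad += 1
                        continue
                    if tad_e != tad_g:
                        continue  # cross-TAD interactions are removed
                    pair = EPPair(e.id, g.gene_id, e.chrom,
                                  abs(e.midpoint - g.tss), tad_e, label=1)
                    positives[pair.key()] = pair
    if n_skipped_no_tad:
        logger.info("label_positives: skipped %d pairs outside TADs", n_skipped_no_tad)
    return set(positives.values())


def _negative_pool(
    genome: GenomeAnnotation,
    positives: set[EPPair],
    expression: pd.DataFrame,
    cell_type: str,
) -> list[EPPair]:
    """Intra-TAD pairs that are not positives, for genes with expression > 0."""
    pos_keys = {p.key() for p in positives}
    expr = expression[cell_type]
    pool = []
    for eid, gid, tad, dist in _candidate_pairs(genome):
        if (eid, gid) in pos_keys:
            continue
        v = expr.get(gid)
        if v is None or not np.isfinite(v) or v <= 0:
            continue
        chrom = genome.enhancer_by_id(eid).chrom
        pool.append(EPPair(eid, gid, chrom, dist, tad, label=0))
    return pool


def sample_negatives(
    genome: GenomeAnnotation,
    positives: set[EPPair],
    expression: pd.DataFrame,
    cell_type: str,
    bin_size_bp: int = DEFAULT_BIN_SIZE,
    seed: int = 0,
    neg_per_pos: float = 1.0,
) -> set[EPPair]:
    """Distance-matched negative sampling.

    For each ``bin_size_bp`` distance bin of the positives, draw
    ``round(neg_per_pos * count)`` negatives uniformly without replacement
    from the candidate pool in that bin.  Bins with insufficient candidates
    take all available (logged deficit).
    """
    rng = np.random.default_rng(seed)
    pool = _negative_pool(genome, positives, expression, cell_type)
    pool_by_bin: dict[int, list[EPPair]] = {}
    for p in pool:
        pool_by_bin.setdefault(p.distance_bp // bin_size_bp, []).append(p)
    pos_counts: dict[int, int] = {}
    for p in positives:
        b = p.distance_bp // bin_size_bp
        pos_counts[b] = pos_counts.get(b, 0) + 1

    negatives: set[EPPair] = set()
    for b in sorted(pos_counts):
        want = int(round(neg_per_pos * pos_counts[b]))
        bucket = sorted(pool_by_bin.get(b, []), key=EPPair.key)
        if len(bucket) < want:
            logger.warning(
                "sample_negatives: bin %d wants %d negatives, only %d candidates",
                b, want, len(bucket),
            )
            negatives.update(bucket)
        else:
            idx = rng.choice(len(bucket), size=want, replace=False)
            negatives.update(bucket[int(i)] for i in idx)
    return negatives


def build_training_table(
    positives: set[EPPair],
    negatives: set[EPPair],
    provenance: dict | None = None,
) -> pd.DataFrame:
    """Single labeled table in stable (chrom, enhancer_id, gene_id) order."""
    overlap = {p.key() for p in positives} & {n.key() for n in negatives}
    if overlap:
        raise ValueError(f"pairs present in both label sets: {sorted(overlap)[:5]}")
    rows = [
        (p.enhancer_id, p.gene_id, p.chrom, p.distance_bp, p.tad_id, p.label)
        for p in list(positives) + list(negatives)
    ]
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    df = df.sort_values(["chrom", "enhancer_id", "gene_id"]).reset_index(drop=True)
    df.attrs["provenance"] = provenance or {}
    return df


def make_training_table(
    genome: GenomeAnnotation,
    contacts: ContactSet,
    expression: pd.DataFrame,
    cell_type: str,
    bin_size_bp: int = DEFAULT_BIN_SIZE,
    seed: int = 0,
    strict_balance: bool = False,
) -> pd.DataFrame:
    """Convenience: label positives, sample balanced negatives, build table.

    With ``strict_balance`` the excess positives in deficit bins are dropped
    so the per-bin counts are exactly equal.
    """
    positives = label_positives(genome, contacts)
    negatives = sample_negatives(genome, positives, expression, cell_type,
                                 bin_size_bp=bin_size_bp, seed=seed)
    if strict_balance:
        neg_counts: dict[int, int] = {}
        for n in negatives:
            b = n.distance_bp // bin_size_bp
            neg_counts[b] = neg_counts.get(b, 0) + 1
        rng = np.random.default_rng(seed + 1)
        kept: set[EPPair] = set()
        by_bin: dict[int, list[EPPair]] = {}
        for p in positives:
            by_bin.setdefault(p.distance_bp // bin_size_bp, []).append(p)
        for b, plist in by_bin.items():
            plist = sorted(plist, key=EPPair.key)
            keep = min(len(plist), neg_counts.get(b, 0))
            idx = rng.choice(len(plist), size=keep, replace=False)
            kept.update(plist[int(i)] for i in idx)
        positives = kept
    return build_training_table(
        positives, negatives,
        provenance={"cell_type": cell_type, "bin_size_bp": bin_size_bp, "seed": seed},
    )


def make_imbalanced_table(
    genome: GenomeAnnotation,
    contacts: ContactSet,
    expression: pd.DataFrame,
    cell_type: str,
    pos_to_neg_ratio: float = 0.1,
    bin_size_bp: int = DEFAULT_BIN_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Imbalanced variant: negatives per bin = positives / ratio.

    Keeps the per-bin distance proportions of negatives matched to positives.
    If the pool is exhausted in some bin, all candidates there are used and a
    warning is logged (the achieved ratio is reported in provenance).
    """
    if not 0 < pos_to_neg_ratio <= 1:
        raise ValueError("pos_to_neg_ratio must be in (0, 1]")
    positives = label_positives(genome, contacts)
    negatives = sample_negatives(
        genome, positives, expression, cell_type,
        bin_size_bp=bin_size_bp, seed=seed, neg_per_pos=1.0 / pos_to_neg_ratio,
    )
    table = build_training_table(
        positives, negatives,
        provenance={
            "cell_type": cell_type,
            "bin_size_bp": bin_size_bp,
            "seed": seed,
            "requested_ratio": pos_to_neg_ratio,
            "achieved_ratio": (len(positives) / len(negatives)) if negatives else float("nan"),
        },
    )
    return table


def distance_histogram(table: pd.DataFrame, bin_size_bp: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Per-bin counts of each label; used to verify distance matching."""
    df = table.copy()
    df["bin"] = df["distance_bp"] // bin_size_bp
    return df.pivot_table(index="bin", columns="label", values="enhancer_id",
                          aggfunc="count", fill_value=0)
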