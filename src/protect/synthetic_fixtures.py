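"""Seeded toy-genome generator with planted PPI modules and causal TF PPIs.

The generator emulates the statistical structure the predictor is built to
exploit: enhancer-promoter contacts arise from an exponential distance decay,
and pairs where a planted "causal" TF PPI bridges the enhancer and the
promoter receive a multiplicative odds boost.  The PPI network is a stochastic
block model with planted modules, so community detection has a known truth.

All randomness flows from one seed through named per-substep generators, so
adding a step never perturbs earlier draws.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genome_io import (
    ContactSet,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    PPINetwork,
    TFPeakSet,
    write_bed,
    write_bedpe,
    write_gene_table,
    write_matrix_tsv,
    write_narrowpeak,
    write_ppi_edges,
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Sizes and rates are chosen to mimic a small regulatory landscape: TADs of
    ~1-2 Mb, enhancers a few hundred bp wide, contact probability decaying
    with distance (half-life ~200 kb), and a PPI network with a few dense
    planted communities.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    n_tads_per_chrom: int = 5
    n_enhancers: int = 200
    n_genes: int = 100
    enhancer_width_bp: int = 1000
    n_tfs: int = 24
    n_nontf_proteins: int = 12
    n_planted_modules: int = 4
    within_module_edge_prob: float = 0.9
    between_module_edge_prob: float = 0.05
    n_causal_ppis: int = 4
    causal_ppi_list: list[tuple[str, str]] | None = None
    base_contact_prob: float = 0.15
    causal_odds_multiplier: float = 20.0
    distance_decay_halflife_bp: int = 250_000
    #: loop-caller detection limit: a physical contact at distance d is
    #: emitted as a called loop with probability 1 - 2**(-d/halflife),
    #: reproducing the rising-then-decaying distance profile of real
    #: significant-loop sets (ultra-short loops are not callable).
    detection_halflife_bp: int = 100_000
    peak_prob_per_tf: float = 0.2
    n_cell_types: int = 12
    #: weak residual activity/expression coupling for contacted pairs;
    #: activity-based features alone are only mildly predictive of loops.
    activity_correlation: float = 0.05
    min_ppi_score: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_module_edge_prob", "between_module_edge_prob",
                     "base_contact_prob", "peak_prob_per_tf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.causal_odds_multiplier < 1.0:
            raise ValueError("causal_odds_multiplier must be >= 1")

    def rng(self, substep: str) -> np.random.Generator:
        """Named substream: independent of draws made by other substeps."""
        return _stable_rng(self.seed, substep)


@dataclass
class GroundTruth:
    true_module_of: dict[str, int] = field(default_factory=dict)
    causal_ppis: set[tuple[str, str]] = field(default_factory=set)
    true_positive_pairs: set[tuple[str, str]] = field(default_factory=set)


def _stable_rng(seed: int, tag: str) -> np.random.Generator:
    # hash() is salted per-process for str; use a deterministic digest instead
    import zlib

    return np.random.default_rng([seed, zlib.crc32(tag.encode())])


def tf_names(config: SimulationConfig) -> list[str]:
    return [f"TF{i:02d}" for i in range(config.n_tfs)]


def nontf_names(config: SimulationConfig) -> list[str]:
    return [f"NT{i:02d}" for i in range(config.n_nontf_proteins)]


def simulate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place TADs, enhancers, genes and per-TF peaks on a toy genome.

    TADs tile each chromosome without gaps.  Enhancers and gene TSSs are
    placed uniformly within TADs.  Each enhancer and each promoter receives a
    peak of each TF independently with probability ``peak_prob_per_tf``; the
    peak interval equals the element and its summit is the midpoint offset.
    Activity and expression matrices are log-normal across the cell-type
    panel (true-positive correlation is injected later by
    :func:`simulate_dataset`, once contacts are known).
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length_bp for c in chroms}
    tad_width = config.chrom_length_bp // config.n_tads_per_chrom
    if tad_width <= 2 * config.enhancer_width_bp:
        raise ValueError("TADs too small for requested element widths")

    tads = [
        GenomicInterval(c, i * tad_width, (i + 1) * tad_width, id=f"{c}:TAD{i}")
        for c in chroms
        for i in range(config.n_tads_per_chrom)
    ]

    rng_place = config.rng("placement")
    half_w = config.enhancer_width_bp // 2
    enhancers = []
    for i in range(config.n_enhancers):
        tad = tads[rng_place.integers(len(tads))]
        mid = int(rng_place.integers(tad.start + half_w, tad.end - half_w))
        enhancers.append(
            GenomicInterval(tad.chrom, mid - half_w, mid + half_w, id=f"E{i:04d}")
        )
    genes = []
    for i in range(config.n_genes):
        tad = tads[rng_place.integers(len(tads))]
        tss = int(rng_place.integers(tad.start + 1000, tad.end - 1000))
        strand = "+" if rng_place.random() < 0.5 else "-"
        genes.append(Gene(gene_id=f"G{i:04d}", chrom=tad.chrom, tss=tss, strand=strand))

    rng_peaks = config.rng("peaks")
    peaks: dict[str, TFPeakSet] = {}
    for tf in tf_names(config):
        tf_peaks: list[GenomicInterval] = []
        for e in enhancers:
            if rng_peaks.random() < config.peak_prob_per_tf:
                tf_peaks.append(
                    GenomicInterval(e.chrom, e.start, e.end,
                                    id=f"{tf}:{e.id}", summit=e.length // 2)
                )
        for g in genes:
            p = g.promoter
            if rng_peaks.random() < config.peak_prob_per_tf:
                tf_peaks.append(
                    GenomicInterval(p.chrom, p.start, p.end,
                                    id=f"{tf}:{g.gene_id}", summit=p.length // 2)
                )
        peaks[tf] = TFPeakSet(tf_name=tf, peaks=tf_peaks)

    cell_types = [f"CT{i:02d}" for i in range(config.n_cell_types)]
    rng_act = config.rng("activity")
    activity = pd.DataFrame(
        np.exp(rng_act.normal(0.0, 1.0, size=(len(enhancers), len(cell_types)))),
        index=[e.id for e in enhancers],
        columns=cell_types,
    )
    rng_expr = config.rng("expression")
    expression = pd.DataFrame(
        np.exp(rng_expr.normal(0.0, 1.0, size=(len(genes), len(cell_types)))),
        index=[g.gene_id for g in genes],
        columns=cell_types,
    )
    return GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        tads=tads,
        enhancers=enhancers,
        genes=genes,
        peaks=peaks,
        activity=activity,
        expression=expression,
    )


def simulate_ppi_network(config: SimulationConfig) -> tuple[PPINetwork, GroundTruth]:
    """Stochastic block model over TF and non-TF proteins with planted modules.

    Nodes are assigned round-robin to ``n_planted_modules`` blocks; edges are
    drawn independently with the within/between probabilities and receive
    uniform confidence weights in ``(min_ppi_score, 1000]``.
    """
    if config.n_planted_modules < 2:
        raise ValueError("need at least 2 planted modules")
    all_nodes = tf_names(config) + nontf_names(config)
    module_of = {n: i % config.n_planted_modules for i, n in enumerate(all_nodes)}

    rng = config.rng("ppi_edges")
    graph = nx.Graph()
    graph.add_nodes_from(all_nodes)
    for i, a in enumerate(all_nodes):
        for b in all_nodes[i + 1:]:
            p = (
                config.within_module_edge_prob
                if module_of[a] == module_of[b]
                else config.between_module_edge_prob
            )
            if rng.random() < p:
                w = config.min_ppi_score + rng.random() * (1000.0 - config.min_ppi_score)
                graph.add_edge(a, b, weight=float(w))
    tf_set = set(tf_names(config))
    for n in graph.nodes:
        graph.nodes[n]["is_tf"] = n in tf_set
        graph.nodes[n]["is_expressed"] = True

    truth = GroundTruth(true_module_of={n: module_of[n] for n in tf_set})
    if config.causal_ppi_list is not None:
        causal = [tuple(p) for p in config.causal_ppi_list]
        for a, b in causal:
            if not graph.has_edge(a, b):
                raise ValueError(f"causal PPI ({a},{b}) not an edge of the network")
    else:
        tf_edges = [
            (a, b) for a, b in graph.edges
            if a in tf_set and b in tf_set and a != b
        ]
        rng_causal = config.rng("causal_choice")
        idx = rng_causal.choice(len(tf_edges), size=min(config.n_causal_ppis, len(tf_edges)),
                                replace=False)
        causal = []
        for k in idx:
            a, b = tf_edges[int(k)]
            causal.append((a, b) if rng_causal.random() < 0.5 else (b, a))
    truth.causal_ppis = set(causal)
    return PPINetwork(graph=graph), truth


def _bound_elements(genome: GenomeAnnotation) -> tuple[dict, dict]:
    """Per-TF sets of bound enhancer ids and bound gene ids (promoter overlap)."""
    from .genome_io import overlap_any

    chroms = sorted(genome.chrom_lengths) or sorted({e.chrom for e in genome.enhancers})
    enh_by_chrom = {c: [e for e in genome.enhancers if e.chrom == c] for c in chroms}
    prom_by_chrom = {
        c: [(g.gene_id, g.promoter) for g in genome.genes if g.chrom == c] for c in chroms
    }
    bound_enh: dict[str, set[str]] = {}
    bound_prom: dict[str, set[str]] = {}
    for tf, ps in genome.peaks.items():
        be: set[str] = set()
        bp: set[str] = set()
        for c in chroms:
            pk = [p for p in ps.peaks if p.chrom == c]
            pk_s = np.array([p.start for p in pk])
            pk_e = np.array([p.end for p in pk])
            enh = enh_by_chrom[c]
            hits = overlap_any([e.start for e in enh], [e.end for e in enh], pk_s, pk_e)
            be.update(e.id for e, h in zip(enh, hits) if h)
            proms = prom_by_chrom[c]
            hits = overlap_any([p.start for _, p in proms], [p.end for _, p in proms],
                               pk_s, pk_e)
            bp.update(gid for (gid, _), h in zip(proms, hits) if h)
        bound_enh[tf] = be
        bound_prom[tf] = bp
    return bound_enh, bound_prom


def intra_tad_pairs(genome: GenomeAnnotation) -> list[tuple[GenomicInterval, Gene, str]]:
    """All (enhancer, gene, tad_id) triples with both elements in one TAD."""
    out = []
    for e in genome.enhancers:
        tad_e = genome.tad_of(e.chrom, e.midpoint)
        if tad_e is None:
            continue
        for g in genome.genes:
            if g.chrom != e.chrom:
                continue
            if genome.tad_of(g.chrom, g.tss) == tad_e:
                out.append((e, g, tad_e))
    return out


def contact_probability(distance_bp: float, causal: bool, config: SimulationConfig) -> float:
    """Physical contact probability:
    ``expit(logit(base * 2**(-d/halflife)) + log(multiplier) * causal)``."""
    p_base = config.base_contact_prob * 2.0 ** (
        -distance_bp / config.distance_decay_halflife_bp
    )
    p_base = min(max(p_base, 1e-12), 1 - 1e-12)
    eta = logit(p_base)
    if causal:
        eta += np.log(config.causal_odds_multiplier)
    return float(expit(eta))


def detection_probability(distance_bp: float, config: SimulationConfig) -> float:
    """Probability that a physical contact is callable as a significant loop."""
    if config.detection_halflife_bp <= 0:
        return 1.0
    return 1.0 - 2.0 ** (-distance_bp / config.detection_halflife_bp)


def simulate_contacts(
    genome: GenomeAnnotation,
    network: PPINetwork,
    truth: GroundTruth,
    config: SimulationConfig,
) -> ContactSet:
    """Draw called loops for intra-TAD enhancer-promoter pairs.

    A physical contact occurs with :func:`contact_probability`, where
    ``causal`` indicates that some planted PPI (TFa, TFb) has a TFa peak in
    the enhancer and a TFb peak in the promoter.  A contact is emitted as a
    called loop with :func:`detection_probability`, which suppresses
    ultra-short-range loops the way real loop callers do; only emitted loops
    enter the gold standard and the recorded true-positive pairs.
    """
    bound_enh, bound_prom = _bound_elements(genome)
    rng = config.rng("contacts")
    anchors = []
    truth.true_positive_pairs = set()
    for e, g, _tad in intra_tad_pairs(genome):
        d = abs(e.midpoint - g.tss)
        has_causal = any(
            e.id in bound_enh.get(a, ()) and g.gene_id in bound_prom.get(b, ())
            for a, b in truth.causal_ppis
        )
        p = contact_probability(d, has_causal, config)
        if rng.random() < p and rng.random() < detection_probability(d, config):
            prom = g.promoter
            a1, a2 = (e, prom) if e.start <= prom.start else (prom, e)
            anchors.append((a1, a2))
            truth.true_positive_pairs.add((e.id, g.gene_id))
    return ContactSet(anchors=anchors, source_tag="synthetic")


@dataclass
class FixtureData:
    config: SimulationConfig
    genome: GenomeAnnotation
    network: PPINetwork
    truth: GroundTruth
    contacts: ContactSet


def simulate_dataset(config: SimulationConfig) -> FixtureData:
    """Full generator: genome -> PPI network -> contacts -> activity coupling.

    After contacts are drawn, the log-activity of each contacted enhancer is
    mixed with the standardized log-expression of its target gene at weight
    ``activity_correlation``, so true pairs show correlated activity across
    the cell-type panel.
    """
    genome = simulate_genome(config)
    network, truth = simulate_ppi_network(config)
    contacts = simulate_contacts(genome, network, truth, config)

    rho = config.activity_correlation
    if rho > 0 and truth.true_positive_pairs:
        log_act = np.log(genome.activity)
        log_expr = np.log(genome.expression)
        z_expr = log_expr.sub(log_expr.mean(axis=1), axis=0).div(
            log_expr.std(axis=1).replace(0.0, 1.0), axis=0
        )
        for eid, gid in sorted(truth.true_positive_pairs):
            mixed = rho * z_expr.loc[gid] + np.sqrt(1 - rho**2) * log_act.loc[eid]
            log_act.loc[eid] = mixed
        genome.activity = np.exp(log_act)
    return FixtureData(config=config, genome=genome, network=network,
                       truth=truth, contacts=contacts)


def write_fixtures(data: FixtureData, out_dir: str) -> None:
    """Write the dataset in the formats the readers consume, plus the truth."""
    os.makedirs(out_dir, exist_ok=True)
    g = data.genome
    write_bed(g.enhancers, os.path.join(out_dir, "enhancers.bed"))
    write_bed(g.tads, os.path.join(out_dir, "tads.bed"))
    write_gene_table(g.genes, os.path.join(out_dir, "genes.tsv"))
    write_bedpe(data.contacts, os.path.join(out_dir, "contacts.bedpe"))
    write_matrix_tsv(g.activity, os.path.join(out_dir, "activity.tsv"), "enhancer_id")
    write_matrix_tsv(g.expression, os.path.join(out_dir, "expression.tsv"), "gene_id")
    write_ppi_edges(data.network, os.path.join(out_dir, "ppi_edges.tsv"))
    peak_dir = os.path.join(out_dir, "peaks")
    os.makedirs(peak_dir, exist_ok=True)
    with open(os.path.join(out_dir, "peak_manifest.tsv"), "w") as fh:
        fh.write("tf_name\tpath\n")
        for tf, ps in sorted(g.peaks.items()):
            rel = os.path.join("peaks", f"{tf}.narrowPeak")
            write_narrowpeak(ps, os.path.join(out_dir, rel))
            fh.write(f"{tf}\t{rel}\n")
    truth_json = {
        "true_module_of": data.truth.true_module_of,
        "causal_ppis": sorted(data.truth.causal_ppis),
        "true_positive_pairs": sorted(data.truth.true_positive_pairs),
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth_json, fh, indent=1)
    with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
        cfg = asdict(data.config)
        json.dump(cfg, fh, indent=1)
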