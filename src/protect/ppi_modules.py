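"""Random-walk community detection on the PPI network and the S/L module catalog.

The walk runs on the full network (non-TF proteins included, since they
mediate indirect TF-TF connectivity); the pairwise distance matrix is then
restricted to TFs and Ward-clustered.  Cutting the dendrogram at every merge
height yields candidate partitions indexed by their largest-module size; the
S-module cut maximizes weighted modularity Q and the L-module cut sits at the
elbow of the Q-vs-size curve, so the two layers are nested by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .genome_io import PPINetwork

logger = logging.getLogger(__name__)

DEFAULT_WALK_STEPS = 20


@dataclass
class RandomWalkDistance:
    """Pairwise random-walk distances between TFs.

    ``R[i, j] = G[i, i] + G[j, j] - 2 G[i, j]`` with ``G = T T^t`` and ``T``
    the p-step transition matrix: a squared-Euclidean distance between the
    p-step visiting-probability profiles of the two nodes.
    """

    node_order: list[str]
    R: np.ndarray
    p: int


@dataclass
class ModuleAssignment:
    """Two-layer module memberships; every S-module lies in exactly one L-module."""

    s_module_of: dict[str, int]
    l_module_of: dict[str, int]
    S_max: int
    L_max: int
    modularity_curve: list[tuple[int, float]] = field(default_factory=list)

    def s_members(self) -> dict[int, list[str]]:
        return _invert(self.s_module_of)

    def l_members(self) -> dict[int, list[str]]:
        return _invert(self.l_module_of)


def _invert(mapping: dict[str, int]) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for k, v in mapping.items():
        out.setdefault(v, []).append(k)
    return {k: sorted(v) for k, v in out.items()}


def adjacency(network: PPINetwork, nodes: list[str]) -> np.ndarray:
    """Dense symmetric weighted adjacency over ``nodes`` (self-loops on diagonal)."""
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for a, b, d in network.graph.edges(data=True):
        if a in index and b in index:
            i, j = index[a], index[b]
            W[i, j] = d["weight"]
            W[j, i] = d["weight"]
    return W


def transition_matrix(
    network: PPINetwork, p: int = DEFAULT_WALK_STEPS
) -> tuple[list[str], np.ndarray]:
    """p-step transition matrix ``(D^-1 W)^p`` computed by repeated multiplication.

    Isolated nodes (zero weighted degree) cannot host a walk; they are dropped
    with a warning and later receive singleton modules.
    """
    nodes = sorted(network.graph.nodes)
    W = adjacency(network, nodes)
    deg = W.sum(axis=1)
    keep = deg > 0
    dropped = [n for n, k in zip(nodes, keep) if not k]
    if dropped:
        logger.warning("transition_matrix: dropping %d isolated nodes", len(dropped))
    nodes = [n for n, k in zip(nodes, keep) if k]
    W = W[np.ix_(keep, keep)]
    T1 = W / W.sum(axis=1, keepdims=True)
    T = np.eye(len(nodes))
    for _ in range(p):
        T = T @ T1
    return nodes, T


def rw_distance(
    node_order: list[str], trans: np.ndarray, tf_nodes: list[str], p: int = DEFAULT_WALK_STEPS
) -> RandomWalkDistance:
    """Restrict the walk-profile distance matrix to the TF nodes.

    ``G`` is formed over all walked nodes; ``R`` keeps only rows/columns of
    TFs that participated in the walk.
    """
    G = trans @ trans.T
    g = np.diag(G)
    R_full = g[:, None] + g[None, :] - 2.0 * G
    index = {n: i for i, n in enumerate(node_order)}
    tf_in = [t for t in tf_nodes if t in index]
    idx = [index[t] for t in tf_in]
    R = R_full[np.ix_(idx, idx)]
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 0.0)
    R[R < 0] = 0.0  # clip numerical negatives (magnitude < 1e-10)
    return RandomWalkDistance(node_order=tf_in, R=R, p=p)


def modularity(network: PPINetwork, membership: dict[str, int],
               nodes: list[str] | None = None) -> float:
    """Weighted Newman modularity Q of a partition.

    ``Q = (1/2m) sum_ij (W_ij - k_i k_j / 2m) delta(c_i, c_j)`` with weighted
    degrees ``k_i`` and ``m = (1/2) sum_i k_i``.
    """
    if nodes is None:
        nodes = sorted(n for n in network.graph.nodes if n in membership)
    W = adjacency(network, nodes)
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    labels = np.array([membership[n] for n in nodes])
    same = labels[:, None] == labels[None, :]
    B = W - np.outer(k, k) / two_m
    return float(B[same].sum() / two_m)


def _elbow_index(x: np.ndarray, y: np.ndarray) -> int:
    """Index of maximum perpendicular distance to the chord between endpoints.

    First index wins on ties; degenerate chords fall back to index 0.
    """
    if len(x) < 3:
        return 0
    p0 = np.array([x[0], y[0]], dtype=float)
    p1 = np.array([x[-1], y[-1]], dtype=float)
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 0
    pts = np.stack([x, y], axis=1).astype(float) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))


def hierarchical_modules(
    rwd: RandomWalkDistance, network: PPINetwork
) -> ModuleAssignment:
    """Ward clustering of R plus modularity-guided S/L cut selection.

    Every dendrogram level is a candidate cut; a cut's "maximum module size"
    is its largest cluster.  The S cut maximizes Q (ties toward smaller
    size, then toward the finer cut); the L cut is the elbow of the Q-vs-size
    curve over cuts at or above the S cut, so the S partition refines the L
    partition.  TFs absent from the walk get singleton modules in both layers.
    """
    tfs = rwd.node_order
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs to build modules")
    Z = linkage(squareform(rwd.R, checks=False), method="ward")
    cuts = cut_tree(Z)  # shape (n, n): column j has n - j clusters
    n = len(tfs)

    levels = []  # (level_index, max_size, Q, membership)
    for j in range(n):
        labels = cuts[:, j]
        membership = {tf: int(lab) for tf, lab in zip(tfs, labels)}
        sizes = np.bincount(labels)
        q = modularity(network, membership, nodes=tfs)
        levels.append((j, int(sizes.max()), q, membership))

    # S cut: maximum Q, ties toward smaller max size then finer cut
    s_level = min(levels, key=lambda t: (-round(t[2], 12), t[1], t[0]))
    s_j, s_max, _, s_membership = s_level

    coarser = [t for t in levels if t[0] >= s_j]
    coarser.sort(key=lambda t: t[0])
    xs = np.array([t[1] for t in coarser])
    ys = np.array([t[2] for t in coarser])
    l_level = coarser[_elbow_index(xs, ys)]
    _, l_max, _, l_membership = l_level

    curve = sorted({(t[1], round(t[2], 12)) for t in levels})

    # attach singleton modules for TFs that were excluded from the walk
    all_tfs = sorted(network.tf_nodes())
    next_s = max(s_membership.values(), default=-1) + 1
    next_l = max(l_membership.values(), default=-1) + 1
    s_module_of = dict(s_membership)
    l_module_of = dict(l_membership)
    for tf in all_tfs:
        if tf not in s_module_of:
            s_module_of[tf] = next_s
            l_module_of[tf] = next_l
            next_s += 1
            next_l += 1
    return ModuleAssignment(
        s_module_of=s_module_of,
        l_module_of=l_module_of,
        S_max=s_max,
        L_max=l_max,
        modularity_curve=[(int(a), float(b)) for a, b in curve],
    )


@dataclass(frozen=True)
class ModuleFeature:
    """One module-level PPI feature and the TF-level PPIs it aggregates.

    ``constituents`` are ordered (enhancer-TF, promoter-TF) pairs.  Intra
    features are un-directional (both orders included); inter features are
    directional, one per ordered module pair.
    """

    feature_id: str
    layer: str          # "S" or "L"
    kind: str           # "intra" or "inter"
    modules: tuple[int, ...]
    constituents: tuple[tuple[str, str], ...]


@dataclass
class ModuleFeatureCatalog:
    features: list[ModuleFeature]
    assignment: ModuleAssignment

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def by_id(self, feature_id: str) -> ModuleFeature:
        if not hasattr(self, "_idx"):
            self._idx = {f.feature_id: f for f in self.features}
        return self._idx[feature_id]

    def directional_pairs(self) -> list[tuple[str, str]]:
        """(a->b, b->a) inter-module feature id pairs, each pair listed once."""
        ids = set(self.feature_ids)
        pairs = []
        for f in self.features:
            if f.kind != "inter":
                continue
            a, b = f.modules
            if a < b:
                other = f"{f.layer}{b}>{f.layer}{a}"
                if other in ids:
                    pairs.append((f.feature_id, other))
        return pairs

    def features_of_tf_pair(self, tf_enh: str, tf_prom: str) -> list[str]:
        """Module-level feature ids (one per layer) for an ordered TF pair."""
        out = []
        for layer, module_of in (("S", self.assignment.s_module_of),
                                 ("L", self.assignment.l_module_of)):
            ma = module_of.get(tf_enh)
            mb = module_of.get(tf_prom)
            if ma is None or mb is None:
                continue
            fid = f"{layer}{ma}" if ma == mb else f"{layer}{ma}>{layer}{mb}"
            out.append(fid)
        return out


def module_feature_catalog(
    assignment: ModuleAssignment, network: PPINetwork
) -> ModuleFeatureCatalog:
    """Enumerate intra- and inter-module features backed by >=1 TF-TF PPI.

    Intra features exist for every S/L module with an internal TF-TF edge
    (homotypic self-PPIs count).  Inter features exist for every ordered
    module pair bridged by a PPI and are split by direction.
    """
    graph = network.graph
    features: list[ModuleFeature] = []
    for layer, module_of in (("S", assignment.s_module_of),
                             ("L", assignment.l_module_of)):
        members = _invert(module_of)
        tf_set = set(module_of)
        intra: dict[int, list[tuple[str, str]]] = {}
        inter: dict[tuple[int, int], list[tuple[str, str]]] = {}
        for a, b in graph.edges:
            if a not in tf_set or b not in tf_set:
                continue
            ma, mb = module_of[a], module_of[b]
            if ma == mb:
                if a == b:
                    intra.setdefault(ma, []).append((a, a))
                else:
                    intra.setdefault(ma, []).extend([(a, b), (b, a)])
            else:
                inter.setdefault((ma, mb), []).append((a, b))
                inter.setdefault((mb, ma), []).append((b, a))
        for m in sorted(intra):
            features.append(ModuleFeature(
                feature_id=f"{layer}{m}", layer=layer, kind="intra",
                modules=(m,), constituents=tuple(sorted(set(intra[m]))),
            ))
        for (ma, mb) in sorted(inter):
            features.append(ModuleFeature(
                feature_id=f"{layer}{ma}>{layer}{mb}", layer=layer, kind="inter",
                modules=(ma, mb), constituents=tuple(sorted(set(inter[(ma, mb)]))),
            ))
    return ModuleFeatureCatalog(features=features, assignment=assignment)


def detect_modules(
    network: PPINetwork, p: int = DEFAULT_WALK_STEPS
) -> tuple[ModuleAssignment, ModuleFeatureCatalog]:
    """Full pipeline: walk -> distances -> Ward cuts -> feature catalog."""
    nodes, T = transition_matrix(network, p=p)
    rwd = rw_distance(nodes, T, sorted(network.tf_nodes()), p=p)
    assignment = hierarchical_modules(rwd, network)
    catalog = module_feature_catalog(assignment, network)
    return assignment, catalog
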