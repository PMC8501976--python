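"""Domain types and plain-text readers/writers for the genomic input formats.

All coordinates in memory are 0-based half-open (BED convention) regardless of
the source dialect.  Promoters are symmetric +/-1 kb windows around the TSS,
clipped at the chromosome start; the window is not strand-shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_HALF_WIDTH = 1000

#: TF families whose intratypic dimer PPIs are removed from the network:
#: these factors co-bind locally as dimers rather than bridging distal sites.
DEFAULT_EXCLUDED_FAMILIES = frozenset({"NR", "bHLH", "bZIP"})


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class ValidationError(ValueError):
    """Input parsed but violated a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``summit`` (narrowPeak peaks only) is an offset within the interval.
    Extra BED columns are preserved in ``attrs``.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    summit: int | None = None
    attrs: tuple = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValidationError(
                f"end <= start in {self.chrom}:{self.start}-{self.end} ({self.id!r})"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValidationError(f"summit offset {self.summit} outside peak {self.id!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp intersection on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene anchored at its TSS; the promoter is tss +/- 1 kb, clipped at 0."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS")

    @property
    def promoter(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            max(0, self.tss - PROMOTER_HALF_WIDTH),
            self.tss + PROMOTER_HALF_WIDTH,
            id=f"promoter:{self.gene_id}",
        )


@dataclass
class TFPeakSet:
    """ChIP-seq peaks of one TF, each carrying a summit offset."""

    tf_name: str
    peaks: list[GenomicInterval]


@dataclass
class ContactSet:
    """Intra-chromosomal contact anchors, canonically ordered by start."""

    anchors: list[tuple[GenomicInterval, GenomicInterval]]
    source_tag: str = ""
    n_dropped_interchromosomal: int = 0

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class PPINetwork:
    """Weighted undirected PPI graph over TF and non-TF proteins.

    Node attributes: ``is_tf`` (has a ChIP-seq peak set in the cell-type) and
    ``is_expressed``.  Edge attribute ``weight`` is the confidence score.
    """

    graph: nx.Graph
    excluded_families: frozenset = DEFAULT_EXCLUDED_FAMILIES

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def tf_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("is_tf", False)]

    def has_ppi(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def set_tf_flags(self, tf_names: Iterable[str]) -> None:
        tf_set = set(tf_names)
        for n in self.graph.nodes:
            self.graph.nodes[n]["is_tf"] = n in tf_set

    def degree_sequence(self) -> dict[str, int]:
        return dict(self.graph.degree())


@dataclass
class GenomeAnnotation:
    """Enhancers, genes, TADs and per-TF peak sets on one coordinate system."""

    chrom_lengths: dict[str, int]
    tads: list[GenomicInterval]
    enhancers: list[GenomicInterval]
    genes: list[Gene]
    peaks: dict[str, TFPeakSet] = field(default_factory=dict)
    activity: pd.DataFrame | None = None   # enhancer x cell-type
    expression: pd.DataFrame | None = None  # gene x cell-type

    def enhancer_by_id(self, eid: str) -> GenomicInterval:
        return self._enh_index()[eid]

    def gene_by_id(self, gid: str) -> Gene:
        return self._gene_index()[gid]

    def _enh_index(self) -> dict[str, GenomicInterval]:
        if not hasattr(self, "_enh_idx"):
            self._enh_idx = {e.id: e for e in self.enhancers}
        return self._enh_idx

    def _gene_index(self) -> dict[str, Gene]:
        if not hasattr(self, "_gene_idx"):
            self._gene_idx = {g.gene_id: g for g in self.genes}
        return self._gene_idx

    def tad_of(self, chrom: str, pos: int) -> str | None:
        """TAD id containing ``pos``, or None if outside every TAD."""
        if not hasattr(self, "_tad_idx"):
            self._tad_idx = {}
            for t in self.tads:
                self._tad_idx.setdefault(t.chrom, []).append(t)
        for t in self._tad_idx.get(chrom, ()):
            if t.start <= pos < t.end:
                return t.id
        return None


def overlap_any(starts_a, ends_a, starts_b, ends_b):
    """Boolean vector over the ``a`` intervals: overlaps any ``b`` interval.

    All arrays are positions on one chromosome, half-open convention.
    """
    import numpy as np

    sa = np.asarray(starts_a)[:, None]
    ea = np.asarray(ends_a)[:, None]
    sb = np.asarray(starts_b)[None, :]
    eb = np.asarray(ends_b)[None, :]
    if sb.size == 0 or sa.size == 0:
        return np.zeros(sa.shape[0], dtype=bool)
    return ((sa < eb) & (ea > sb)).any(axis=1)


# ---------------------------------------------------------------------------
# readers / writers


def _split_line(line: str, path: str, lineno: int, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise ParseError(f"{path}:{lineno}: expected >={min_cols} columns, got {len(fields)}")
    return fields


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, preserving file order and extra columns."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, path, lineno, 3)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, attrs=tuple(fields[4:]))
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.id, *iv.attrs]
            fh.write("\t".join(cols) + "\n")


def read_narrowpeak(path: str, tf_name: str) -> TFPeakSet:
    """Read an ENCODE narrowPeak file (10 columns; column 10 = summit offset).

    A summit offset of -1 (unknown) is replaced by the floor midpoint offset.
    """
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            start, end = int(fields[1]), int(fields[2])
            summit = int(fields[9])
            if summit == -1:
                summit = (end - start) // 2
            peaks.append(
                GenomicInterval(fields[0], start, end, fields[3], summit=summit)
            )
    return TFPeakSet(tf_name=tf_name, peaks=peaks)


def write_narrowpeak(peak_set: TFPeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for p in peak_set.peaks:
            fh.write(
                "\t".join(
                    [p.chrom, str(p.start), str(p.end), p.id, "0", ".",
                     "0", "-1", "-1", str(p.summit if p.summit is not None else -1)]
                )
                + "\n"
            )


def read_bedpe(path: str, source_tag: str = "") -> ContactSet:
    """Read a BEDPE contact file; inter-chromosomal rows are dropped (counted)."""
    anchors: list[tuple[GenomicInterval, GenomicInterval]] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line, path, lineno, 6)
            c1, s1, e1, c2, s2, e2 = fields[:6]
            if c1 != c2:
                n_dropped += 1
                continue
            a = GenomicInterval(c1, int(s1), int(e1), id=f"{path}:{lineno}:a")
            b = GenomicInterval(c2, int(s2), int(e2), id=f"{path}:{lineno}:b")
            if b.start < a.start:
                a, b = b, a
            anchors.append((a, b))
    if n_dropped:
        logger.info("read_bedpe(%s): dropped %d inter-chromosomal rows", path, n_dropped)
    return ContactSet(anchors=anchors, source_tag=source_tag or path,
                      n_dropped_interchromosomal=n_dropped)


def write_bedpe(contacts: ContactSet, path: str) -> None:
    with open(path, "w") as fh:
        for a, b in contacts.anchors:
            fh.write(
                "\t".join([a.chrom, str(a.start), str(a.end),
                           b.chrom, str(b.start), str(b.end)]) + "\n"
            )


def read_ppi_edges(
    path: str,
    min_score: float = 100,
    family_of: Mapping[str, str] | None = None,
    excluded_families: Iterable[str] = DEFAULT_EXCLUDED_FAMILIES,
) -> PPINetwork:
    """Read a TSV PPI edge list (proteinA, proteinB, score) into a network.

    Edges with score <= ``min_score`` are removed (the retention rule is a
    strict "greater than").  Edges whose two endpoints belong to the same
    excluded family (intratypic dimers) are removed.  Duplicate rows collapse
    keeping the maximum score.
    """
    family_of = family_of or {}
    excluded = frozenset(excluded_families)
    graph = nx.Graph()
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, path, lineno, 3)
            if first:
                first = False
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header row
            a, b = fields[0], fields[1]
            score = float(fields[2])
            if score < 0:
                raise ValidationError(f"{path}:{lineno}: negative PPI score {score}")
            if score <= min_score:
                continue
            fam_a, fam_b = family_of.get(a), family_of.get(b)
            if fam_a is not None and fam_a == fam_b and fam_a in excluded:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["weight"] = max(graph[a][b]["weight"], score)
            else:
                graph.add_edge(a, b, weight=score)
    for n in graph.nodes:
        graph.nodes[n].setdefault("is_tf", False)
        graph.nodes[n].setdefault("is_expressed", True)
    return PPINetwork(graph=graph, excluded_families=excluded)


def write_ppi_edges(network: PPINetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("proteinA\tproteinB\tscore\n")
        for a, b, d in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']:g}\n")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    """Read a row-id x cell-type TSV matrix; empty cells become NaN (not 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dups[:5]}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_gene_table(path: str) -> list[Gene]:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return [
        Gene(gene_id=row.gene_id, chrom=row.chrom, tss=int(row.tss), strand=row.strand)
        for row in df.itertuples()
    ]


def write_gene_table(genes: Sequence[Gene], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_peak_manifest(path: str) -> dict[str, TFPeakSet]:
    """Read a TSV manifest mapping tf_name -> narrowPeak path (relative to it)."""
    import os

    base = os.path.dirname(os.path.abspath(path))
    peak_sets: dict[str, TFPeakSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("tf_name"):
                continue
            fields = _split_line(line, path, lineno, 2)
            tf, peak_path = fields[0], fields[1]
            if not os.path.isabs(peak_path):
                peak_path = os.path.join(base, peak_path)
            peak_sets[tf] = read_narrowpeak(peak_path, tf)
    return peak_sets
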