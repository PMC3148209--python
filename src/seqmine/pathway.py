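"""Pathway-distance association between SNP-harbouring genes and DEGs.

Directed pathway graphs (e.g. parsed from KEGG) are merged into one graph
G of N gene nodes.  The all-pairs shortest-path matrix d over unit-weight
edges gives the test statistic: the distance from the SNP gene to the DEG,
with unreachable pairs set to N.  Its significance is the fraction of all
ordered gene pairs at least as close:

    p = |{(i, j) : d[i][j] <= d[gSNP][gDEG]}| / N**2

so a cis pair (gSNP = gDEG, distance 0) is the most significant possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

#: background pairs include the diagonal, making the cis case well defined
INCLUDE_DIAGONAL = True


@dataclass
class PathwayDistanceMatrix:
    """All-pairs shortest directed distances; unreachable entries equal N."""

    nodes: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self._pos = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def distance(self, source: str, target: str) -> int:
        for g in (source, target):
            if g not in self._pos:
                raise KeyError(f"gene {g!r} not in the pathway graph")
        return int(self.d[self._pos[source], self._pos[target]])


@dataclass
class SnpDegAssociation:
    gsnp: str
    gdeg: str
    distance: int
    pvalue: float


def merge_pathways(edge_lists) -> nx.DiGraph:
    """Union a collection of directed edge lists into one graph.

    Each element is an iterable of (source, target) pairs; duplicate edges
    collapse.  Isolated nodes may be added afterwards with ``add_node``.
    """
    edge_lists = list(edge_lists)
    if not edge_lists:
        raise ValueError("at least one pathway required")
    g = nx.DiGraph()
    for edges in edge_lists:
        for u, v in edges:
            g.add_edge(u, v)
    return g


def read_edge_list(path: str) -> list[tuple[str, str]]:
    """Read a two-column source<TAB>target edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"edge line needs 2 genes: {line!r}")
            edges.append((fields[0], fields[1]))
    return edges


def read_kgml(path: str) -> list[tuple[str, str]]:
    """Reduce a KGML pathway file to directed gene->gene edges.

    Gene entries may name several genes (space-separated KEGG ids); a
    relation between two entries yields one edge per gene pair.  Relation
    subtypes (activation, inhibition, ...) are ignored — only topology is
    kept.  Group entries and non-gene entries (compounds, maps) contribute
    no edges.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    genes: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        if entry.get("type") == "gene":
            genes[entry.get("id")] = entry.get("name", "").split()
    edges = []
    for rel in root.iter("relation"):
        for u in genes.get(rel.get("entry1"), []):
            for v in genes.get(rel.get("entry2"), []):
                if u != v:
                    edges.append((u, v))
    return edges


def all_pairs_distances(g: nx.DiGraph) -> PathwayDistanceMatrix:
    """Exact shortest directed path lengths between every ordered gene pair.

    Unit edge weights; unreachable pairs are set to N (the node count).
    Computed with Johnson's all-pairs algorithm, which reduces to
    per-source BFS on unit weights.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), n, dtype=np.int64)
    np.fill_diagonal(d, 0)
    if g.number_of_edges():
        for src, lengths in nx.johnson(g, weight="weight").items():
            i = pos[src]
            for tgt, path in lengths.items():
                d[i, pos[tgt]] = len(path) - 1
    return PathwayDistanceMatrix(nodes=nodes, d=d)


def snp_deg_pvalue(gsnp: str, gdeg: str, dm: PathwayDistanceMatrix
                   ) -> SnpDegAssociation:
    """Distance-based association p-value for a (gSNP, gDEG) pair.

    The background is every ordered pair of the matrix (diagonal included);
    ties count as at least as extreme, so the p-value is never 0 and equals
    1 for unreachable pairs.
    """
    dist = dm.distance(gsnp, gdeg)
    d = dm.d
    if INCLUDE_DIAGONAL:
        count = int((d <= dist).sum())
        total = dm.n ** 2
    else:
        off = ~np.eye(dm.n, dtype=bool)
        count = int((d[off] <= dist).sum())
        total = dm.n ** 2 - dm.n
    return SnpDegAssociation(gsnp=gsnp, gdeg=gdeg, distance=dist,
                             pvalue=count / total)
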