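"""The 52-descriptor structure/complexity profile of a NIP.

The profile has 25 basic descriptors drawn from four notions — degree,
distance, centrality and cliques — plus 27 information-theoretic
derivatives: the Average (A.I.), Normalized (N.I.) and Total (T.I.)
Information of nine equivalence distributions obtained by partitioning
graph elements into classes of equal value of an integer-valued quantity
(degrees, strengths, edge weights, distance sums, eccentricities, pairwise
distances, clique sizes, clique memberships, triangle counts).

Conventions used throughout:

* weighted shortest-path length of an edge is the reciprocal of its weight
  (more metabolites exchanged = shorter effective distance);
* disconnected graphs are allowed — distances are averaged over reachable
  pairs, eccentricities are taken within components, and closeness is the
  harmonic form ``C(v) = (1/(n-1)) * sum 1/d(v,u)`` with ``1/inf = 0``;
* betweenness is normalized by the number of vertex pairs excluding the
  element's endpoints ((n-1)(n-2)/2 for vertices, n(n-1)/2 for edges);
* weighted clustering follows Barrat,
  ``C_w(i) = 1/(s_i (k_i - 1)) * sum_{(j,h)} (w_ij + w_ih)/2`` over ordered
  neighbour pairs closing a triangle at ``i``;
* descriptors that are undefined on a graph (e.g. average distance with no
  reachable pair, information over an empty distribution) are NaN.

Heavy traversals (all-pairs shortest paths, betweenness, maximal cliques)
run on an igraph view of the NIP; results are re-keyed to pathway ids in
canonical lexicographic order.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .nip_core import NIP

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorSpec",
    "REGISTRY",
    "DESCRIPTOR_IDS",
    "DescriptorVector",
    "distance_matrix",
    "betweenness",
    "closeness",
    "clustering",
    "maximal_cliques",
    "information_index",
    "compute_descriptor_vector",
    "compute_descriptor_table",
    "write_descriptor_table",
    "read_descriptor_table",
]


@dataclass(frozen=True)
class DescriptorSpec:
    id: str
    name: str
    category: str  # degree | distance | centrality | clique | information
    weighted: bool
    basic: bool


_BASIC = [
    # degree / adjacency (9)
    ("n_vertices", "number of vertices", "degree", False),
    ("n_edges", "number of edges", "degree", False),
    ("total_adjacency", "total adjacency (sum of degrees)", "degree", False),
    ("avg_degree", "average vertex degree", "degree", False),
    ("degree_range", "vertex degree range", "degree", False),
    ("connectedness", "connectedness (density)", "degree", False),
    ("total_weight", "total edge weight", "degree", True),
    ("avg_strength", "average vertex strength", "degree", True),
    ("strength_range", "vertex strength range", "degree", True),
    # distance (6)
    ("radius", "network radius", "distance", False),
    ("diameter", "network diameter", "distance", False),
    ("total_distance", "total graph distance", "distance", False),
    ("avg_distance", "average distance between vertices", "distance", False),
    ("node_distance_range", "vertex distance-sum range", "distance", False),
    ("weighted_avg_distance", "weighted average distance", "distance", True),
    # centrality (6)
    ("avg_degree_centrality", "average degree centrality", "centrality", False),
    ("avg_closeness", "average harmonic closeness centrality", "centrality", False),
    ("avg_vertex_betweenness", "average vertex betweenness", "centrality", False),
    ("avg_edge_betweenness", "average edge betweenness", "centrality", False),
    ("weighted_avg_vertex_betweenness", "average weighted vertex betweenness", "centrality", True),
    ("weighted_avg_edge_betweenness", "average weighted edge betweenness", "centrality", True),
    # cliques / clustering (4)
    ("avg_clustering", "average clustering coefficient", "clique", False),
    ("weighted_avg_clustering", "average weighted (Barrat) clustering", "clique", True),
    ("n_maximal_cliques", "number of maximal cliques", "clique", False),
    ("max_clique_size", "maximum clique size", "clique", False),
]

# The nine integer-valued equivalence distributions feeding A.I./N.I./T.I.
DISTRIBUTIONS = (
    "degrees",
    "strengths",
    "edge_weights",
    "distance_sums",
    "eccentricities",
    "distances",
    "clique_sizes",
    "clique_membership",
    "triangles",
)

REGISTRY: list[DescriptorSpec] = [
    DescriptorSpec(i, n, c, w, True) for i, n, c, w in _BASIC
]
for _dist in DISTRIBUTIONS:
    for _v in ("ai", "ni", "ti"):
        REGISTRY.append(
            DescriptorSpec(
                f"{_v}_{_dist}",
                f"{_v.upper()} of the {_dist.replace('_', ' ')} distribution",
                "information",
                _dist in ("strengths", "edge_weights"),
                False,
            )
        )
assert len(REGISTRY) == 52
DESCRIPTOR_IDS = [spec.id for spec in REGISTRY]


@dataclass
class DescriptorVector:
    """All 52 descriptor values for one NIP (NaN where undefined)."""

    taxon_id: str
    values: dict[str, float]

    def to_series(self) -> pd.Series:
        return pd.Series(
            [self.values[i] for i in DESCRIPTOR_IDS], index=DESCRIPTOR_IDS, name=self.taxon_id
        )


# ---------------------------------------------------------------------------
# igraph view


class _GraphView:
    """One-time conversion of a NIP into numpy/igraph structures."""

    def __init__(self, nip: NIP):
        self.nodes = nip.nodes()
        self.n = len(self.nodes)
        index = {v: i for i, v in enumerate(self.nodes)}
        self.edges = sorted(
            (min(index[a], index[b]), max(index[a], index[b]))
            for a, b in nip.graph.edges
        )
        self.weights = np.array(
            [nip.weight(self.nodes[a], self.nodes[b]) for a, b in self.edges], dtype=float
        )
        self.g = ig.Graph(n=self.n, edges=self.edges)
        self.lengths = 1.0 / self.weights if len(self.weights) else self.weights
        self.A = np.zeros((self.n, self.n))
        self.W = np.zeros((self.n, self.n))
        for (a, b), w in zip(self.edges, self.weights):
            self.A[a, b] = self.A[b, a] = 1.0
            self.W[a, b] = self.W[b, a] = w

    def dist(self, weighted: bool) -> np.ndarray:
        key = "_dist_w" if weighted else "_dist_u"
        if not hasattr(self, key):
            if self.n == 0:
                d = np.zeros((0, 0))
            else:
                d = np.array(
                    self.g.distances(weights=list(self.lengths) if weighted else None),
                    dtype=float,
                )
            setattr(self, key, d)
        return getattr(self, key)

    def cliques(self) -> list[tuple[int, ...]]:
        if not hasattr(self, "_cliques"):
            self._cliques = sorted(
                tuple(sorted(c)) for c in self.g.maximal_cliques()
            )
        return self._cliques


# ---------------------------------------------------------------------------
# individual operations (public API keyed by pathway id)


def distance_matrix(nip: NIP, weighted: bool = False) -> pd.DataFrame:
    """Pairwise shortest-path distances (hop counts, or reciprocal-weight
    lengths when ``weighted``); unreachable pairs are ``inf``."""
    view = _GraphView(nip)
    return pd.DataFrame(view.dist(weighted), index=view.nodes, columns=view.nodes)


def betweenness(nip: NIP, element: str = "vertex", weighted: bool = False):
    """Normalized shortest-path betweenness for vertices or edges.

    Vertex values are divided by (n-1)(n-2)/2, edge values by n(n-1)/2, so a
    vertex all shortest paths pass through scores 1. Equal-length shortest
    paths split the contribution evenly.
    """
    view = _GraphView(nip)
    w = list(view.lengths) if weighted else None
    if element == "vertex":
        raw = np.array(view.g.betweenness(weights=w)) if view.n else np.array([])
        denom = (view.n - 1) * (view.n - 2) / 2
        vals = raw / denom if denom > 0 else raw * 0.0
        return dict(zip(view.nodes, vals))
    if element == "edge":
        raw = np.array(view.g.edge_betweenness(weights=w)) if view.edges else np.array([])
        denom = view.n * (view.n - 1) / 2
        vals = raw / denom if denom > 0 else raw * 0.0
        return {
            (view.nodes[a], view.nodes[b]): v for (a, b), v in zip(view.edges, vals)
        }
    raise ValueError(f"element must be 'vertex' or 'edge', got {element!r}")


def closeness(nip: NIP, weighted: bool = False) -> dict[str, float]:
    """Harmonic closeness ``C(v) = (1/(n-1)) sum_{u != v} 1/d(v,u)``.

    Well defined on disconnected graphs (unreachable vertices contribute 0);
    a single-vertex graph has closeness 0 by convention.
    """
    view = _GraphView(nip)
    if view.n <= 1:
        return {v: 0.0 for v in view.nodes}
    d = view.dist(weighted).copy()
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        vals = (1.0 / d).sum(axis=1) / (view.n - 1)
    return dict(zip(view.nodes, vals))


def clustering(nip: NIP, weighted: bool = False) -> dict[str, float]:
    """Local clustering coefficient; the weighted form is Barrat's.

    Vertices of degree < 2 have coefficient 0.
    """
    view = _GraphView(nip)
    out = {}
    deg = view.A.sum(axis=1)
    strength = view.W.sum(axis=1)
    for i, v in enumerate(view.nodes):
        k = deg[i]
        if k < 2:
            out[v] = 0.0
            continue
        a = view.A[i]
        if weighted:
            # sum over ordered neighbour pairs (j, h) with j~h of (w_ij+w_ih)/2
            s_ord = float((a * view.W[i]) @ view.A @ a)
            out[v] = s_ord / (strength[i] * (k - 1))
        else:
            triangles = float(a @ view.A @ a) / 2.0
            out[v] = triangles / (k * (k - 1) / 2.0)
    return out


def maximal_cliques(nip: NIP) -> list[tuple[str, ...]]:
    """All maximal cliques (isolated vertices count as singleton cliques),
    in deterministic sorted order."""
    view = _GraphView(nip)
    return sorted(
        tuple(sorted(view.nodes[i] for i in c)) for c in view.cliques()
    )


def information_index(class_sizes: Iterable[int], variant: str) -> float:
    """Shannon-type information of a partition into equivalence classes.

    For class sizes ``n_1..n_k`` over ``N = sum n_i`` elements:
    ``AI = -sum (n_i/N) log2 (n_i/N)``; ``TI = N log2 N - sum n_i log2 n_i``;
    ``NI = AI / log2 N`` (0 when N = 1).
    """
    sizes = [int(s) for s in class_sizes]
    if not sizes or any(s <= 0 for s in sizes):
        raise ValueError("class sizes must be positive integers")
    n_total = sum(sizes)
    ai = -sum((s / n_total) * math.log2(s / n_total) for s in sizes)
    variant = variant.lower()
    if variant == "ai":
        return ai
    if variant == "ti":
        return n_total * math.log2(n_total) - sum(s * math.log2(s) for s in sizes)
    if variant == "ni":
        return 0.0 if n_total == 1 else ai / math.log2(n_total)
    raise ValueError(f"variant must be one of 'ai', 'ni', 'ti', got {variant!r}")


def _class_sizes(values: Sequence) -> list[int]:
    """Partition a value multiset into equal-value equivalence classes."""
    sizes: dict = {}
    for v in values:
        sizes[v] = sizes.get(v, 0) + 1
    return [sizes[k] for k in sorted(sizes)]


def _info_triplet(values: Sequence) -> tuple[float, float, float]:
    if len(values) == 0:
        return (math.nan, math.nan, math.nan)
    sizes = _class_sizes(values)
    return tuple(information_index(sizes, v) for v in ("ai", "ni", "ti"))


# ---------------------------------------------------------------------------
# full vector


def compute_descriptor_vector(nip: NIP) -> DescriptorVector:
    """Evaluate all 52 descriptors on one NIP.

    An empty graph yields an all-NaN vector (with a warning); quantities
    undefined on a particular graph (see module docstring) are NaN.
    """
    view = _GraphView(nip)
    n = view.n
    if n == 0:
        warnings.warn(f"NIP {nip.taxon_id!r} is empty; all descriptors are NaN")
        return DescriptorVector(nip.taxon_id, {i: math.nan for i in DESCRIPTOR_IDS})

    vals: dict[str, float] = {}
    deg = view.A.sum(axis=1)
    strength = view.W.sum(axis=1)
    m = len(view.edges)

    vals["n_vertices"] = float(n)
    vals["n_edges"] = float(m)
    vals["total_adjacency"] = float(deg.sum())
    vals["avg_degree"] = float(deg.mean())
    vals["degree_range"] = float(deg.max() - deg.min())
    vals["connectedness"] = 2.0 * m / (n * (n - 1)) if n > 1 else math.nan
    vals["total_weight"] = float(view.weights.sum())
    vals["avg_strength"] = float(strength.mean())
    vals["strength_range"] = float(strength.max() - strength.min())

    d = view.dist(False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    ecc = np.where(finite, d, 0.0).max(axis=1) if n else np.zeros(0)  # within components
    dist_sums = np.where(finite, d, 0.0).sum(axis=1)
    n_pairs = int(finite.sum()) // 2  # unordered reachable pairs
    vals["radius"] = float(ecc.min())
    vals["diameter"] = float(ecc.max())
    vals["total_distance"] = float(np.where(finite, d, 0.0).sum() / 2.0)
    vals["avg_distance"] = vals["total_distance"] / n_pairs if n_pairs else math.nan
    vals["node_distance_range"] = float(dist_sums.max() - dist_sums.min())
    dw = view.dist(True)
    finite_w = np.isfinite(dw) & off
    vals["weighted_avg_distance"] = (
        float(np.where(finite_w, dw, 0.0).sum() / 2.0) / n_pairs if n_pairs else math.nan
    )

    vals["avg_degree_centrality"] = float((deg / (n - 1)).mean()) if n > 1 else math.nan
    vals["avg_closeness"] = float(np.mean(list(closeness(nip).values())))
    for key, element, weighted in (
        ("avg_vertex_betweenness", "vertex", False),
        ("weighted_avg_vertex_betweenness", "vertex", True),
    ):
        vals[key] = float(np.mean(list(betweenness(nip, element, weighted).values())))
    for key, weighted in (
        ("avg_edge_betweenness", False),
        ("weighted_avg_edge_betweenness", True),
    ):
        eb = betweenness(nip, "edge", weighted)
        vals[key] = float(np.mean(list(eb.values()))) if eb else math.nan

    vals["avg_clustering"] = float(np.mean(list(clustering(nip, False).values())))
    vals["weighted_avg_clustering"] = float(np.mean(list(clustering(nip, True).values())))
    cliques = view.cliques()
    clique_sizes = [len(c) for c in cliques]
    vals["n_maximal_cliques"] = float(len(cliques))
    vals["max_clique_size"] = float(max(clique_sizes))

    membership = np.zeros(n, dtype=int)
    for c in cliques:
        for i in c:
            membership[i] += 1
    triangles = (np.linalg.matrix_power(view.A, 3).diagonal() / 2.0).round().astype(int)

    dist_values = d[np.triu(finite)].astype(int)
    dists = {
        "degrees": deg.astype(int),
        "strengths": strength.astype(int),
        "edge_weights": view.weights.astype(int),
        "distance_sums": dist_sums.astype(int),
        "eccentricities": ecc.astype(int),
        "distances": dist_values,
        "clique_sizes": clique_sizes,
        "clique_membership": membership,
        "triangles": triangles,
    }
    for name in DISTRIBUTIONS:
        ai, ni, ti = _info_triplet(list(dists[name]))
        vals[f"ai_{name}"], vals[f"ni_{name}"], vals[f"ti_{name}"] = ai, ni, ti

    return DescriptorVector(nip.taxon_id, vals)


def compute_descriptor_table(nips: Mapping[str, NIP] | Iterable[NIP]) -> pd.DataFrame:
    """Descriptor vectors for many NIPs as a taxa x 52 DataFrame in registry
    column order."""
    if isinstance(nips, Mapping):
        nips = [nips[k] for k in sorted(nips)]
    rows = [compute_descriptor_vector(nip).to_series() for nip in nips]
    table = pd.DataFrame(rows)
    table.index.name = "taxon_id"
    return table


def write_descriptor_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.12g")


def read_descriptor_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="taxon_id")
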