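"""Construction and serialization of Networks of Interacting Pathways (NIPs).

A NIP summarizes one taxon's metabolism at the pathway level: vertices are
metabolic pathways, and two pathways are joined by an undirected edge when
they share at least one metabolite, the edge weight counting the shared
metabolites (the intensity of potential cross-talk between the two
pathways). Isolated pathways are kept as vertices: a pathway with no
metabolite overlap still contributes to network size and to the
information-theoretic descriptors.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import networkx as nx

from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = ["NIP", "build_nip", "build_nips", "write_nip", "read_nip"]

UNCATEGORIZED = "uncategorized"


@dataclass
class NIP:
    """A weighted, undirected pathway-overlap graph for one taxon."""

    taxon_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        """Vertices in the canonical (lexicographic) order."""
        return sorted(self.graph.nodes)

    def weight(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["weight"]

    def category(self, pathway_id: str) -> str:
        return self.graph.nodes[pathway_id].get("category", UNCATEGORIZED)


def build_nip(
    taxon_annotation: Mapping[str, set[str]],
    categories: Mapping[str, str] | None = None,
    taxon_id: str = "",
) -> NIP:
    """Build the NIP of one taxon from its pathway -> metabolite-set map.

    Every unordered pathway pair with a non-empty metabolite intersection
    becomes an edge weighted by the intersection size. Pathways missing from
    ``categories`` are labeled ``uncategorized`` (with a warning).
    """
    categories = categories or {}
    g = nx.Graph(taxon_id=taxon_id)
    for pid in sorted(taxon_annotation):
        cat = categories.get(pid)
        if categories and cat is None:
            logger.warning("pathway %r has no category; using %r", pid, UNCATEGORIZED)
        g.add_node(pid, category=cat if cat is not None else UNCATEGORIZED)
    for a, b in combinations(sorted(taxon_annotation), 2):
        shared = len(taxon_annotation[a] & taxon_annotation[b])
        if shared:
            g.add_edge(a, b, weight=shared)
    return NIP(taxon_id=taxon_id, graph=g)


def build_nips(ann, categories: Mapping[str, str] | None = None) -> dict[str, NIP]:
    """Build one NIP per taxon of an AnnotationSet, keyed by taxon_id."""
    return {
        taxon_id: build_nip(ann.taxa[taxon_id], categories, taxon_id=taxon_id)
        for taxon_id in sorted(ann.taxa)
    }


def write_nip(nip: NIP, path) -> None:
    """Serialize a NIP to GraphML (``.graphml``) or an edge-list TSV dialect.

    The TSV dialect stores one ``# taxon:`` header line, one ``# vertex:``
    comment line per vertex (id and category), and one
    ``pathway_a<TAB>pathway_b<TAB>weight`` row per edge.
    """
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.Graph(nip.graph)
        g.graph["taxon_id"] = nip.taxon_id
        nx.write_graphml(g, path, named_key_ids=True)
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# taxon:\t{nip.taxon_id}\n")
        for v in nip.nodes():
            fh.write(f"# vertex:\t{v}\t{nip.category(v)}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a, b in sorted(tuple(sorted(e)) for e in nip.graph.edges):
            writer.writerow([a, b, nip.weight(a, b)])


def read_nip(path) -> NIP:
    """Inverse of :func:`write_nip`; validates that all weights are >= 1."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        taxon_id = g.graph.get("taxon_id", "")
        out = nx.Graph(taxon_id=taxon_id)
        for v, data in g.nodes(data=True):
            out.add_node(str(v), category=data.get("category", UNCATEGORIZED))
        for a, b, data in g.edges(data=True):
            w = data.get("weight")
            _check_weight(w, path)
            out.add_edge(str(a), str(b), weight=int(w))
        return NIP(taxon_id=taxon_id, graph=out)

    g = nx.Graph()
    taxon_id = ""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("# taxon:"):
                taxon_id = line.split("\t", 1)[1].strip() if "\t" in line else ""
                continue
            if line.startswith("# vertex:"):
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError("malformed vertex line", path=path, line=lineno)
                g.add_node(
                    parts[1].strip(),
                    category=parts[2].strip() if len(parts) > 2 else UNCATEGORIZED,
                )
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError("expected 3 tab-separated fields", path=path, line=lineno)
            a, b, w_raw = parts
            try:
                w = int(w_raw)
            except ValueError:
                raise ParseError(
                    f"weight {w_raw!r} is not an integer", path=path, line=lineno
                ) from None
            _check_weight(w, path, lineno)
            for v in (a, b):
                if v not in g:
                    g.add_node(v, category=UNCATEGORIZED)
            g.add_edge(a, b, weight=w)
    g.graph["taxon_id"] = taxon_id
    return NIP(taxon_id=taxon_id, graph=g)


def _check_weight(w, path, line=None):
    if w is None or float(w) <= 0:
        raise ParseError(f"edge weight must be a positive integer, got {w!r}", path=path, line=line)
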