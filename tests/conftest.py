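import numpy as np
import pytest

from nipevo.nip_core import NIP, build_nip

import networkx as nx


def make_nip(n, edges, taxon_id="t"):
    """NIP over vertices v00..v(n-1) from (i, j, w) index triples."""
    g = nx.Graph(taxon_id=taxon_id)
    names = [f"v{i:02d}" for i in range(n)]
    for name in names:
        g.add_node(name, category="uncategorized")
    for i, j, w in edges:
        g.add_edge(names[i], names[j], weight=int(w))
    return NIP(taxon_id=taxon_id, graph=g)


def random_graph(rng, n_max=30, dyadic=True):
    """Random weighted graph; dyadic weights keep 1/w exact in binary floats,
    so shortest-path ties are algorithm-independent."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.15, 0.6))
    weights = (1, 2, 4, 8, 16) if dyadic else tuple(range(1, 10))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j, int(rng.choice(weights))))
    return n, edges


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_annotation(tmp_path):
    """Three-taxon annotation files on disk, returned as (ann_path, taxa_path)."""
    ann = tmp_path / "annotations.tsv"
    taxa = tmp_path / "taxa.tsv"
    ann.write_text(
        "taxon_id\tpathway_id\tmetabolite_id\n"
        "t1\tP1\tm1\n"
        "t1\tP1\tm2\n"
        "t1\tP2\tm2\n"
        "t2\tP1\tm1\n"
        "t3\tP2\tm3\n"
    )
    taxa.write_text(
        "taxon_id\torf_count\tmotility\n"
        "t1\t1000\tmotile\n"
        "t2\t800\timmotile\n"
        "t3\t1200\t\n"
    )
    return ann, taxa
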