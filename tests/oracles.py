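"""Independent naive re-implementations used as test oracles.

Everything here is deliberately written from the definitions with the
slowest transparent algorithm available (Floyd-Warshall distances,
pair-by-pair path counting for betweenness, subset enumeration or
pivotless Bron-Kerbosch for cliques) and shares no code with the package.

Graphs are given as ``(n, edges)`` with ``edges`` a list of ``(i, j, w)``
tuples over vertex indices ``0..n-1``.
"""

from __future__ import annotations

import itertools
import math

INF = math.inf


def edge_lengths(edges, weighted):
    return [(i, j, (1.0 / w) if weighted else 1.0) for i, j, w in edges]


def floyd_warshall(n, edges, weighted=False):
    d = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
    for i, j, l in edge_lengths(edges, weighted):
        d[i][j] = min(d[i][j], l)
        d[j][i] = min(d[j][i], l)
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == INF:
                continue
            for j in range(n):
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return d


def shortest_path_counts(n, edges, weighted, dist):
    """sigma[s][v]: number of shortest s-v paths, by DP over distance order."""
    adj = {i: [] for i in range(n)}
    for i, j, l in edge_lengths(edges, weighted):
        adj[i].append((j, l))
        adj[j].append((i, l))
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        order = sorted((v for v in range(n) if dist[s][v] < INF), key=lambda v: dist[s][v])
        sigma[s][s] = 1
        for v in order:
            if v == s:
                continue
            total = 0
            for u, l in adj[v]:
                if dist[s][u] + l == dist[s][v]:
                    total += sigma[s][u]
            sigma[s][v] = total
    return sigma


def vertex_betweenness(n, edges, weighted=False):
    dist = floyd_warshall(n, edges, weighted)
    sigma = shortest_path_counts(n, edges, weighted, dist)
    raw = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s][t] == INF or sigma[s][t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    raw[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    denom = (n - 1) * (n - 2) / 2
    return [b / denom if denom > 0 else 0.0 for b in raw]


def edge_betweenness(n, edges, weighted=False):
    dist = floyd_warshall(n, edges, weighted)
    sigma = shortest_path_counts(n, edges, weighted, dist)
    lengths = edge_lengths(edges, weighted)
    raw = [0.0] * len(edges)
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s][t] == INF or sigma[s][t] == 0:
                continue
            for e, (i, j, l) in enumerate(lengths):
                contrib = 0.0
                if dist[s][i] + l + dist[j][t] == dist[s][t]:
                    contrib += sigma[s][i] * sigma[j][t]
                if dist[s][j] + l + dist[i][t] == dist[s][t]:
                    contrib += sigma[s][j] * sigma[i][t]
                raw[e] += contrib / sigma[s][t]
    denom = n * (n - 1) / 2
    return [b / denom if denom > 0 else 0.0 for b in raw]


def betweenness_by_path_enumeration(n, edges, weighted=False):
    """Vertex betweenness by literally enumerating all simple paths (tiny n)."""
    adj = {i: set() for i in range(n)}
    length = {}
    for i, j, l in edge_lengths(edges, weighted):
        adj[i].add(j)
        adj[j].add(i)
        length[(i, j)] = length[(j, i)] = l

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for u in sorted(adj[v]):
                if u not in path:
                    stack.append((u, path + [u]))
        return paths

    raw = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            plen = [sum(length[(p[k], p[k + 1])] for k in range(len(p) - 1)) for p in paths]
            best = min(plen)
            shortest = [p for p, l in zip(paths, plen) if l == best]
            for p in shortest:
                for v in p[1:-1]:
                    raw[v] += 1.0 / len(shortest)
    denom = (n - 1) * (n - 2) / 2
    return [b / denom if denom > 0 else 0.0 for b in raw]


def harmonic_closeness(n, edges, weighted=False):
    if n <= 1:
        return [0.0] * n
    dist = floyd_warshall(n, edges, weighted)
    return [
        sum(1.0 / dist[v][u] for u in range(n) if u != v and dist[v][u] < INF) / (n - 1)
        for v in range(n)
    ]


def clustering_unweighted(n, edges):
    adj = {i: set() for i in range(n)}
    for i, j, _ in edges:
        adj[i].add(j)
        adj[j].add(i)
    out = []
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            out.append(0.0)
            continue
        tri = sum(
            1 for a, b in itertools.combinations(sorted(adj[v]), 2) if b in adj[a]
        )
        out.append(tri / (k * (k - 1) / 2))
    return out


def clustering_barrat(n, edges):
    adj = {i: set() for i in range(n)}
    w = {}
    for i, j, wt in edges:
        adj[i].add(j)
        adj[j].add(i)
        w[(i, j)] = w[(j, i)] = wt
    out = []
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            out.append(0.0)
            continue
        s = sum(w[(v, u)] for u in adj[v])
        acc = 0.0
        for a, b in itertools.combinations(sorted(adj[v]), 2):
            if b in adj[a]:
                acc += (w[(v, a)] + w[(v, b)]) / 2.0
        out.append(2.0 * acc / (s * (k - 1)))  # unordered pairs -> x2 for ordered
    return out


def maximal_cliques_bruteforce(n, edges):
    """All maximal cliques by testing every vertex subset (n <= ~16)."""
    adj = {i: set() for i in range(n)}
    for i, j, _ in edges:
        adj[i].add(j)
        adj[j].add(i)

    def is_clique(sub):
        return all(b in adj[a] for a, b in itertools.combinations(sub, 2))

    cliques = []
    for r in range(1, n + 1):
        for sub in itertools.combinations(range(n), r):
            if not is_clique(sub):
                continue
            extendable = any(
                all(v in adj[u] for v in sub) for u in range(n) if u not in sub
            )
            if not extendable:
                cliques.append(tuple(sub))
    return sorted(cliques)


def maximal_cliques_bk(n, edges):
    """Bron-Kerbosch without pivoting (independent of igraph's pivoted variant)."""
    adj = {i: set() for i in range(n)}
    for i, j, _ in edges:
        adj[i].add(j)
        adj[j].add(i)
    out = []

    def expand(r, p, x):
        if not p and not x:
            out.append(tuple(sorted(r)))
            return
        for v in sorted(p):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(range(n)), set())
    return sorted(out)


def information(sizes, variant):
    total = sum(sizes)
    ai = -sum(s / total * math.log2(s / total) for s in sizes)
    if variant == "ai":
        return ai
    if variant == "ti":
        return total * math.log2(total) - sum(s * math.log2(s) for s in sizes)
    return 0.0 if total == 1 else ai / math.log2(total)


def _info_triplet(values):
    if not values:
        return (math.nan,) * 3
    sizes = {}
    for v in values:
        sizes[v] = sizes.get(v, 0) + 1
    return tuple(information(list(sizes.values()), v) for v in ("ai", "ni", "ti"))


def descriptor_vector(n, edges):
    """All 52 descriptors computed naively; mirrors the documented definitions."""
    vals = {}
    if n == 0:
        return vals
    deg = [0] * n
    strength = [0.0] * n
    for i, j, w in edges:
        deg[i] += 1
        deg[j] += 1
        strength[i] += w
        strength[j] += w
    m = len(edges)
    vals["n_vertices"] = float(n)
    vals["n_edges"] = float(m)
    vals["total_adjacency"] = float(sum(deg))
    vals["avg_degree"] = sum(deg) / n
    vals["degree_range"] = float(max(deg) - min(deg))
    vals["connectedness"] = 2.0 * m / (n * (n - 1)) if n > 1 else math.nan
    vals["total_weight"] = float(sum(w for *_, w in edges))
    vals["avg_strength"] = sum(strength) / n
    vals["strength_range"] = float(max(strength) - min(strength))

    d = floyd_warshall(n, edges, False)
    dw = floyd_warshall(n, edges, True)
    ecc = [max((d[v][u] for u in range(n) if u != v and d[v][u] < INF), default=0.0) for v in range(n)]
    dist_sums = [sum(d[v][u] for u in range(n) if u != v and d[v][u] < INF) for v in range(n)]
    pairs = [(s, t) for s in range(n) for t in range(s + 1, n) if d[s][t] < INF]
    vals["radius"] = float(min(ecc))
    vals["diameter"] = float(max(ecc))
    vals["total_distance"] = float(sum(d[s][t] for s, t in pairs))
    vals["avg_distance"] = vals["total_distance"] / len(pairs) if pairs else math.nan
    vals["node_distance_range"] = float(max(dist_sums) - min(dist_sums))
    vals["weighted_avg_distance"] = (
        sum(dw[s][t] for s, t in pairs) / len(pairs) if pairs else math.nan
    )

    vals["avg_degree_centrality"] = (
        sum(k / (n - 1) for k in deg) / n if n > 1 else math.nan
    )
    vals["avg_closeness"] = sum(harmonic_closeness(n, edges)) / n
    vals["avg_vertex_betweenness"] = sum(vertex_betweenness(n, edges, False)) / n
    vals["weighted_avg_vertex_betweenness"] = sum(vertex_betweenness(n, edges, True)) / n
    eb = edge_betweenness(n, edges, False)
    ebw = edge_betweenness(n, edges, True)
    vals["avg_edge_betweenness"] = sum(eb) / len(eb) if eb else math.nan
    vals["weighted_avg_edge_betweenness"] = sum(ebw) / len(ebw) if ebw else math.nan

    vals["avg_clustering"] = sum(clustering_unweighted(n, edges)) / n
    vals["weighted_avg_clustering"] = sum(clustering_barrat(n, edges)) / n
    cliques = maximal_cliques_bk(n, edges)
    vals["n_maximal_cliques"] = float(len(cliques))
    vals["max_clique_size"] = float(max(len(c) for c in cliques))

    membership = [0] * n
    for c in cliques:
        for v in c:
            membership[v] += 1
    adj = {i: set() for i in range(n)}
    for i, j, _ in edges:
        adj[i].add(j)
        adj[j].add(i)
    triangles = [
        sum(1 for a, b in itertools.combinations(sorted(adj[v]), 2) if b in adj[a])
        for v in range(n)
    ]
    dists = {
        "degrees": deg,
        "strengths": [int(s) for s in strength],
        "edge_weights": [int(w) for *_, w in edges],
        "distance_sums": [int(s) for s in dist_sums],
        "eccentricities": [int(e) for e in ecc],
        "distances": [int(d[s][t]) for s, t in pairs],
        "clique_sizes": [len(c) for c in cliques],
        "clique_membership": membership,
        "triangles": triangles,
    }
    for name, values in dists.items():
        ai, ni, ti = _info_triplet(list(values))
        vals[f"ai_{name}"], vals[f"ni_{name}"], vals[f"ti_{name}"] = ai, ni, ti
    return vals
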