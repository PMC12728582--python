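"""Independent brute-force reference implementations used as oracles.

Everything here is written from first principles (plain loops, BFS, explicit
path enumeration) so it shares no code path with the package: rank
correlations from scipy's per-pair routine, step-up FDR as a literal loop,
graph metrics by enumeration.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy import stats


def naive_bh(p_values):
    """Literal Benjamini–Hochberg step-up: sort ascending, q_i = min_{j>=i}
    p_(j) * m / j, cap at 1, restore original order."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return np.array(q)


def naive_spearman(x, y):
    """Spearman rho via scipy's pairwise routine, with the t-approximation
    p-value recomputed from the textbook formula."""
    r = stats.spearmanr(x, y).statistic
    n = len(x)
    if abs(r) >= 1.0:
        return r, np.finfo(float).tiny
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * (1 - stats.t.cdf(abs(t), n - 2))
    return r, p


def naive_network_edges(counts, r_threshold=0.70, p_threshold=0.01, adjust=True,
                        positive_only=False):
    """All-pairs Spearman + step-up FDR + thresholds on a taxa x samples
    count matrix (dict asv -> vector). Returns {frozenset{u,v}: r}."""
    ids = list(counts)
    pairs, rs, ps = [], [], []
    for u, v in itertools.combinations(ids, 2):
        x, y = counts[u], counts[v]
        if len(set(x)) == 1 or len(set(y)) == 1:
            continue
        r, p = naive_spearman(x, y)
        pairs.append((u, v))
        rs.append(r)
        ps.append(p)
    adj = naive_bh(ps) if adjust else np.array(ps)
    edges = {}
    for (u, v), r, q in zip(pairs, rs, adj):
        if abs(r) > r_threshold and q < p_threshold:
            if positive_only and r <= 0:
                continue
            edges[frozenset((u, v))] = r
    return edges


class NaiveGraph:
    """Adjacency-set graph with metric computation by explicit enumeration."""

    def __init__(self, nodes, edges):
        self.nodes = list(nodes)
        self.adj = {v: set() for v in self.nodes}
        self.edges = set()
        for u, v in edges:
            self.adj[u].add(v)
            self.adj[v].add(u)
            self.edges.add(frozenset((u, v)))

    def degree(self, v):
        return len(self.adj[v])

    def avg_degree(self):
        n = len(self.nodes)
        return 2 * len(self.edges) / n if n else 0.0

    def density(self):
        n = len(self.nodes)
        return 2 * len(self.edges) / (n * (n - 1)) if n > 1 else 0.0

    def clustering(self):
        """Mean local clustering; degree<2 nodes contribute 0."""
        vals = []
        for v in self.nodes:
            nb = list(self.adj[v])
            k = len(nb)
            if k < 2:
                vals.append(0.0)
                continue
            links = sum(
                1 for a, b in itertools.combinations(nb, 2) if b in self.adj[a]
            )
            vals.append(2 * links / (k * (k - 1)))
        return float(np.mean(vals)) if vals else 0.0

    def _bfs_dist(self, src):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for w in self.adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        return dist

    def avg_path_length(self):
        """Mean shortest-path length over connected (ordered-halved) pairs."""
        total, count = 0, 0
        for v in self.nodes:
            for w, d in self._bfs_dist(v).items():
                if d > 0:
                    total += d
                    count += 1
        return total / count if count else 0.0  # each pair counted twice; ratio unchanged

    def _all_shortest_paths(self, src, dst):
        """Enumerate every shortest simple path from src to dst via BFS layers."""
        dist = self._bfs_dist(src)
        if dst not in dist:
            return []
        paths = []

        def extend(path):
            last = path[-1]
            if last == dst:
                paths.append(path)  # layer-respecting, so length == dist[dst]
                return
            for w in self.adj[last]:
                if dist.get(w, -1) == dist[last] + 1 and dist[w] <= dist[dst]:
                    extend(path + [w])

        extend([src])
        return paths

    def betweenness(self):
        """Betweenness normalised by (n-1)(n-2)/2, by explicit shortest-path
        enumeration over all unordered pairs."""
        n = len(self.nodes)
        bc = {v: 0.0 for v in self.nodes}
        if n < 3:
            return bc
        for s, t in itertools.combinations(self.nodes, 2):
            paths = self._all_shortest_paths(s, t)
            if not paths:
                continue
            for v in self.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
        norm = (n - 1) * (n - 2) / 2
        return {v: b / norm for v, b in bc.items()}

    def mean_betweenness(self):
        bc = self.betweenness()
        return float(np.mean(list(bc.values()))) if bc else 0.0


def naive_minmax(values):
    lo, hi = min(values), max(values)
    return [(v - lo) / (hi - lo) for v in values]


def naive_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def enumerate_directed_paths(edges, src, dst):
    """All simple directed paths src -> dst by DFS over an edge list."""
    out = {}
    for u, v in edges:
        out.setdefault(u, []).append(v)
    paths = []

    def walk(path):
        last = path[-1]
        if last == dst:
            paths.append(list(path))
            return
        for w in out.get(last, []):
            if w not in path:
                walk(path + [w])

    walk([src])
    return paths
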