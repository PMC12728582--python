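"""Co-occurrence networks, per-sample subnetworks, topology, and complexity.

The network recipe: keep "core" ASVs (mean relative abundance above 0.5% by
default), Spearman-correlate all unordered core-ASV pairs across samples
(cross-kingdom pairs included when both kingdoms are supplied), adjust the
p-values with Benjamini–Hochberg within the network, and keep edges with
|r| > 0.70 and adjusted p < 0.01. Edges carry their sign; a ``positive_only``
flag reproduces the stricter positive-edge reading.

Each sample's subnetwork is the induced subgraph on the ASVs present (count
> 0) in that sample. Seven topology metrics per subnetwork — node count, edge
count, positive-edge count, average degree, mean local clustering, average
shortest-path length (over connected pairs), density, and mean normalised
betweenness — feed a PCoA whose leading axis, oriented to increase with
average degree, is the network-complexity score.

Statistical note for small designs: with n samples a Spearman p-value below
~1e-4 (what a BH-adjusted 0.01 gate demands among thousands of pairs)
requires near-perfect correlation when n is around ten, so the adjusted gate
has essentially no power for moderate block correlations at that scale. The
treatment-level pipeline therefore exposes ``p_adjust="none"`` (gate on the
raw p) for desk-scale studies, while this module's default keeps the
BH-adjusted gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ordination import pcoa
from .tables import AsvTable, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams", "TopologyRecord", "ComplexityResult",
    "filter_core_asvs", "spearman_edge_test", "bh_adjust",
    "build_network", "topology", "sample_subnetwork", "complexity_index",
]

TOPOLOGY_METRICS = (
    "n_nodes", "n_edges", "n_positive_edges", "avg_degree",
    "clustering_coef", "avg_path_length", "density", "mean_betweenness",
)


class ConstantVectorError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


@dataclass
class NetworkParams:
    """Edge-filter settings; defaults follow the standard recipe
    (core > 0.5% mean relative abundance, |r| > 0.70, BH-adjusted p < 0.01)."""

    min_mean_rel_abund: float = 0.005
    r_threshold: float = 0.70
    p_threshold: float = 0.01
    positive_only: bool = False
    p_adjust: str = "bh"  # "bh" or "none"

    def __post_init__(self) -> None:
        if self.p_adjust not in ("bh", "none"):
            raise ValueError("p_adjust must be 'bh' or 'none'")


def filter_core_asvs(table: AsvTable, min_mean_rel_abund: float = 0.005) -> AsvTable:
    """Keep ASVs whose mean per-sample relative abundance exceeds the cutoff."""
    rel = table.relative_abundance()
    keep = rel.mean(axis=1) > min_mean_rel_abund
    kept = table.counts.loc[keep.to_numpy()]
    tax = None
    if table.taxonomy is not None:
        tax = {a: table.taxonomy[a] for a in kept.index if a in table.taxonomy}
    return AsvTable(counts=kept, kingdom=table.kingdom, taxonomy=tax)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n-2 df; |r|=1 maps to the
    smallest positive double."""
    r = np.asarray(r, dtype=float)
    p = np.full(r.shape, np.finfo(float).tiny)
    interior = np.abs(r) < 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[interior] * np.sqrt((n - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return p


def spearman_edge_test(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its two-sided t-approximation
    p-value for one pair of abundance profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    r = float(_snap_unit(np.corrcoef(rx, ry)[0, 1]))
    return r, float(_p_from_r(np.array([r]), len(x))[0])


def _snap_unit(r):
    """Clamp rank correlations to exactly +/-1 where only rounding error
    separates them (perfectly monotone profiles)."""
    r = np.asarray(r, dtype=float)
    snapped = np.where(np.abs(np.abs(r) - 1.0) < 1e-12, np.sign(r), r)
    return snapped if snapped.ndim else float(snapped)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, original
    order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_all_pairs(counts: np.ndarray):
    """Rank-correlation matrix over rows plus a constant-row mask."""
    n = counts.shape[1]
    ranks = stats.rankdata(counts, axis=1)
    constant = np.ptp(counts, axis=1) == 0
    ranks_ok = ranks[~constant]
    if ranks_ok.shape[0] >= 2:
        r = _snap_unit(np.corrcoef(ranks_ok))
    else:
        r = np.ones((ranks_ok.shape[0], ranks_ok.shape[0]))
    return r, constant, n


def build_network(tables, params: NetworkParams | None = None) -> nx.Graph:
    """Build one co-occurrence network from one or two kingdoms' tables.

    Tables are core-filtered, all unordered ASV pairs (cross-kingdom pairs
    included) are Spearman-tested, p-values are BH-adjusted across all tested
    pairs of this network (or left raw with ``p_adjust="none"``), and edges
    satisfying the |r| and p gates are kept. Nodes are the ASVs incident to
    at least one kept edge.
    """
    if isinstance(tables, AsvTable):
        tables = [tables]
    if params is None:
        params = NetworkParams()
    cores = [filter_core_asvs(t, params.min_mean_rel_abund) for t in tables]
    sample_sets = {tuple(t.sample_ids) for t in cores}
    if len(sample_sets) != 1:
        raise FormatError("tables must share an identical sample set (and order)")
    n_samples = len(cores[0].sample_ids)
    if n_samples < 5:
        raise ValueError(f"only {n_samples} samples; correlation is underpowered (< 5)")

    counts = pd.concat([t.counts for t in cores], axis=0)
    kingdom_of = {}
    for t in cores:
        kingdom_of.update({a: t.kingdom for a in t.asv_ids})

    arr = counts.to_numpy(dtype=float)
    r_mat, constant, _ = _spearman_all_pairs(arr)
    n_const = int(constant.sum())
    if n_const:
        logger.info("skipped %d constant ASV profile(s)", n_const)
    ids = counts.index[~constant].to_numpy()
    m = len(ids)
    iu, ju = np.triu_indices(m, k=1)
    r_vec = r_mat[iu, ju]
    p_raw = _p_from_r(r_vec, n_samples)
    p_adj = bh_adjust(p_raw) if params.p_adjust == "bh" else p_raw.copy()

    keep = (np.abs(r_vec) > params.r_threshold) & (p_adj < params.p_threshold)
    if params.positive_only:
        keep &= r_vec > 0

    g = nx.Graph()
    g.graph["build_params"] = {
        "min_mean_rel_abund": params.min_mean_rel_abund,
        "r_threshold": params.r_threshold,
        "p_threshold": params.p_threshold,
        "positive_only": params.positive_only,
        "p_adjust": params.p_adjust,
        "n_samples": n_samples,
        "n_pairs_tested": int(len(r_vec)),
    }
    for k in np.flatnonzero(keep):
        u, v = ids[iu[k]], ids[ju[k]]
        g.add_edge(
            u, v,
            r=float(r_vec[k]),
            p_raw=float(p_raw[k]),
            p_adj=float(p_adj[k]),
            sign="+" if r_vec[k] > 0 else "-",
        )
    nx.set_node_attributes(g, {node: kingdom_of[node] for node in g.nodes}, "kingdom")
    return g


@dataclass
class TopologyRecord:
    """Seven topology metrics of one (sub)network."""

    graph_id: str
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    avg_degree: float
    clustering_coef: float
    avg_path_length: float
    density: float
    mean_betweenness: float
    is_empty: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("graph_id", *TOPOLOGY_METRICS)}


def topology(graph: nx.Graph, graph_id: str = "") -> TopologyRecord:
    """Compute the seven topology metrics.

    Conventions: mean local clustering counts degree<2 nodes as 0; the
    average path length on a disconnected graph averages over connected pairs
    only; betweenness is normalised by (n-1)(n-2)/2 and averaged over nodes.
    An empty graph yields zeros with ``is_empty=True``.
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        return TopologyRecord(graph_id, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, is_empty=True)
    n_pos = sum(1 for _, _, d in graph.edges(data=True) if d.get("sign", "+") == "+")
    avg_degree = 2.0 * e / n
    clustering = nx.average_clustering(graph) if n > 0 else 0.0
    density = nx.density(graph)
    # mean shortest-path length over connected (unordered) pairs
    total_len, n_pairs = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for dist in lengths.values():
            if dist > 0:
                total_len += dist
                n_pairs += 1
    apl = total_len / n_pairs if n_pairs else 0.0
    bc = nx.betweenness_centrality(graph, normalized=True) if n > 2 else {v: 0.0 for v in graph}
    mean_bc = float(np.mean(list(bc.values()))) if bc else 0.0
    return TopologyRecord(
        graph_id=graph_id,
        n_nodes=n,
        n_edges=e,
        n_positive_edges=n_pos,
        avg_degree=avg_degree,
        clustering_coef=float(clustering),
        avg_path_length=float(apl),
        density=float(density),
        mean_betweenness=mean_bc,
        is_empty=(e == 0 and n == 0),
    )


def sample_subnetwork(graph: nx.Graph, tables, sample_id: str) -> nx.Graph:
    """Induced subgraph on the network nodes present (count > 0) in a sample."""
    if isinstance(tables, AsvTable):
        tables = [tables]
    present: set[str] = set()
    found = False
    for t in tables:
        if sample_id in t.counts.columns:
            found = True
            col = t.counts[sample_id]
            present.update(col.index[(col > 0).to_numpy()])
    if not found:
        raise KeyError(f"unknown sample {sample_id!r}")
    sub = graph.subgraph(n for n in graph.nodes if n in present)
    return nx.Graph(sub)


@dataclass
class ComplexityResult:
    """Leading ordination axis over subnetwork topology profiles."""

    scores: pd.Series            # per graph_id, centered, increases with avg_degree
    loadings: pd.Series          # correlation of each retained metric with the score
    eigenvalues: np.ndarray
    metrics_used: list[str] = field(default_factory=list)


def complexity_index(records: list[TopologyRecord]) -> ComplexityResult:
    """Network-complexity score: PCoA (Euclidean, hence PCA-equivalent) of the
    z-scored topology metrics; axis 1, oriented to correlate positively with
    average degree (falling back to edge count if degree is constant)."""
    if len(records) < 3:
        raise ValueError("need at least 3 topology records")
    df = pd.DataFrame([r.as_dict() for r in records]).set_index("graph_id")
    keep = []
    for col in TOPOLOGY_METRICS:
        if df[col].nunique() > 1:
            keep.append(col)
        else:
            logger.warning("dropping constant topology metric %r", col)
    if not keep:
        raise ValueError("all topology metrics are constant across records")
    z = (df[keep] - df[keep].mean()) / df[keep].std(ddof=1)
    zm = z.to_numpy()
    diff = zm[:, None, :] - zm[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    coords, eigvals = pcoa(d)
    axis1 = coords[:, 0] if coords.shape[1] else np.zeros(len(df))
    for ref_col in ("avg_degree", "n_edges", *keep):
        if ref_col in keep and df[ref_col].nunique() > 1:
            ref = df[ref_col].to_numpy(dtype=float)
            break
    else:
        ref = np.arange(len(df), dtype=float)
    if len(axis1) > 1 and np.std(axis1) > 0:
        corr = np.corrcoef(axis1, ref)[0, 1]
        if math.isfinite(corr) and corr < 0:
            axis1 = -axis1
    scores = pd.Series(axis1, index=df.index, name="complexity")
    loadings = {}
    for col in keep:
        v = df[col].to_numpy(dtype=float)
        if np.std(axis1) > 0 and np.std(v) > 0:
            loadings[col] = float(np.corrcoef(axis1, v)[0, 1])
        else:
            loadings[col] = float("nan")
    return ComplexityResult(
        scores=scores,
        loadings=pd.Series(loadings),
        eigenvalues=eigvals,
        metrics_used=keep,
    )
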