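"""Co-occurrence networks and the weighted graph-dissimilarity D-measure.

Per subcommunity, taxa are correlated pairwise with Spearman's rho and an
edge is admitted only when |rho| strictly exceeds 0.8 and the two-sided
p-value is strictly below 0.001 (raw p-values, no multiple-testing
correction). Edges recurring in strictly more than a cutoff number of the
bootstrap subcommunity networks form the combined network. Structural
distances between networks use the three-term D-measure of Schieber-style
network comparison: mean node-distance distributions, network node
dispersion, and alpha-centrality distributions of the graph and its
complement, weighted (0.45, 0.45, 0.10) by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_tiers import SubcommunityView
from .preprocess import DistanceMatrix, Ordination, nmds

logger = logging.getLogger(__name__)

Edge = frozenset  # frozenset({taxon_a, taxon_b})


@dataclass
class Network:
    """Simple undirected taxon graph with per-edge rho and p-value."""

    label: str
    nodes: tuple[str, ...]
    edges: dict[Edge, tuple[float, float]] = field(default_factory=dict)  # edge -> (rho, p)
    n_skipped_pairs: int = 0  # constant-vector pairs with undefined rho

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e, (rho, p) in self.edges.items():
            a, b = sorted(e)
            g.add_edge(a, b, rho=rho, p=p)
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": min(e), "taxon_b": max(e), "rho": rho, "p": p}
            for e, (rho, p) in sorted(self.edges.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"])


@dataclass
class CombinedNetwork:
    """Edges by cross-subcommunity frequency, thresholded strictly."""

    nodes: tuple[str, ...]
    edges: dict[Edge, int]  # edge -> frequency among source networks
    n_source: int
    min_freq: int
    histogram: pd.DataFrame = field(repr=False)  # frequency -> number of edges (all edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e, freq in self.edges.items():
            a, b = sorted(e)
            g.add_edge(a, b, frequency=freq)
        return g


@dataclass
class DMeasureParams:
    w1: float = 0.45
    w2: float = 0.45
    w3: float = 0.10

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def edge_admitted(rho: float, p: float, rho_min: float = 0.8, p_max: float = 0.001) -> bool:
    """Strict admission rule: |rho| > rho_min AND p < p_max."""
    return abs(rho) > rho_min and p < p_max


@lru_cache(maxsize=4)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """All n! Spearman rho values of one fixed ranking against every permutation."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1.0))


def _spearman_pvalues(ranks: np.ndarray, rho: np.ndarray, exact: bool) -> np.ndarray:
    """Two-sided p-values for a matrix of Spearman rhos.

    Exact permutation p (tie-free null) for n <= 9 samples, t-distribution
    approximation otherwise.
    """
    n = ranks.shape[0]
    if exact:
        dist = _exact_rho_distribution(n)
        # P(|rho_perm| >= |rho_obs|) under the uniform-permutation null
        return np.mean(
            np.abs(dist)[None, None, :] >= np.abs(rho)[:, :, None] - 1e-12, axis=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isnan(tstat)] = 0.0 if n > 2 else 1.0  # |rho| == 1 exactly
    p[np.abs(rho) >= 1.0] = 0.0
    return p


def spearman_network(
    sub: SubcommunityView,
    rho_min: float = 0.8,
    p_max: float = 0.001,
    abundances: np.ndarray | None = None,
) -> Network:
    """Spearman co-occurrence network of one subcommunity.

    Correlations run over the view's samples x taxa values (its counts by
    default; any monotone per-taxon transform gives identical rhos). Taxa
    that are constant across the view's samples (including all-absent
    taxa) have undefined correlations; their pairs are skipped and
    counted.
    """
    if abundances is None:
        abundances = np.asarray(sub.counts, dtype=float)
    n, t = abundances.shape
    if n < 5:
        raise ValueError("need at least 5 samples for correlation")
    if t < 2:
        raise ValueError("need at least 2 taxa")
    variable = abundances.std(axis=0) > 0
    n_const = int((~variable).sum())
    if n_const:
        logger.debug("%s: %d constant taxa dropped before correlation", sub.label, n_const)
    idx = np.flatnonzero(variable)
    edges: dict[Edge, tuple[float, float]] = {}
    n_skipped = (t * (t - 1)) // 2 - (len(idx) * (len(idx) - 1)) // 2
    if len(idx) >= 2:
        ranks = np.apply_along_axis(stats.rankdata, 0, abundances[:, idx])
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        rho = np.atleast_2d(rho)
        p = _spearman_pvalues(ranks, rho, exact=n <= 9)
        ii, jj = np.triu_indices(len(idx), k=1)
        keep = (np.abs(rho[ii, jj]) > rho_min) & (p[ii, jj] < p_max)
        for a, b in zip(ii[keep], jj[keep]):
            e = Edge({sub.taxon_ids[idx[a]], sub.taxon_ids[idx[b]]})
            edges[e] = (float(rho[a, b]), float(p[a, b]))
    return Network(sub.label, tuple(sub.taxon_ids), edges, n_skipped)


def combine_networks(nets: list[Network], min_freq: int = 20) -> CombinedNetwork:
    """Combine edges by frequency across source networks, keeping freq > ``min_freq``."""
    if not nets:
        raise ValueError("need at least one source network")
    universe = nets[0].nodes
    for net in nets[1:]:
        if net.nodes != universe:
            raise ValueError("networks must share one taxon universe")
    freq: dict[Edge, int] = {}
    for net in nets:
        for e in net.edges:
            freq[e] = freq.get(e, 0) + 1
    hist = (
        pd.Series(list(freq.values()), dtype=int).value_counts().sort_index()
        if freq
        else pd.Series([], dtype=int)
    )
    histogram = hist.rename_axis("frequency").reset_index(name="n_edges")
    kept = {e: c for e, c in freq.items() if c > min_freq}
    return CombinedNetwork(universe, kept, len(nets), min_freq, histogram)


def node_metrics(net: Network | CombinedNetwork) -> pd.DataFrame:
    """Degree, closeness and betweenness centrality per vertex.

    Closeness follows the component-scaled (Wasserman-Faust) convention:
    computed within each vertex's connected component and scaled by the
    component's share of the graph; isolated vertices get 0. Betweenness
    uses shortest-path counting with fractional credit for ties.
    """
    g = net.to_networkx()
    closeness = nx.closeness_centrality(g, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {
            "taxon": list(g.nodes),
            "degree": [g.degree(v) for v in g.nodes],
            "closeness": [closeness[v] for v in g.nodes],
            "betweenness": [betweenness[v] for v in g.nodes],
        }
    )


# ---------------------------------------------------------------------------
# D-measure


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log), always finite, in [0, log 2].

    Distributions carry their "unreachable" mass in the LAST bin; when the
    supports differ in length, zero bins are inserted before that last bin
    so the unreachable bins stay aligned.
    """
    size = max(p.size, q.size)

    def _align(v: np.ndarray) -> np.ndarray:
        if v.size == size:
            return v
        return np.concatenate([v[:-1], np.zeros(size - v.size), v[-1:]])

    p, q = _align(p), _align(q)
    m = (p + q) / 2.0
    return max(0.0, _entropy(m) - (_entropy(p) + _entropy(q)) / 2.0)


def _node_distance_distributions(g: nx.Graph) -> tuple[np.ndarray, int]:
    """Per-node shortest-path distance distributions with an unreachable bin.

    Row i gives, for node i, the fraction of the other N-1 nodes at
    distance 1..N-1, plus a final bin for unreachable nodes (row length
    N). Returns (matrix, diameter), the diameter being the largest finite
    distance (0 for an edgeless graph).
    """
    nodes = list(g.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        i = index[src]
        for dst, d in lengths.items():
            dist[i, index[dst]] = d
    finite = dist[np.isfinite(dist)]
    diam = int(finite.max()) if finite.size else 0
    rows = np.zeros((n, n))
    for i in range(n):
        d = np.delete(dist[i], i)
        for k in range(1, n):
            rows[i, k - 1] = np.sum(d == k)
        rows[i, n - 1] = np.sum(~np.isfinite(d))
        rows[i] /= max(n - 1, 1)
    return rows, diam


def _nnd(g: nx.Graph) -> tuple[float, np.ndarray]:
    """Network node dispersion and the mean node-distance distribution."""
    rows, diam = _node_distance_distributions(g)
    mu = rows.mean(axis=0)
    if diam == 0:
        return 0.0, mu
    js_n = _entropy(mu) - np.mean([_entropy(r) for r in rows])
    nnd = max(0.0, js_n) / np.log(diam + 1)
    return float(nnd), mu


def _alpha_centrality_distribution(g: nx.Graph) -> np.ndarray:
    """Sorted, normalized alpha-centrality values of a graph.

    Alpha-centrality solves ``c = alpha * A^T c + e`` with exogenous input
    ``e = degree/(N-1)`` and ``alpha = 1/(1 + spectral_radius(A))``, a
    documented constant strictly below the reciprocal spectral radius so
    the series converges.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=1)
    e = deg / max(n - 1, 1)
    if A.any():
        rho = float(np.max(np.abs(np.linalg.eigvals(A)).real))
    else:
        rho = 0.0
    alpha = 1.0 / (1.0 + rho)
    c = np.linalg.solve(np.eye(n) - alpha * A.T, e)
    c = np.sort(np.clip(c, 0.0, None))
    total = c.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return c / total


def graph_dissimilarity(
    g1: nx.Graph | Network | CombinedNetwork,
    g2: nx.Graph | Network | CombinedNetwork,
    params: DMeasureParams | None = None,
) -> float:
    """Three-term weighted structural dissimilarity between two graphs.

    ``D = w1 * sqrt(JS(mu1, mu2)/log 2)
       + w2 * |sqrt(NND1) - sqrt(NND2)|
       + w3/2 * (sqrt(JS(Pa(g1), Pa(g2))/log 2)
               + sqrt(JS(Pa(~g1), Pa(~g2))/log 2))``

    where ``mu`` is the graph's mean node-distance distribution (with a
    dedicated bin for unreachable pairs), NND the network node dispersion,
    and ``Pa`` the sorted alpha-centrality distribution of the graph or
    its complement. D is in [0, 1], symmetric, and exactly 0 for identical
    graphs.
    """
    params = params or DMeasureParams()
    if not isinstance(g1, nx.Graph):
        g1 = g1.to_networkx()
    if not isinstance(g2, nx.Graph):
        g2 = g2.to_networkx()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("graphs must have at least 2 vertices")

    nnd1, mu1 = _nnd(g1)
    nnd2, mu2 = _nnd(g2)
    term1 = np.sqrt(_js_divergence(mu1, mu2) / np.log(2.0))
    term2 = abs(np.sqrt(nnd1) - np.sqrt(nnd2))
    term3 = 0.0
    if params.w3 > 0:
        pa1 = _alpha_centrality_distribution(g1)
        pa2 = _alpha_centrality_distribution(g2)
        pc1 = _alpha_centrality_distribution(nx.complement(g1))
        pc2 = _alpha_centrality_distribution(nx.complement(g2))
        term3 = 0.5 * (
            np.sqrt(_js_divergence(pa1, pa2) / np.log(2.0))
            + np.sqrt(_js_divergence(pc1, pc2) / np.log(2.0))
        )
    return float(params.w1 * term1 + params.w2 * term2 + params.w3 * term3)


def network_ordination(
    nets: list[Network | CombinedNetwork | nx.Graph],
    params: DMeasureParams | None = None,
    seed: int = 0,
) -> Ordination:
    """NMDS ordination of networks under the pairwise D-measure."""
    if len(nets) < 4:
        raise ValueError("need at least 4 networks to ordinate")
    n = len(nets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = graph_dissimilarity(nets[i], nets[j], params)
    if np.all(d == 0):
        logger.warning("all pairwise network dissimilarities are zero; ordination degenerate")
    ids = [getattr(net, "label", f"net_{i:03d}") for i, net in enumerate(nets)]
    ids = [f"net_{i:03d}" if not isinstance(s, str) else s for i, s in enumerate(ids)]
    # labels may repeat across simulated networks; disambiguate
    seen: dict[str, int] = {}
    uniq = []
    for s in ids:
        seen[s] = seen.get(s, 0)
        uniq.append(s if seen[s] == 0 else f"{s}#{seen[s]}")
        seen[s] += 1
    return nmds(DistanceMatrix(uniq, d), k=2, n_restarts=5, seed=seed)
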