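"""Co-occurrence networks and their topological attribute panel.

Edges are Spearman correlations between ASVs across a group's samples,
retained when |rho| exceeds a threshold and the BH-corrected p-value is
below a threshold.  The attribute panel follows the microbiome-network
literature: node/edge counts, average degree, mean shortest-path length on
the largest component, mean local clustering, greedy modularity, random-
removal robustness ("network stability"), and single-node vulnerability via
global efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import RelAbundTable, ValidationError


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Thresholded Spearman correlation graph (undirected, no self-loops)."""

    graph: nx.Graph
    rho_threshold: float
    q_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_i": u, "node_j": v,
             "rho": d.get("rho", np.nan), "q": d.get("q", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "rho", "q"])


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_path_length: float | None
    clustering_coefficient: float
    modularity: float | None
    robustness: float | None = None
    vulnerability: float | None = None


def build_network(
    rel: RelAbundTable,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.05,
    min_prevalence: float = 1 / 3,
) -> CooccurrenceNetwork:
    """Spearman + BH co-occurrence network for one group of samples.

    Taxa are first filtered to prevalence >= ``min_prevalence`` across the
    slice; all retained pairs are tested and corrected together.  All
    retained (and even isolated) prevalent taxa appear as nodes, so node
    counts reflect the filtered community, not just connected taxa.
    """
    x = rel.values
    if x.shape[0] < 5:
        raise ValidationError(
            f"need >= 5 samples for rank correlations, got {x.shape[0]}"
        )
    prevalence = np.mean(x > 0, axis=0)
    keep = prevalence >= min_prevalence
    taxa = [a for a, k in zip(rel.asv_ids, keep) if k]
    g = nx.Graph()
    g.add_nodes_from(taxa)
    if len(taxa) >= 2:
        sub = x[:, keep]
        rho, p = stats.spearmanr(sub)
        rho = np.atleast_2d(rho)
        p = np.atleast_2d(p)
        iu, ju = np.triu_indices(len(taxa), k=1)
        pvals = p[iu, ju]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for i, j, r, q in zip(iu, ju, rho[iu, ju], qvals):
            if np.isfinite(r) and abs(r) >= rho_threshold and q < q_threshold:
                g.add_edge(taxa[i], taxa[j], rho=float(r), q=float(q))
    return CooccurrenceNetwork(g, rho_threshold, q_threshold)


def _as_graph(net: CooccurrenceNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


def topology(net: CooccurrenceNetwork | nx.Graph) -> NetworkMetrics:
    """Topological attribute panel (robustness/vulnerability computed apart).

    Path length is averaged over pairs in the largest connected component
    (None for edgeless graphs); clustering is the mean local coefficient with
    degree < 2 nodes contributing zero; modularity is greedy maximization on
    the unweighted graph with node order fixed by sorted id for reproducible
    tie-breaks.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("empty node set")
    g = nx.Graph()
    g.add_nodes_from(sorted(_as_graph(net).nodes))
    g.add_edges_from(
        (min(u, v), max(u, v)) for u, v in sorted(
            (tuple(sorted(e)) for e in _as_graph(net).edges))
    )
    n, m = g.number_of_nodes(), g.number_of_edges()
    avg_degree = 2.0 * m / n
    if m == 0:
        return NetworkMetrics(n, 0, avg_degree, None, 0.0, None)
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    lcc = g.subgraph(components[0])
    apl = (nx.average_shortest_path_length(lcc)
           if lcc.number_of_nodes() > 1 else None)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    communities = nx.community.greedy_modularity_communities(g)
    modularity = float(nx.community.modularity(g, communities))
    return NetworkMetrics(n, m, avg_degree, apl, clustering, modularity)


def robustness(
    net: CooccurrenceNetwork | nx.Graph,
    removal_fraction: float = 0.5,
    n_trials: int = 100,
    seed: int = 0,
) -> float:
    """Random-removal robustness ("network stability").

    Mean over trials of the largest-connected-component fraction among the
    nodes remaining after uniformly random removal of
    ``floor(removal_fraction * n)`` nodes.  1 for complete graphs.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 4:
        raise ValidationError("robustness needs >= 4 nodes")
    if not (0.0 < removal_fraction < 1.0):
        raise ValueError("removal_fraction must lie in (0, 1)")
    k = int(np.floor(removal_fraction * n))
    if k == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    vals = []
    for _ in range(n_trials):
        removed = set(rng.choice(len(nodes), size=k, replace=False))
        keep = [v for i, v in enumerate(nodes) if i not in removed]
        sub = g.subgraph(keep)
        if not keep:
            vals.append(0.0)
            continue
        largest = max((len(c) for c in nx.connected_components(sub)), default=0)
        vals.append(largest / len(keep))
    return float(np.mean(vals))


def global_efficiency(net: CooccurrenceNetwork | nx.Graph) -> float:
    """Mean over ordered node pairs of 1 / shortest-path length."""
    return float(nx.global_efficiency(_as_graph(net)))


def _efficiency_sum(sub: nx.Graph) -> float:
    """Sum of 1/shortest-path-length over ordered node pairs."""
    s = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(sub):
        for d in lengths.values():
            if d > 0:
                s += 1.0 / d
    return s


def vulnerability(net: CooccurrenceNetwork | nx.Graph) -> float:
    """Max relative drop in global efficiency from deleting a single node:
    max_v (E - E_without_v) / E.

    Exact but decomposed by connected component: removing a node only
    re-routes paths inside its own component, so the other components'
    efficiency sums are reused.
    """
    g = _as_graph(net)
    components = [set(c) for c in nx.connected_components(g)]
    if max((len(c) for c in components), default=0) < 3:
        raise ValidationError(
            "vulnerability needs a connected component with >= 3 nodes"
        )
    n = g.number_of_nodes()
    comp_sums = [_efficiency_sum(g.subgraph(c)) for c in components]
    total = sum(comp_sums)
    e_full = total / (n * (n - 1))
    if e_full == 0:
        raise ValidationError("zero global efficiency")
    worst = -np.inf
    for c, cs in zip(components, comp_sums):
        for v in sorted(c):
            rem = _efficiency_sum(g.subgraph(c - {v})) if len(c) > 1 else 0.0
            e_wo = ((total - cs + rem) / ((n - 1) * (n - 2))
                    if n > 2 else 0.0)
            worst = max(worst, (e_full - e_wo) / e_full)
    return float(worst)


def full_metrics(
    net: CooccurrenceNetwork | nx.Graph,
    removal_fraction: float = 0.5,
    n_trials: int = 100,
    seed: int = 0,
) -> NetworkMetrics:
    """Topology panel plus robustness and vulnerability (where defined)."""
    base = topology(net)
    g = _as_graph(net)
    rob = (robustness(net, removal_fraction, n_trials, seed)
           if g.number_of_nodes() >= 4 else None)
    try:
        vul = vulnerability(net)
    except ValidationError:
        vul = None
    return NetworkMetrics(
        base.n_nodes, base.n_edges, base.avg_degree, base.avg_path_length,
        base.clustering_coefficient, base.modularity, rob, vul,
    )
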