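"""Summary statistics of signed co-occurrence networks.

Degree, betweenness centrality, positive:negative edge ratio, module
detection, keystone OTU calls, taxonomic composition of the node set,
and rank-based between-network comparisons. Shortest-path quantities
are computed on the unweighted undirected topology — partial-correlation
magnitudes are association strengths, not distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .containers import SignedNetwork

__all__ = [
    "MetricsReport",
    "degree_stats",
    "betweenness",
    "sign_ratio",
    "keystone_otus",
    "detect_modules",
    "taxon_composition",
    "compare_networks",
    "metrics_report",
]


@dataclass
class MetricsReport:
    """Per-network summary; internal consistency is checked on creation."""

    name: str
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    mean_degree: float
    pos_neg_ratio: float  # math.inf when there are no negative edges
    mean_node_betweenness: float
    mean_edge_betweenness: float
    keystones: list[tuple[str, int]]
    modules: dict[str, int]
    modularity: float
    taxon_composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_edges != self.n_positive + self.n_negative:
            raise ValueError("edge sign counts do not sum to the edge count")
        expect = 2 * self.n_edges / self.n_nodes if self.n_nodes else 0.0
        if not math.isclose(self.mean_degree, expect, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("mean_degree inconsistent with node/edge counts")
        if self.taxon_composition:
            total = sum(self.taxon_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"taxon fractions sum to {total}, not 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if math.isinf(d["pos_neg_ratio"]):
            d["pos_neg_ratio"] = None
            d["pos_neg_ratio_infinite"] = True
        d["keystones"] = [{"otu": o, "degree": k} for o, k in self.keystones]
        return d


def degree_stats(net: SignedNetwork) -> tuple[int, int, float]:
    """(n_nodes, n_edges, mean_degree); mean degree is 2E/N, 0 for empty nets."""
    n, e = net.n_nodes, net.n_edges
    return n, e, (2.0 * e / n) if n else 0.0


def betweenness(net: SignedNetwork) -> tuple[dict[str, float], dict[tuple[str, str], float], float, float]:
    """Unnormalized node and edge betweenness on the unweighted topology.

    Pair counts with even splitting across equal-length shortest paths,
    each unordered pair counted once; computed per connected component
    (pairs in different components contribute nothing). Returns
    ``(node_values, edge_values, mean_node, mean_edge)``.
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        return {}, {}, 0.0, 0.0
    node_b = nx.betweenness_centrality(g, normalized=False, weight=None)
    edge_b_raw = nx.edge_betweenness_centrality(g, normalized=False, weight=None)
    edge_b = {(a, b) if a < b else (b, a): v for (a, b), v in edge_b_raw.items()}
    mean_node = float(np.mean(list(node_b.values())))
    mean_edge = float(np.mean(list(edge_b.values()))) if edge_b else 0.0
    return node_b, edge_b, mean_node, mean_edge


def sign_ratio(net: SignedNetwork) -> float:
    """Positive:negative edge ratio; ``math.inf`` when no negative edges."""
    if net.n_negative == 0:
        return math.inf
    return net.n_positive / net.n_negative


def keystone_otus(net: SignedNetwork, k: float = 3.0) -> list[tuple[str, int]]:
    """Nodes whose degree exceeds mean + k·SD of the degree distribution.

    An operationalization of "outstanding degree relative to the rest of
    the network"; returns (otu, degree) sorted by degree descending then
    by OTU id for determinism.
    """
    if net.n_nodes < 3:
        raise ValueError("keystone detection needs at least 3 nodes")
    g = net.to_networkx()
    degrees = dict(g.degree())
    vals = np.array(list(degrees.values()), dtype=float)
    cut = vals.mean() + k * vals.std()
    out = [(o, d) for o, d in degrees.items() if d > cut]
    return sorted(out, key=lambda t: (-t[1], t[0]))


def detect_modules(net: SignedNetwork, seed: int = 0) -> tuple[dict[str, int], float]:
    """Greedy modularity maximization on absolute edge weights.

    Returns a node → module-index partition covering every node, and
    the modularity of that partition. Module indices are assigned by
    decreasing module size, ties broken by smallest member id, so the
    labelling is deterministic.
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        return {}, 0.0
    communities = nx.community.greedy_modularity_communities(g, weight="abs_weight")
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    score = nx.community.modularity(g, [set(c) for c in communities],
                                    weight="abs_weight")
    partition = {node: i for i, c in enumerate(communities) for node in c}
    return partition, float(score)


def taxon_composition(net: SignedNetwork, taxonomy: dict[str, str]) -> dict[str, float]:
    """Fraction of network nodes per taxon (e.g. phylum); sums to 1.

    Nodes absent from the taxonomy map count as ``"Unassigned"``.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        return {}
    counts: dict[str, int] = {}
    for node in nodes:
        taxon = taxonomy.get(node, "Unassigned")
        counts[taxon] = counts.get(taxon, 0) + 1
    return {t: c / len(nodes) for t, c in sorted(counts.items())}


@dataclass
class ComparisonReport:
    """Rank-based comparison of two networks' centrality distributions."""

    metric_pvalues: dict[str, float]
    metric_means_a: dict[str, float]
    metric_means_b: dict[str, float]
    directions: dict[str, str]  # "a > b", "b > a" or "tied"
    tied_flags: dict[str, bool]


def compare_networks(a: SignedNetwork, b: SignedNetwork) -> ComparisonReport:
    """Wilcoxon–Mann–Whitney tests on degree and betweenness distributions.

    Two-sided rank-sum p-values per metric (degree, node betweenness,
    edge betweenness). All-tied distributions get p = 1 with a flag.
    """
    if a.n_edges == 0 or b.n_edges == 0:
        raise ValueError("both networks must be non-empty")

    ga, gb = a.to_networkx(), b.to_networkx()
    na_b, ea_b, _, _ = betweenness(a)
    nb_b, eb_b, _, _ = betweenness(b)
    samples = {
        "degree": ([d for _, d in ga.degree()], [d for _, d in gb.degree()]),
        "node_betweenness": (list(na_b.values()), list(nb_b.values())),
        "edge_betweenness": (list(ea_b.values()), list(eb_b.values())),
    }
    pvals, ma, mb, direction, tied = {}, {}, {}, {}, {}
    for metric, (xs, ys) in samples.items():
        ma[metric] = float(np.mean(xs))
        mb[metric] = float(np.mean(ys))
        all_tied = len(set(xs) | set(ys)) <= 1
        tied[metric] = all_tied
        if all_tied:
            pvals[metric] = 1.0
            direction[metric] = "tied"
        else:
            pvals[metric] = float(stats.mannwhitneyu(
                xs, ys, alternative="two-sided").pvalue)
            if ma[metric] > mb[metric]:
                direction[metric] = "a > b"
            elif ma[metric] < mb[metric]:
                direction[metric] = "b > a"
            else:
                direction[metric] = "tied"
    return ComparisonReport(pvals, ma, mb, direction, tied)


def metrics_report(net: SignedNetwork, taxonomy: dict[str, str] | None = None,
                   keystone_k: float = 3.0, seed: int = 0) -> MetricsReport:
    """Full MetricsReport for one network."""
    n, e, mean_deg = degree_stats(net)
    _, _, mean_nb, mean_eb = betweenness(net)
    modules, modularity = detect_modules(net, seed=seed)
    keystones = keystone_otus(net, k=keystone_k) if n >= 3 else []
    return MetricsReport(
        name=net.name,
        n_nodes=n, n_edges=e,
        n_positive=net.n_positive, n_negative=net.n_negative,
        mean_degree=mean_deg,
        pos_neg_ratio=sign_ratio(net),
        mean_node_betweenness=mean_nb,
        mean_edge_betweenness=mean_eb,
        keystones=keystones,
        modules=modules,
        modularity=modularity,
        taxon_composition=taxon_composition(net, taxonomy or {}),
    )
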