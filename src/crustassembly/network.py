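"""Signed co-occurrence networks and their topology panel.

Edges connect pairs of abundant OTUs (the 99%-cumulative-abundance set of
each domain) whose abundance profiles across samples are strongly rank
correlated: |Spearman rho| >= 0.7 by default, positive rho = coexistence,
negative = mutual exclusion.  A second, Bray-Curtis-based agreement filter
keeps an edge only when the profile similarity of the pair falls in the
concordant extreme tail (top tail for coexistence, bottom tail for
exclusion), a two-measure simplification of ensemble co-occurrence
inference; it can be disabled for Spearman-only networks.

The topology panel mirrors a standard co-occurrence network summary:
edge/node ratio, signed-edge percentages, max and average degree, mean
local clustering, connected components, Freeman degree centralization,
density, degree heterogeneity, average shortest-path length over connected
pairs, and the node share of each domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .core_io import GroupAssignment, OtuTable, TaxonomyTable

logger = logging.getLogger(__name__)

__all__ = [
    "SignedGraph",
    "TopologyMetrics",
    "infer_edges",
    "topology",
    "network_by_group",
    "topology_table",
]


@dataclass
class SignedGraph:
    """Simple graph over taxa with signed (coexistence/exclusion) edges.

    ``graph`` is a networkx Graph; nodes carry ``domain``, ``phylum`` and
    ``mean_rel_abundance`` attributes, edges carry ``rho`` and ``sign``
    ("coexistence" or "exclusion").  Isolated taxa are dropped at
    construction and counted in ``n_isolated_dropped``.
    """

    graph: nx.Graph
    n_isolated_dropped: int = 0
    n_zero_variance_dropped: int = 0

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(v, v) for v in self.graph):
            raise ValueError("self-loops are not allowed")
        if any(d == 0 for _, d in self.graph.degree()):
            raise ValueError("isolated nodes must be dropped before wrapping")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            dict(taxon_a=a, taxon_b=b, rho=d["rho"], sign=d["sign"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            dict(taxon=v, domain=d.get("domain", ""), phylum=d.get("phylum", ""),
                 degree=self.graph.degree(v),
                 mean_rel_abundance=d.get("mean_rel_abundance", float("nan")))
            for v, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows).set_index("taxon")


@dataclass(frozen=True)
class TopologyMetrics:
    """Co-occurrence network summary (one column of the topology table)."""

    edge_node_ratio: float
    pct_coexistence: float
    pct_exclusion: float
    max_degree: int
    clustering_coefficient: float
    connected_components: int
    centralization: float       # NaN when |V| < 3
    density: float
    heterogeneity: float
    average_degree: float
    average_path_length: float
    pct_eukaryota_nodes: float
    pct_bacteria_nodes: float

    FIELDS = (
        "edge_node_ratio", "pct_coexistence", "pct_exclusion", "max_degree",
        "clustering_coefficient", "connected_components", "centralization",
        "density", "heterogeneity", "average_degree", "average_path_length",
        "pct_eukaryota_nodes", "pct_bacteria_nodes",
    )

    def as_series(self, name: str = "network") -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in self.FIELDS}, name=name)


def _combine_tables(t_bact: OtuTable, t_euk: OtuTable) -> pd.DataFrame:
    if t_bact.sample_ids != t_euk.sample_ids:
        raise ValueError("bacterial and eukaryotic tables must share the "
                         "same samples in the same order")
    overlap = set(t_bact.taxon_ids) & set(t_euk.taxon_ids)
    if overlap:
        raise ValueError(f"taxon ids shared between domains: {sorted(overlap)[:5]}")
    return pd.concat([t_bact.data, t_euk.data], axis=1)


def infer_edges(
    t_bact: OtuTable,
    t_euk: OtuTable,
    taxonomy: TaxonomyTable | None = None,
    rho_threshold: float = 0.7,
    require_bc_support: bool = True,
    bc_tail_fraction: float = 0.2,
) -> SignedGraph:
    """Infer the signed co-occurrence network from two domain tables.

    Candidate edges have |Spearman rho| >= ``rho_threshold`` across
    samples (mid-rank ties); the Bray-Curtis agreement filter then keeps a
    coexistence edge only if the pair's profile similarity (1 - BC between
    the two taxa's relative-abundance profiles) ranks in the top
    ``bc_tail_fraction`` of all candidate-pool pairs, and an exclusion
    edge only if it ranks in the bottom tail.  Cross-domain edges are
    allowed.  Zero-variance taxa are dropped before correlation.
    """
    combined = _combine_tables(t_bact, t_euk)
    if combined.shape[0] < 5:
        raise ValueError("need at least 5 samples for rank correlations")
    domains = {tid: "Bacteria" for tid in t_bact.taxon_ids}
    domains.update({tid: "Eukaryota" for tid in t_euk.taxon_ids})

    variances = combined.var(axis=0)
    zero_var = list(variances.index[variances == 0])
    if zero_var:
        logger.info("dropping %d zero-variance taxa before correlation",
                    len(zero_var))
        combined = combined.drop(columns=zero_var)
    taxa = list(combined.columns)
    X = combined.to_numpy(float)
    n_taxa = len(taxa)
    if n_taxa < 2:
        raise ValueError("fewer than 2 variable taxa; no network possible")

    rho = spearmanr(X).statistic
    if np.isscalar(rho):  # spearmanr collapses to a scalar for 2 columns
        rho = np.array([[1.0, rho], [rho, 1.0]])

    # taxon-profile Bray-Curtis similarity on per-sample relative abundances
    rel = X / X.sum(axis=1, keepdims=True)
    profiles = rel.T
    sim = 1.0 - squareform(pdist(profiles, metric="braycurtis"))
    iu = np.triu_indices(n_taxa, k=1)
    sim_pool = sim[iu]
    lo = np.quantile(sim_pool, bc_tail_fraction)
    hi = np.quantile(sim_pool, 1.0 - bc_tail_fraction)

    g = nx.Graph()
    rel_mean = rel.mean(axis=0)
    for a, b in zip(*iu):
        r = rho[a, b]
        if abs(r) < rho_threshold:
            continue
        if require_bc_support:
            s = sim[a, b]
            if r > 0 and s < hi:
                continue
            if r < 0 and s > lo:
                continue
        sign = "coexistence" if r > 0 else "exclusion"
        g.add_edge(taxa[a], taxa[b], rho=float(r), sign=sign)

    for v in g.nodes:
        i = taxa.index(v)
        dom = (taxonomy.domain_of(v) if taxonomy is not None else domains[v])
        phy = (taxonomy.phylum_of(v) if taxonomy is not None else "Unclassified")
        g.nodes[v].update(domain=dom, phylum=phy,
                          mean_rel_abundance=float(rel_mean[i]))
    n_isolated = n_taxa - g.number_of_nodes()
    return SignedGraph(g, n_isolated_dropped=n_isolated,
                       n_zero_variance_dropped=len(zero_var))


def topology(g: SignedGraph) -> TopologyMetrics:
    """Compute the topology panel for a signed network (sign-blind paths).

    Centralization is Freeman's degree centralization
    ``sum(deg_max - deg_i) / ((|V|-1)(|V|-2))`` (NaN for |V| < 3);
    heterogeneity is sd(degree)/mean(degree) (population sd); the average
    path length averages shortest paths over connected pairs only.
    """
    G = g.graph
    n, m = G.number_of_nodes(), G.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    signs = [d["sign"] for _, _, d in G.edges(data=True)]
    n_co = signs.count("coexistence")
    pct_co = 100.0 * n_co / m if m else 0.0
    pct_ex = 100.0 - pct_co if m else 0.0

    clustering = float(np.mean(list(nx.clustering(G).values()))) if n else 0.0
    components = nx.number_connected_components(G)
    if n < 3:
        centralization = float("nan")
    else:
        centralization = float((degrees.max() - degrees).sum()
                               / ((n - 1) * (n - 2)))
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg else 0.0

    total_len = 0
    total_pairs = 0
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(lengths.values())
        total_pairs += sub.number_of_nodes() * (sub.number_of_nodes() - 1)
    avg_path = total_len / total_pairs if total_pairs else float("nan")

    doms = [d.get("domain", "") for _, d in G.nodes(data=True)]
    pct_euk = 100.0 * doms.count("Eukaryota") / n
    pct_bact = 100.0 * doms.count("Bacteria") / n

    return TopologyMetrics(
        edge_node_ratio=m / n,
        pct_coexistence=pct_co,
        pct_exclusion=pct_ex,
        max_degree=int(degrees.max()),
        clustering_coefficient=clustering,
        connected_components=components,
        centralization=centralization,
        density=density,
        heterogeneity=heterogeneity,
        average_degree=float(2.0 * m / n),
        average_path_length=float(avg_path),
        pct_eukaryota_nodes=pct_euk,
        pct_bacteria_nodes=pct_bact,
    )


def network_by_group(
    t_bact: OtuTable,
    t_euk: OtuTable,
    taxonomy: TaxonomyTable | None,
    groups: GroupAssignment,
    min_samples: int = 5,
    **infer_kwargs,
) -> dict:
    """One network + topology panel per group level.

    Levels with fewer than ``min_samples`` samples (or whose filtered
    tables collapse) are skipped with a warning-level log message.
    """
    import warnings

    out = {}
    for level in groups.levels:
        samples = [s for s in groups.level_samples(level)
                   if s in t_bact.sample_ids]
        if len(samples) < min_samples:
            warnings.warn(f"group {level!r}: fewer than {min_samples} samples; skipped")
            continue
        try:
            sub_b = t_bact.select_samples(samples)
            sub_e = t_euk.select_samples(samples)
            graph = infer_edges(sub_b, sub_e, taxonomy, **infer_kwargs)
            out[level] = (graph, topology(graph))
        except ValueError as exc:
            warnings.warn(f"group {level!r} skipped: {exc}")
    return out


def topology_table(results: dict) -> pd.DataFrame:
    """Metrics x groups table (the topology-panel layout)."""
    cols = {level: metrics.as_series(level)
            for level, (graph, metrics) in results.items()}
    return pd.DataFrame(cols)


def write_graphml(g: SignedGraph, path) -> None:
    nx.write_graphml(g.graph, path)
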