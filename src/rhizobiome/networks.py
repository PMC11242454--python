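"""Compositional co-occurrence networks per sample group and their comparison.

Pipeline per group: agglomerate ASV counts to genus level, apply the
centered log-ratio (clr) transform to address compositionality, compute all
pairwise Pearson correlations, and keep an edge only if it passes the full
conjunction |r| ≥ r_min AND t-test p ≤ α AND local FDR ≤ lfdr_max.  The
resulting signed weighted network is partitioned into modules by greedy
modularity maximization; hub taxa are nodes whose eigenvector centrality
exceeds the empirical 95% quantile.  Topology metrics (components counted
over the full genus universe, clustering coefficient, modularity, positive
edge percentage, edge density, natural-connectivity robustness, average
path length, number of modules) support side-by-side group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable

__all__ = [
    "AssociationNetwork",
    "NetworkProperties",
    "agglomerate_genus",
    "clr_transform",
    "correlation_edges",
    "build_network",
    "detect_modules",
    "hub_taxa",
    "natural_connectivity",
    "network_properties",
    "compare_networks",
]

RANK_ORDER = ["domain", "phylum", "class", "order", "family", "genus"]


def agglomerate_genus(table: FeatureTable, taxonomy: pd.DataFrame) -> FeatureTable:
    """Sum counts over taxa sharing their deepest classified rank label.

    Taxa classified to genus keep the genus name; taxa unclassified at genus
    are pooled under ``U. <deepest classified rank label>`` (e.g. an ASV
    resolved only to order Vicinamibacterales becomes ``U.
    Vicinamibacterales``).  Total reads per sample are conserved.
    """
    missing = [t for t in table.taxon_ids if t not in taxonomy.index]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing[:5]}")
    labels = {}
    for taxon in table.taxon_ids:
        lineage = taxonomy.loc[taxon]
        label = None
        genus = lineage.get("genus")
        if genus is not None and not pd.isna(genus):
            label = str(genus)
        else:
            for rank in reversed(RANK_ORDER[:-1]):
                value = lineage.get(rank)
                if value is not None and not pd.isna(value):
                    label = f"U. {value}"
                    break
        if label is None:
            raise ValueError(f"taxon {taxon!r} has an empty lineage")
        labels[taxon] = label
    grouped = table.data.T.groupby(pd.Series(labels)).sum().T
    return FeatureTable(grouped, is_relative=table.is_relative)


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform per sample: ln(x + c) − mean ln(x + c)."""
    x = table.to_numpy()
    if np.any(x < 0):
        raise ValueError("clr_transform requires non-negative abundances")
    logged = np.log(x + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)


def _local_fdr(z: np.ndarray) -> np.ndarray:
    """Two-component empirical-null local FDR for z-scored statistics.

    The null component N(μ₀, σ₀²) is fitted robustly from the central half
    of the z distribution (median and scaled interquartile range), the
    marginal density by a Gaussian KDE, and lfdr(z) = π₀·f₀(z)/f(z)
    clipped to [0, 1] with π₀ capped at 1.
    """
    mu0 = np.median(z)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    sigma0 = max(iqr / 1.349, 1e-12)
    f0 = sps.norm.pdf(z, loc=mu0, scale=sigma0)
    kde = sps.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    pi0 = min(1.0, 1.0 / np.max(f0 / f))
    return np.clip(pi0 * f0 / f, 0.0, 1.0)


def correlation_edges(
    clr: pd.DataFrame,
    r_min: float = 0.3,
    alpha: float = 0.0001,
    lfdr_max: float = 0.2,
) -> pd.DataFrame:
    """Pearson edges surviving the conjunction of all three sparsification rules.

    For every genus pair (i < j): Pearson r on clr abundances; two-sided
    t-test with t = r·√((n−2)/(1−r²)); local FDR on the Fisher-z-transformed
    correlations (when fewer than 200 pairs are tested the empirical-null
    fit is unstable and Benjamini–Hochberg q-values are substituted, with a
    logged notice).  Zero-variance genera are excluded with a warning.
    """
    if clr.shape[0] < 4:
        raise ValueError("need at least 4 samples to test correlations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X = clr.to_numpy()
    sd = X.std(axis=0)
    dead = clr.columns[sd == 0].tolist()
    if dead:
        warnings.warn(f"excluding zero-variance genera: {dead[:5]}", stacklevel=2)
        clr = clr.drop(columns=dead)
        X = clr.to_numpy()
    n, m = X.shape
    empty = pd.DataFrame(columns=["source", "target", "r", "p", "lfdr", "sign"])
    if m < 2:
        return empty
    R = np.corrcoef(X, rowvar=False)
    iu, ju = np.triu_indices(m, k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    edges = pd.DataFrame(
        {
            "source": clr.columns.to_numpy()[iu],
            "target": clr.columns.to_numpy()[ju],
            "r": r,
            "p": p,
        }
    )
    if len(edges) < 200:
        warnings.warn(
            f"only {len(edges)} correlation tests; substituting BH q-values "
            "for the empirical-null local FDR",
            stacklevel=2,
        )
        edges["lfdr"] = multipletests(p, method="fdr_bh")[1]
    else:
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        edges["lfdr"] = _local_fdr(z)
    edges["sign"] = np.sign(edges["r"]).astype(int)
    keep = (np.abs(edges["r"]) >= r_min) & (edges["p"] <= alpha) & (edges["lfdr"] <= lfdr_max)
    return edges[keep].reset_index(drop=True)


@dataclass
class AssociationNetwork:
    """Genus-level co-occurrence network for one sample group."""

    graph: nx.Graph
    edges: pd.DataFrame
    node_universe: list[str]
    modules: dict[str, int] = field(default_factory=dict)
    modularity: float | None = None
    hubs: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class NetworkProperties:
    n_nodes: int
    n_edges: int
    n_components: int
    clustering_coefficient: float
    modularity: float | None
    positive_edge_pct: float
    edge_density: float
    robustness: float
    robustness_raw: float
    average_path_length: float
    n_modules: int

    def as_dict(self) -> dict:
        return {
            "Connected nodes": self.n_nodes,
            "Edges": self.n_edges,
            "Number of components": self.n_components,
            "Clustering coefficient": self.clustering_coefficient,
            "Modularity": self.modularity,
            "Positive edge (%)": self.positive_edge_pct,
            "Edge density": self.edge_density,
            "Robustness": self.robustness,
            "Average path length": self.average_path_length,
            "Number of modules": self.n_modules,
        }


def build_network(
    table: FeatureTable,
    taxonomy: pd.DataFrame,
    r_min: float = 0.3,
    alpha: float = 0.0001,
    lfdr_max: float = 0.2,
    pseudocount: float = 1.0,
) -> AssociationNetwork:
    """Full per-group network construction from an ASV count table."""
    genus = agglomerate_genus(table, taxonomy)
    clr = clr_transform(genus, pseudocount=pseudocount)
    edges = correlation_edges(clr, r_min=r_min, alpha=alpha, lfdr_max=lfdr_max)
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=abs(row.r), r=row.r, p=row.p, lfdr=row.lfdr)
    rel = genus.to_numpy() / genus.to_numpy().sum(axis=1, keepdims=True)
    mean_rel = dict(zip(genus.taxon_ids, rel.mean(axis=0)))
    nx.set_node_attributes(g, {n: mean_rel.get(n, 0.0) for n in g.nodes}, "abundance")
    net = AssociationNetwork(graph=g, edges=edges, node_universe=list(genus.taxon_ids))
    net.modules, net.modularity = detect_modules(net)
    net.hubs = hub_taxa(net)
    nx.set_node_attributes(g, {n: net.modules.get(n, -1) for n in g.nodes}, "module")
    nx.set_node_attributes(g, {n: n in net.hubs for n in g.nodes}, "hub")
    return net


def detect_modules(network: AssociationNetwork | nx.Graph) -> tuple[dict[str, int], float | None]:
    """Greedy (Clauset–Newman–Moore) modularity maximization on |r| weights.

    Returns a node → module-id mapping over the connected part of the
    graph and the modularity Q of the found partition; an empty network
    yields an empty partition with Q reported as missing (None).
    """
    g = network.graph if isinstance(network, AssociationNetwork) else network
    if g.number_of_edges() == 0:
        return {}, None
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    q = nx.community.modularity(g, communities, weight="weight")
    modules = {}
    for i, comm in enumerate(communities):
        for node in comm:
            modules[node] = i
    return modules, float(q)


def hub_taxa(network: AssociationNetwork | nx.Graph, quantile: float = 0.95) -> set[str]:
    """Hub taxa: eigenvector centrality strictly above the empirical quantile.

    Centrality is computed per connected component (≥ 2 nodes) as the
    leading eigenvector of the absolute-weight adjacency, scaled to unit
    maximum within each component; hubs are the nodes whose score exceeds
    the ``quantile`` of the pooled score distribution.  A fully regular
    graph has all scores equal, hence no node strictly above the quantile
    and an empty hub set.
    """
    g = network.graph if isinstance(network, AssociationNetwork) else network
    if g.number_of_edges() == 0:
        return set()
    scores: dict[str, float] = {}
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        nodes = sorted(comp)
        A = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
        eigvals, eigvecs = np.linalg.eigh(A)
        lead = np.abs(eigvecs[:, np.argmax(eigvals)])
        lead /= lead.max()
        scores.update(zip(nodes, lead))
    if not scores:
        return set()
    values = np.array(list(scores.values()))
    cutoff = np.quantile(values, quantile)
    # tolerance so that exact score ties (all-regular graphs) never produce
    # hubs through last-bit floating-point differences
    return {n for n, s in scores.items() if s > cutoff + 1e-9}


def natural_connectivity(g: nx.Graph, normalized: bool = True) -> float:
    """Spectral robustness ln((1/N)·Σ exp(λ_i)) of the unweighted adjacency.

    Computed over the connected (non-isolated) nodes; with ``normalized``
    the value is divided by (N − ln N), a size normalization that makes
    networks of different order comparable.  An edgeless graph scores 0.
    """
    nodes = [n for n in g.nodes if g.degree(n) > 0]
    n = len(nodes)
    if n == 0:
        return 0.0
    A = (np.abs(nx.to_numpy_array(g, nodelist=nodes, weight=None)) > 0).astype(float)
    eigvals = np.linalg.eigvalsh(A)
    # log-sum-exp for numerical stability
    m = eigvals.max()
    core = m + np.log(np.exp(eigvals - m).mean())
    if not normalized:
        return float(core)
    return float(core / (n - np.log(n)))


def network_properties(
    network: AssociationNetwork, node_universe: list[str] | None = None
) -> NetworkProperties:
    """Topology metrics for one group network.

    Components are counted over the full genus universe, so genera that
    never gained an edge appear as singleton components; edge density uses
    the same universe.  Clustering is the mean local transitivity over
    nodes with degree ≥ 2, and the average path length runs over reachable
    pairs of connected nodes only.
    """
    universe = list(node_universe) if node_universe is not None else list(network.node_universe)
    if not universe:
        raise ValueError("node_universe must not be empty")
    missing = set(network.nodes) - set(universe)
    if missing:
        raise ValueError(f"network nodes outside the universe: {sorted(missing)[:5]}")
    g = network.graph
    n_universe = len(universe)
    n_edges = g.number_of_edges()
    connected_nodes = [n for n in g.nodes if g.degree(n) > 0]
    n_isolated = n_universe - len(connected_nodes)
    n_components = nx.number_connected_components(g.subgraph(connected_nodes)) + n_isolated

    deg2 = [n for n in connected_nodes if g.degree(n) >= 2]
    clustering = float(np.mean(list(nx.clustering(g, deg2).values()))) if deg2 else 0.0

    if n_edges:
        pos_pct = 100.0 * float((network.edges["r"] > 0).sum()) / n_edges
    else:
        pos_pct = 0.0
    density = n_edges / (n_universe * (n_universe - 1) / 2.0)

    sub = g.subgraph(connected_nodes)
    lengths = []
    for comp in nx.connected_components(sub):
        cg = sub.subgraph(comp)
        for _, targets in nx.all_pairs_shortest_path_length(cg):
            lengths.extend(v for v in targets.values() if v > 0)
    apl = float(np.mean(lengths)) if lengths else float("nan")

    return NetworkProperties(
        n_nodes=len(connected_nodes),
        n_edges=n_edges,
        n_components=n_components,
        clustering_coefficient=clustering,
        modularity=network.modularity,
        positive_edge_pct=pos_pct,
        edge_density=float(density),
        robustness=natural_connectivity(g, normalized=True),
        robustness_raw=natural_connectivity(g, normalized=False),
        average_path_length=apl,
        n_modules=len(set(network.modules.values())),
    )


def compare_networks(
    tables: dict[str, FeatureTable],
    taxonomy: pd.DataFrame,
    r_min: float = 0.3,
    alpha: float = 0.0001,
    lfdr_max: float = 0.2,
    min_samples: int = 4,
) -> dict:
    """Build one network per group with identical parameters and compare.

    Returns per-group networks and properties plus a hub-overlap report
    separating hubs present in every group ("core hubs") from
    group-specific ones.  Groups with fewer than ``min_samples`` samples
    are skipped with a warning.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 groups to compare")
    networks: dict[str, AssociationNetwork] = {}
    properties: dict[str, NetworkProperties] = {}
    for group, table in tables.items():
        if table.n_samples < min_samples:
            warnings.warn(
                f"group {group!r} has {table.n_samples} samples (< {min_samples}); skipped",
                stacklevel=2,
            )
            continue
        net = build_network(table, taxonomy, r_min=r_min, alpha=alpha, lfdr_max=lfdr_max)
        networks[group] = net
        properties[group] = network_properties(net)
    hub_sets = {g: net.hubs for g, net in networks.items()}
    core_hubs = set.intersection(*hub_sets.values()) if hub_sets else set()
    specific = {
        g: hubs - set.union(set(), *(h for gg, h in hub_sets.items() if gg != g))
        for g, hubs in hub_sets.items()
    }
    return {
        "networks": networks,
        "properties": properties,
        "core_hubs": core_hubs,
        "group_specific_hubs": specific,
    }
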