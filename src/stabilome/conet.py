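"""Functional-category co-occurrence networks.

Edges are signed Spearman correlations between category relative-abundance
profiles across samples, kept when |r| exceeds a threshold (default 0.75) and
the Benjamini-Hochberg adjusted p-value is below a significance threshold
(default 0.01). Topology (average degree avgK, average clustering coefficient
avgCC, average path distance APD, modularity M, graph density GD) is compared
against an identically sized Erdos-Renyi G(n, m) ensemble, and node roles are
assigned from the within-module degree z-score Zi and the among-module
participation coefficient Pi with the classical (2.5, 0.62) thresholds:
module hubs and network hubs (Zi > 2.5) are the candidate keystone categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stabilome.functional_classes import (
    ENVIRONMENTAL_RESPONSE_CLASSES,
    METABOLIC_CLASSES,
    UNMAPPED,
)
from stabilome.io_model import CountTable

__all__ = [
    "correlate_all_pairs",
    "build_network",
    "topology_summary",
    "random_ensemble_summary",
    "partition_modules",
    "node_roles",
    "role_from_zi_pi",
    "edge_sign_summary",
    "TopologySummary",
    "write_graphml",
    "write_edge_list",
]

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def correlate_all_pairs(table: CountTable) -> pd.DataFrame:
    """Spearman r, two-sided p and BH-adjusted q for every unordered feature pair.

    Ties get average ranks; p-values use the t approximation. Pairs involving a
    constant feature are undefined and excluded from the BH family (their count
    is visible as rows with NaN q).
    """
    X = table.values.astype(float)
    n_feat, n_samp = X.shape
    if n_samp < 4:
        raise ValueError("need >= 4 samples for pairwise correlation")
    if n_feat < 2:
        raise ValueError("need >= 2 features")
    constant = np.array([np.unique(row).size < 2 for row in X])
    # Spearman = Pearson on average ranks; two-sided p via the t approximation
    ranks = stats.rankdata(X, axis=1)
    ranks[constant] = np.arange(n_samp)  # placeholder; pairs are flagged undefined
    rho = np.corrcoef(ranks)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n_samp - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n_samp - 2)
    pval[np.isclose(np.abs(rho), 1.0)] = 0.0
    rows = []
    for i, j in combinations(range(n_feat), 2):
        und = constant[i] or constant[j]
        rows.append({
            "feature_a": table.features[i],
            "feature_b": table.features[j],
            "r": np.nan if und else rho[i, j],
            "p": np.nan if und else pval[i, j],
        })
    edges = pd.DataFrame(rows)
    defined = edges["p"].notna()
    edges["q"] = np.nan
    if defined.any():
        edges.loc[defined, "q"] = multipletests(
            edges.loc[defined, "p"].to_numpy(), method="fdr_bh"
        )[1]
    edges["sign"] = np.sign(edges["r"]).where(edges["r"].notna())
    return edges


def build_network(edges: pd.DataFrame, r_min: float = 0.75, q_max: float = 0.01,
                  use_raw_p: bool = False) -> nx.Graph:
    """Threshold the edge table into a simple undirected signed graph.

    An edge is retained iff |r| > r_min and its (BH-adjusted by default)
    significance is below q_max. The magnitude reading of the correlation
    threshold is what admits negative (co-exclusion) edges. Isolated
    categories are not added as nodes; an empty result is a valid (warned,
    not fatal) outcome.
    """
    pcol = "p" if use_raw_p else "q"
    keep = edges[(edges["r"].abs() > r_min) & (edges[pcol] < q_max)]
    g = nx.Graph()
    for _, row in keep.iterrows():
        g.add_edge(row["feature_a"], row["feature_b"],
                   r=float(row["r"]), sign=int(row["sign"]))
    return g


def partition_modules(net: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Seeded Louvain partition and its Newman-Girvan modularity (unweighted)."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    comms = louvain_communities(net, seed=seed, weight=None)
    m = modularity(net, comms, weight=None)
    assignment = {node: i for i, comm in enumerate(comms) for node in comm}
    return assignment, float(m)


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    avg_k: float
    avg_cc: float
    apd: float
    modularity: float
    graph_density: float
    connected_pair_fraction: float
    n_positive: int
    n_negative: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def _average_path_distance(net: nx.Graph) -> tuple[float, float]:
    """Mean shortest-path length over connected pairs; fraction of pairs connected."""
    n = net.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    if total_pairs == 0:
        return float("nan"), 0.0
    path_sum, connected_pairs = 0, 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())
        connected_pairs += k * (k - 1) // 2
    if connected_pairs == 0:
        return float("nan"), 0.0
    return path_sum / (2 * connected_pairs), connected_pairs / total_pairs


def topology_summary(net: nx.Graph, seed: int = 0,
                     partition_modularity: float | None = None) -> TopologySummary:
    """Global topology metrics under the conventions used throughout.

    avgK = 2m/n; avgCC averages local clustering with degree<2 nodes
    contributing 0; APD averages shortest paths over connected pairs only;
    GD = avgK/(n-1); M comes from the seeded Louvain partition unless the
    caller already has one.
    """
    n, m = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        raise ValueError("empty network has no topology")
    avg_k = 2 * m / n
    avg_cc = nx.average_clustering(net, count_zeros=True)
    apd, frac = _average_path_distance(net)
    if partition_modularity is None:
        _, partition_modularity = partition_modules(net, seed=seed)
    gd = 2 * m / (n * (n - 1)) if n > 1 else float("nan")
    signs = nx.get_edge_attributes(net, "sign")
    n_pos = sum(1 for s in signs.values() if s > 0)
    n_neg = sum(1 for s in signs.values() if s < 0)
    if not signs:  # unsigned graphs (e.g. random nulls) count all edges positive
        n_pos, n_neg = m, 0
    return TopologySummary(
        n_nodes=n, n_links=m, avg_k=avg_k, avg_cc=avg_cc, apd=apd,
        modularity=partition_modularity, graph_density=gd,
        connected_pair_fraction=frac, n_positive=n_pos, n_negative=n_neg,
    )


def random_ensemble_summary(net: nx.Graph, n_draws: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mean and sd of topology metrics over an identically sized G(n, m) ensemble.

    Each draw is uniform over simple graphs with exactly the empirical node and
    edge counts, so avgK and GD are identical in every draw and only avgCC,
    APD and M vary.
    """
    if n_draws < 10:
        raise ValueError("need >= 10 ensemble draws")
    n, m = net.number_of_nodes(), net.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("edge count exceeds simple-graph maximum")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_draws):
        draw_seed = int(rng.integers(2**31 - 1))
        g = nx.gnm_random_graph(n, m, seed=draw_seed)
        s = topology_summary(g, seed=draw_seed)
        rows.append({"avg_k": s.avg_k, "avg_cc": s.avg_cc, "apd": s.apd,
                     "modularity": s.modularity, "graph_density": s.graph_density})
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def role_from_zi_pi(zi: float, pi: float) -> str:
    """Four-region Guimera-Amaral taxonomy on the (Zi, Pi) plane."""
    if zi > ZI_THRESHOLD:
        return ROLE_NETWORK_HUB if pi > PI_THRESHOLD else ROLE_MODULE_HUB
    return ROLE_CONNECTOR if pi > PI_THRESHOLD else ROLE_PERIPHERAL


def node_roles(net: nx.Graph, partition: dict) -> pd.DataFrame:
    """Zi/Pi and the four-region role per node.

    Zi is the z-score of a node's within-module degree against its module's
    within-module degrees (population sd; a zero-sd module gives Zi = 0).
    Pi = 1 - sum_s (k_is / k_i)^2 over modules s. Isolated nodes (degree 0)
    have undefined Pi and are reported with role ``isolated``.
    """
    missing = [v for v in net.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    modules: dict[int, list] = {}
    for node, mod in partition.items():
        if node in net:
            modules.setdefault(mod, []).append(node)
    within = {}
    for mod, members in modules.items():
        member_set = set(members)
        for v in members:
            within[v] = sum(1 for u in net.neighbors(v) if u in member_set)
    rows = []
    for mod, members in modules.items():
        kin = np.array([within[v] for v in members], dtype=float)
        mu, sigma = kin.mean(), kin.std(ddof=0)
        for v in members:
            k = net.degree(v)
            if k == 0:
                rows.append({"node": v, "module": mod, "zi": 0.0, "pi": np.nan,
                             "role": "isolated"})
                continue
            zi = 0.0 if sigma == 0 else (within[v] - mu) / sigma
            per_mod = {}
            for u in net.neighbors(v):
                per_mod[partition[u]] = per_mod.get(partition[u], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
            rows.append({"node": v, "module": mod, "zi": zi, "pi": pi,
                         "role": role_from_zi_pi(zi, pi)})
    return pd.DataFrame(rows).set_index("node")


def edge_sign_summary(net: nx.Graph, classes: dict[str, str]) -> pd.DataFrame:
    """Positive/negative edge counts inside the metabolic and environmental aggregates.

    The metabolic aggregate pools specialized + broad metabolic classes; the
    environmental-responses aggregate pools cellular processes + environmental
    information processing. Edges bridging the two aggregates, touching other
    classes, or touching unmapped nodes are tallied separately.
    """
    counts = {
        "metabolic": [0, 0],
        "environmental_responses": [0, 0],
        "cross_aggregate": [0, 0],
        "other": [0, 0],
    }
    unmapped_nodes = sorted(v for v in net.nodes if classes.get(v, UNMAPPED) == UNMAPPED)
    for u, v, data in net.edges(data=True):
        cu, cv = classes.get(u, UNMAPPED), classes.get(v, UNMAPPED)
        slot = 0 if data.get("sign", 1) > 0 else 1
        in_met = {cu, cv} <= METABOLIC_CLASSES
        in_env = {cu, cv} <= ENVIRONMENTAL_RESPONSE_CLASSES
        met_touch = bool({cu, cv} & METABOLIC_CLASSES)
        env_touch = bool({cu, cv} & ENVIRONMENTAL_RESPONSE_CLASSES)
        if in_met:
            counts["metabolic"][slot] += 1
        elif in_env:
            counts["environmental_responses"][slot] += 1
        elif met_touch and env_touch:
            counts["cross_aggregate"][slot] += 1
        else:
            counts["other"][slot] += 1
    df = pd.DataFrame(counts, index=["positive", "negative"]).T
    df.attrs["unmapped_nodes"] = unmapped_nodes
    return df


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v, "r": d.get("r", np.nan),
             "sign": d.get("sign", 1)} for u, v, d in net.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
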