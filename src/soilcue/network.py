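"""Co-occurrence networks: Spearman edges, modules, Zi/Pi node roles.

The network is built from pairwise Spearman correlations between ASV
count profiles across sites: an edge is kept when |r| > r_min (default
0.8) and the two-sided p-value < alpha (default 0.05). Modules are
detected by greedy (Clauset–Newman–Moore) modularity maximization, which
is deterministic, and labeled ``Mod#0, Mod#1, …`` in order of decreasing
size. Node roles follow the cartographic within-module degree z-score
(Zi) and participation coefficient (Pi) with the classical thresholds
Zi ≥ 2.5 and Pi ≥ 0.62.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from scipy import stats

from .utils import significance_stars, spearman_matrix

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CooccurrenceNetwork:
    """Thresholded correlation graph with (optionally) a module partition."""

    graph: nx.Graph
    edges: pd.DataFrame  # columns: node1, node2, r, p
    partition: dict[str, str] = field(default_factory=dict)


def prefilter_asvs(
    table: pd.DataFrame,
    min_prevalence: float = 0.0,
    min_rel_abundance: float = 0.0,
) -> pd.DataFrame:
    """Drop rare ASVs before correlation.

    Keeps ASVs present (count > 0) in at least ``min_prevalence`` of
    sites and with mean relative abundance at least ``min_rel_abundance``.
    Both thresholds are fractions in [0, 1]; (0, 0) is the identity.
    """
    for name, v in (("min_prevalence", min_prevalence),
                    ("min_rel_abundance", min_rel_abundance)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    prevalence = (table > 0).mean(axis=0)
    rel = table.div(table.sum(axis=1), axis=0).mean(axis=0)
    keep = (prevalence >= min_prevalence) & (rel >= min_rel_abundance)
    if not keep.any():
        raise ValueError("prefilter removed every ASV")
    return table.loc[:, keep]


def spearman_network(
    table: pd.DataFrame, r_min: float = 0.8, alpha: float = 0.05,
    fdr: bool = False,
) -> CooccurrenceNetwork:
    """Build the thresholded Spearman co-occurrence graph.

    All ASVs of ``table`` become nodes; edges connect pairs with
    |Spearman r| > ``r_min`` and p < ``alpha`` (Benjamini–Hochberg
    adjusted when ``fdr``). Constant ASV profiles have undefined
    correlations and contribute no edges (warning).
    """
    if len(table) < 4:
        raise ValueError("need at least 4 sites for a co-occurrence network")
    asv_ids = list(table.columns)
    X = table.to_numpy(dtype=float)
    constant = [a for a, col in zip(asv_ids, X.T) if np.ptp(col) == 0]
    if constant:
        logger.warning("constant ASV profiles excluded from correlation: %s",
                       constant[:10])
    res = stats.spearmanr(X)
    if np.ndim(res.statistic) == 0:  # scipy returns a scalar for 2 columns
        r = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        p = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        r, p = res.statistic, res.pvalue
    iu = np.triu_indices(len(asv_ids), k=1)
    pvals = p[iu]
    if fdr:
        pvals = stats.false_discovery_control(pvals, method="bh")
    records = []
    G = nx.Graph()
    G.add_nodes_from(asv_ids)
    for (i, j), pv in zip(zip(*iu), pvals):
        rv = r[i, j]
        if np.isnan(rv) or np.isnan(pv):
            continue
        if abs(rv) > r_min and pv < alpha:
            G.add_edge(asv_ids[i], asv_ids[j], r=float(rv), p=float(pv))
            records.append({"node1": asv_ids[i], "node2": asv_ids[j],
                            "r": float(rv), "p": float(pv)})
    edges = pd.DataFrame.from_records(records, columns=["node1", "node2", "r", "p"])
    return CooccurrenceNetwork(graph=G, edges=edges)


def detect_modules(network: CooccurrenceNetwork, seed: int | None = None) -> dict[str, str]:
    """Greedy-modularity module partition, labeled by descending size.

    Deterministic: Clauset–Newman–Moore agglomeration on the unweighted
    graph. Nodes without edges become singleton modules. ``seed`` is
    accepted for interface symmetry; the default algorithm ignores it.
    Returns a mapping node → ``"Mod#k"`` and stores it on the network.
    """
    G = network.graph
    if G.number_of_edges() == 0:
        logger.warning("network has no edges; every node is its own module")
        communities = [{n} for n in sorted(G.nodes)]
    else:
        connected = sorted(n for n in G.nodes if G.degree(n) > 0)
        communities = [set(c) for c in
                       greedy_modularity_communities(G.subgraph(connected))]
        communities += [{n} for n in sorted(G.nodes) if G.degree(n) == 0]
    communities.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    partition = {node: f"Mod#{k}" for k, c in enumerate(communities) for node in c}
    network.partition = partition
    return partition


def compute_zi_pi(
    network: CooccurrenceNetwork, partition: dict[str, str] | None = None
) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's
    mean and SD (Zi = 0 when the module SD is 0). Pi = 1 − Σ_t (k_it/k_i)²
    over the modules t the node touches; an isolated node has Pi = 0.
    Degrees are unweighted.
    """
    partition = partition or network.partition
    if not partition:
        raise ValueError("no partition: run detect_modules first")
    G = network.graph
    within = {}
    for node in G.nodes:
        mod = partition[node]
        within[node] = sum(1 for nb in G.neighbors(node) if partition[nb] == mod)
    by_module: dict[str, list[str]] = {}
    for node, mod in partition.items():
        by_module.setdefault(mod, []).append(node)
    records = []
    for node in G.nodes:
        mod = partition[node]
        kin = np.array([within[m] for m in by_module[mod]], dtype=float)
        sd = kin.std()
        zi = 0.0 if sd == 0 else (within[node] - kin.mean()) / sd
        k = G.degree(node)
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[str, int] = {}
            for nb in G.neighbors(node):
                per_module[partition[nb]] = per_module.get(partition[nb], 0) + 1
            pi = 1.0 - sum((kt / k) ** 2 for kt in per_module.values())
        records.append({"node": node, "module": mod, "degree": k,
                        "zi": float(zi), "pi": float(pi)})
    return pd.DataFrame.from_records(records).set_index("node")


def classify_roles(
    topology: pd.DataFrame,
    zi_thr: float = ZI_THRESHOLD,
    pi_thr: float = PI_THRESHOLD,
) -> pd.Series:
    """Cartographic role labels from Zi/Pi.

    module hub (Zi≥thr, Pi<thr), connector (Zi<thr, Pi≥thr), network hub
    (both ≥), peripheral otherwise.
    """
    def role(row):
        hi_z = row["zi"] >= zi_thr
        hi_p = row["pi"] >= pi_thr
        if hi_z and hi_p:
            return "network hub"
        if hi_z:
            return "module hub"
        if hi_p:
            return "connector"
        return "peripheral"

    return topology.apply(role, axis=1).rename("role")


def module_abundance(table: pd.DataFrame, partition: dict[str, str]) -> pd.DataFrame:
    """Per-site summed relative abundance of each module's member ASVs."""
    rel = table.div(table.sum(axis=1), axis=0)
    modules = sorted(set(partition.values()))
    out = {}
    for mod in modules:
        members = [a for a in table.columns if partition.get(a) == mod]
        out[mod] = rel[members].sum(axis=1)
    return pd.DataFrame(out)


def module_factor_correlation(
    table: pd.DataFrame,
    partition: dict[str, str],
    factors: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlations between module abundances and site factors.

    Returns a long-form table (module, factor, r, p, stars). Missing
    factor values are handled pairwise-complete; constant module
    abundances (e.g. a module containing every ASV) yield NaN and are
    flagged by a warning from the correlation helper.
    """
    abundance = module_abundance(table, partition)
    shared = abundance.index.intersection(factors.index)
    if len(shared) < 4:
        raise ValueError("module and factor tables share fewer than 4 sites")
    r, p = spearman_matrix(abundance.loc[shared], factors.loc[shared])
    records = []
    for mod in r.index:
        for fac in r.columns:
            pv = p.loc[mod, fac]
            records.append({"module": mod, "factor": fac,
                            "r": r.loc[mod, fac], "p": pv,
                            "stars": significance_stars(pv)})
    return pd.DataFrame.from_records(records)
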