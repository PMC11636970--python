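"""Taxon co-occurrence networks with topological role classification.

Edges are Spearman correlations passing p < 0.05 and |rho| > 0.3, capped
at the 200 strongest |rho| (all three thresholds configurable).  Modules
come from seeded modularity maximization; each node then gets a
within-module connectivity z-score (Zi) and an among-module participation
coefficient (Pi), and is classified as module hub (Zi>2.5, Pi<0.62),
connector (Zi<2.5, Pi>0.62), network hub (both high) or peripheral.  The
connectors are the network's "core species".  All threshold comparisons
are strict, so a node sitting exactly on a boundary is peripheral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable

log = logging.getLogger("keloidomics.network")


def spearman_matrix(tab: AbundanceTable) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs tie-midrank Spearman rho with two-sided p from the
    t approximation (df = n - 2).  Constant features get NaN against every
    partner and can never become edges; the diagonal is rho=1, p=0."""
    vals = tab.values
    n = vals.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = stats.spearmanr(vals, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the two-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    rho = np.asarray(rho, float).copy()
    p = np.asarray(p, float).copy()
    const = vals.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    ids = tab.feature_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def spearman_cross(a: pd.DataFrame, b: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Spearman rho/p between every column of ``a`` and every column of
    ``b`` over their (aligned) rows; same midrank + t-approximation
    machinery as :func:`spearman_matrix`."""
    n = a.shape[0]
    ra = stats.rankdata(a.to_numpy(float), axis=0)
    rb = stats.rankdata(b.to_numpy(float), axis=0)
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    rho = ra.T @ rb / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    return rho, p


def build_network(rho: pd.DataFrame, p: pd.DataFrame, corr_p: float = 0.05,
                  corr_r: float = 0.3, top_edges: int = 200) -> nx.Graph:
    """Candidate edges satisfy p < corr_p AND |rho| > corr_r (strict); they
    are ranked by |rho| descending and the first ``top_edges`` kept, ties
    at the cut broken by lexicographic (u, v) order.  Isolated nodes stay
    in the node set."""
    ids = list(rho.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    rv, pv = rho.to_numpy(float), p.to_numpy(float)
    cand = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r_ij, p_ij = rv[i, j], pv[i, j]
            if np.isnan(r_ij) or np.isnan(p_ij):
                continue
            if p_ij < corr_p and abs(r_ij) > corr_r:
                u, v = sorted((ids[i], ids[j]))
                cand.append((-abs(r_ij), u, v, r_ij, p_ij))
    cand.sort()
    for _, u, v, r_ij, p_ij in cand[:top_edges]:
        g.add_edge(u, v, rho=float(r_ij), p=float(p_ij),
                   sign="pos" if r_ij > 0 else "neg")
    log.info("network: %d nodes, %d edges (of %d candidates)",
             g.number_of_nodes(), g.number_of_edges(), len(cand))
    return g


def detect_modules(net: nx.Graph, seed: int = 0) -> Dict[str, int]:
    """Seeded Louvain modularity maximization on the unweighted,
    sign-ignored graph; isolated nodes become singleton modules.  The
    assignment is stored on the graph as the node attribute ``module``."""
    if net.number_of_edges() == 0:
        assign = {n: i for i, n in enumerate(sorted(net.nodes))}
    else:
        comms = nx.community.louvain_communities(net, weight=None, seed=seed)
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        assign = {n: i for i, c in enumerate(comms) for n in c}
    nx.set_node_attributes(net, assign, "module")
    return assign


def zipi(net: nx.Graph, weighted: bool = False) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Within-module connectivity Zi and among-module connectivity Pi.

    Zi = (k_within - mean_module k_within) / sd_module (population sd; 0
    when the sd is 0).  Pi = 1 - sum over modules of (k_to_module / k)^2;
    0 for isolated nodes.  Degrees are unweighted and sign-ignored unless
    ``weighted`` uses |rho| edge weights.  Results are stored as node
    attributes ``Zi`` and ``Pi``.
    """
    module = nx.get_node_attributes(net, "module")
    if len(module) != net.number_of_nodes():
        raise ValueError("modules must be assigned before computing Zi/Pi")

    def _w(u, v) -> float:
        return abs(net[u][v].get("rho", 1.0)) if weighted else 1.0

    k_within: Dict[str, float] = {}
    k_total: Dict[str, float] = {}
    k_per_mod: Dict[str, Dict[int, float]] = {}
    for n in net.nodes:
        per: Dict[int, float] = {}
        for nb in net.neighbors(n):
            per[module[nb]] = per.get(module[nb], 0.0) + _w(n, nb)
        k_per_mod[n] = per
        k_total[n] = sum(per.values())
        k_within[n] = per.get(module[n], 0.0)

    zi: Dict[str, float] = {}
    for m in set(module.values()):
        members = [n for n in net.nodes if module[n] == m]
        kw = np.array([k_within[n] for n in members], dtype=float)
        mu, sd = kw.mean(), kw.std()  # population sd
        for n, k in zip(members, kw):
            zi[n] = float((k - mu) / sd) if sd > 0 else 0.0

    pi: Dict[str, float] = {}
    for n in net.nodes:
        k = k_total[n]
        if k == 0:
            pi[n] = 0.0
        else:
            pi[n] = float(1.0 - sum((km / k) ** 2 for km in k_per_mod[n].values()))

    nx.set_node_attributes(net, zi, "Zi")
    nx.set_node_attributes(net, pi, "Pi")
    return zi, pi


def classify_nodes(net: nx.Graph, zi_cut: float = 2.5, pi_cut: float = 0.62
                   ) -> Tuple[Dict[str, str], List[str]]:
    """Strict-threshold role assignment and the core-species list.

    module hub: Zi > zi_cut and Pi < pi_cut; connector: Zi < zi_cut and
    Pi > pi_cut; network hub: both above; values exactly on a threshold
    fall to peripheral.  Core species are the connectors.
    """
    zi = nx.get_node_attributes(net, "Zi")
    pi = nx.get_node_attributes(net, "Pi")
    if len(zi) != net.number_of_nodes():
        raise ValueError("Zi/Pi must be computed before classification")
    cat: Dict[str, str] = {}
    for n in net.nodes:
        z, p = zi[n], pi[n]
        if z > zi_cut and p < pi_cut:
            cat[n] = "module_hub"
        elif z < zi_cut and p > pi_cut:
            cat[n] = "connector"
        elif z > zi_cut and p > pi_cut:
            cat[n] = "network_hub"
        else:
            cat[n] = "peripheral"
    nx.set_node_attributes(net, cat, "category")
    core = sorted(n for n, c in cat.items() if c == "connector")
    log.info("roles: %d module hubs, %d connectors (core), %d network hubs",
             sum(c == "module_hub" for c in cat.values()), len(core),
             sum(c == "network_hub" for c in cat.values()))
    return cat, core


def finalize_network(tab: AbundanceTable, corr_p: float = 0.05,
                     corr_r: float = 0.3, top_edges: int = 200,
                     zi_cut: float = 2.5, pi_cut: float = 0.62,
                     seed: int = 0, weighted: bool = False) -> nx.Graph:
    """Convenience: correlate, build, modularize, score and classify."""
    rho, p = spearman_matrix(tab)
    net = build_network(rho, p, corr_p, corr_r, top_edges)
    detect_modules(net, seed=seed)
    zipi(net, weighted=weighted)
    classify_nodes(net, zi_cut, pi_cut)
    return net


@dataclass
class NetworkComparison:
    shared_core: List[str]
    edge_counts: Dict[str, Dict[str, int]]   # net label -> {pos, neg}
    neighbors: Dict[str, Dict[str, List[str]]]  # node -> net label -> sorted neighbors


def compare_networks(net_a: nx.Graph, net_b: nx.Graph,
                     labels: Tuple[str, str] = ("MK", "NS"),
                     named_nodes: Optional[Sequence[str]] = None) -> NetworkComparison:
    """Shared core species, per-network positive/negative edge counts, and
    the neighbor sets of any named nodes; all output lists sorted."""
    cores = []
    for net in (net_a, net_b):
        cat = nx.get_node_attributes(net, "category")
        cores.append({n for n, c in cat.items() if c == "connector"})
    shared = sorted(cores[0] & cores[1])
    counts = {}
    for lab, net in zip(labels, (net_a, net_b)):
        signs = [d["sign"] for _, _, d in net.edges(data=True)]
        counts[lab] = {"pos": signs.count("pos"), "neg": signs.count("neg")}
    nbrs: Dict[str, Dict[str, List[str]]] = {}
    for n in named_nodes or []:
        nbrs[n] = {lab: sorted(net.neighbors(n)) if n in net else []
                   for lab, net in zip(labels, (net_a, net_b))}
    return NetworkComparison(shared, counts, nbrs)
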