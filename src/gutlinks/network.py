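"""Signed co-occurrence networks, topology statistics, MCODE modules, PCIT.

Edges are correlation estimates passing a magnitude threshold (|rho| > 0.65
by default); negative edges are read as competition, positive as
co-occurrence.  Network "stability" is summarised as the percentage of
negative edges and "complexity" as the average number of edges per node.
Module detection follows MCODE (molecular complex detection): vertices are
weighted by the density of the highest k-core of their closed neighbourhood,
complexes are grown greedily from high-weight seeds, and each module is
scored density x size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import CorrelationMatrix

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceNetwork:
    """Undirected signed graph over OTUs plus the threshold that built it."""

    graph: nx.Graph               # all nodes retained; isolated nodes flagged
    threshold: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class TopologyStats:
    n_nodes: int
    n_edges: int
    pct_negative: float
    avg_edges_per_node: float
    mean_clustering_coefficient: float
    density: float
    connected_component_count: int


@dataclass
class NetworkModule:
    members: tuple
    n_edges: int
    density: float
    mcode_score: float
    seed: object


def build_network(corr: CorrelationMatrix, threshold: float = 0.65,
                  p_max: float | None = None,
                  node_abundance: pd.Series | None = None) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a signed co-occurrence network.

    Edge (i, j) exists iff |rho_ij| > threshold (and p_ij <= p_max when a
    p-value gate is requested).  All nodes are kept; isolated ones carry an
    ``isolated=True`` attribute so exports can omit them the way network
    renderers conventionally do.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if p_max is not None and corr.p is None:
        raise ValueError("p_max given but the correlation matrix has no p-values")
    ids = corr.otu_ids
    rho = corr.rho.to_numpy()
    g = nx.Graph()
    for o in ids:
        attrs = {}
        if node_abundance is not None and o in node_abundance.index:
            attrs["mean_rel_abundance"] = float(node_abundance[o])
        g.add_node(o, **attrs)
    pmat = corr.p.to_numpy() if corr.p is not None else None
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            if abs(rho[i, j]) > threshold and (
                    p_max is None or pmat[i, j] <= p_max):
                g.add_edge(ids[i], ids[j], weight=float(rho[i, j]),
                           sign=1 if rho[i, j] > 0 else -1)
    for o in ids:
        g.nodes[o]["isolated"] = g.degree(o) == 0
    if g.number_of_edges() == 0:
        logger.warning("no correlation exceeds |rho| > %s; empty network", threshold)
    return CooccurrenceNetwork(graph=g, threshold=threshold)


def _loop_free_density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def topology(net: CooccurrenceNetwork,
             include_isolated: bool = False) -> TopologyStats:
    """Stability/complexity summary of a network.

    ``avg_edges_per_node`` divides 2E by the number of non-isolated nodes by
    default (isolated nodes are conventionally omitted from network figures);
    ``include_isolated=True`` divides by all nodes instead.
    """
    g = net.graph
    n_edges = g.number_of_edges()
    if n_edges == 0:
        logger.warning("zero-edge network; topology statistics reported as 0")
        return TopologyStats(g.number_of_nodes(), 0, 0.0, 0.0, 0.0, 0.0,
                             nx.number_connected_components(g))
    non_isolated = [v for v in g if g.degree(v) > 0]
    n_negative = sum(1 for _, _, d in g.edges(data=True) if d["weight"] < 0)
    denom_nodes = g.number_of_nodes() if include_isolated else len(non_isolated)
    sub = g.subgraph(non_isolated)
    clust = nx.clustering(sub)
    deg2 = [clust[v] for v in sub if sub.degree(v) >= 2]
    return TopologyStats(
        n_nodes=g.number_of_nodes(),
        n_edges=n_edges,
        pct_negative=100.0 * n_negative / n_edges,
        avg_edges_per_node=2.0 * n_edges / denom_nodes,
        mean_clustering_coefficient=float(np.mean(deg2)) if deg2 else 0.0,
        density=_loop_free_density(len(non_isolated), n_edges),
        connected_component_count=nx.number_connected_components(g),
    )


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def _vertex_weights(g: nx.Graph) -> dict:
    """MCODE stage 1: weight = k_max x density of the highest k-core of the
    closed neighbourhood of each vertex."""
    weights = {}
    for v in g:
        nbhd = set(g[v]) | {v}
        sub = g.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        kmax = max(core.values())
        knodes = [u for u, c in core.items() if c >= kmax]
        ksub = sub.subgraph(knodes)
        weights[v] = kmax * _loop_free_density(
            ksub.number_of_nodes(), ksub.number_of_edges())
    return weights


def mcode(net: CooccurrenceNetwork, k_core: int = 2,
          node_score_cutoff: float = 0.2, haircut: bool = True,
          fluff: bool = False, fluff_density: float = 0.2,
          min_size: int = 3) -> list[NetworkModule]:
    """Detect and score dense modules with the MCODE procedure.

    Runs on the unsigned graph (signs are edge metadata only).  Complexes are
    grown from unseen seeds in descending vertex-weight order, admitting
    neighbours whose weight is at least ``seed_weight * (1 - node_score_cutoff)``;
    haircut reduces each complex to its 2-core, the ``k_core`` filter drops
    complexes without a k-core, and modules smaller than ``min_size`` are
    discarded.  Each module is scored (loop-free) density x size and the list
    is sorted by descending score.  Ties in vertex weight are broken by node
    ID so the output is deterministic.
    """
    g = net.graph
    weights = _vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    used: set = set()
    modules: list[NetworkModule] = []
    for seed in order:
        if seed in used or g.degree(seed) == 0:
            continue
        threshold_w = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in g[v]:
                if u in members or u in used:
                    continue
                if weights[u] >= threshold_w:
                    members.add(u)
                    frontier.append(u)
        sub = g.subgraph(members).copy()
        if haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() == 0:
            used |= members
            continue
        core = nx.core_number(sub)
        if max(core.values(), default=0) < k_core:
            used |= members
            continue
        if fluff:
            extra = set()
            for v in list(sub.nodes):
                for u in g[v]:
                    if u in sub or u in used:
                        continue
                    nbhd = set(g[u]) | {u}
                    nsub = g.subgraph(nbhd)
                    if _loop_free_density(nsub.number_of_nodes(),
                                          nsub.number_of_edges()) > fluff_density:
                        extra.add(u)
            final_nodes = set(sub.nodes) | extra
        else:
            final_nodes = set(sub.nodes)
        used |= members | final_nodes
        if len(final_nodes) < min_size:
            continue
        msub = g.subgraph(final_nodes)
        dens = _loop_free_density(msub.number_of_nodes(), msub.number_of_edges())
        modules.append(NetworkModule(
            members=tuple(sorted(final_nodes, key=str)),
            n_edges=msub.number_of_edges(),
            density=dens,
            mcode_score=dens * msub.number_of_nodes(),
            seed=seed,
        ))
    modules.sort(key=lambda mod: (-mod.mcode_score, mod.members))
    return modules


def match_modules(modules_a: list[NetworkModule],
                  modules_b: list[NetworkModule]) -> pd.DataFrame:
    """Jaccard overlap matrix between two module lists (e.g. two stages).

    Module identity across networks is not asserted; the matrix lets the
    analyst judge correspondence.
    """
    out = np.zeros((len(modules_a), len(modules_b)))
    for i, ma in enumerate(modules_a):
        sa = set(ma.members)
        for j, mb in enumerate(modules_b):
            sb = set(mb.members)
            out[i, j] = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
    return pd.DataFrame(out,
                        index=[f"module_{i + 1}" for i in range(len(modules_a))],
                        columns=[f"module_{j + 1}" for j in range(len(modules_b))])


# ---------------------------------------------------------------------------
# PCIT
# ---------------------------------------------------------------------------

def pcit_filter(corr: CorrelationMatrix) -> pd.DataFrame:
    """Partial-correlation-and-information-theory edge mask.

    For every triad (i, j, k) the three first-order partial correlations are
    computed and the triad tolerance is the mean ratio of partial to direct
    correlation; edge (i, j) is removed iff some third node k dominates it,
    i.e. |r_ij| < |eps r_ik| and |r_ij| < |eps r_jk|.  Triads containing a
    |r| = 1 pair are skipped.  Returns a symmetric boolean keep-mask with a
    True diagonal; a 2-OTU matrix is returned unmasked (no triads).
    """
    ids = corr.otu_ids
    m = len(ids)
    if m < 2:
        raise ValueError("need at least 2 OTUs")
    r = corr.rho.to_numpy().astype(float)
    removed = np.zeros((m, m), dtype=bool)
    if m >= 3:
        with np.errstate(divide="ignore", invalid="ignore"):
            one_minus_sq = 1.0 - r ** 2
            n_singular = 0
            for k in range(m):
                rk = r[:, k]
                d_ik = one_minus_sq[:, k]           # 1 - r_ik^2
                # partials within triad (i, j, k)
                pc_ij_k = (r - np.outer(rk, rk)) / np.sqrt(np.outer(d_ik, d_ik))
                pc_ik_j = (rk[:, None] - r * rk[None, :]) / np.sqrt(
                    one_minus_sq * d_ik[None, :])
                pc_jk_i = (rk[None, :] - r * rk[:, None]) / np.sqrt(
                    one_minus_sq * d_ik[:, None])
                eps = (pc_ij_k / r + pc_ik_j / rk[:, None]
                       + pc_jk_i / rk[None, :]) / 3.0
                cond = (np.abs(r) < np.abs(eps * rk[:, None])) & (
                        np.abs(r) < np.abs(eps * rk[None, :]))
                valid = np.isfinite(eps)
                n_singular += int(np.sum(~valid & ~np.eye(m, dtype=bool))) // 2
                cond &= valid
                cond[:, k] = False
                cond[k, :] = False
                np.fill_diagonal(cond, False)
                removed |= cond
        if n_singular:
            logger.info("skipped %d singular triad entries in PCIT", n_singular)
    keep = ~removed
    keep &= keep.T
    np.fill_diagonal(keep, True)
    return pd.DataFrame(keep, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_edgelist(net: CooccurrenceNetwork, path) -> None:
    rows = [(u, v, d["weight"], d["sign"])
            for u, v, d in net.graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
    df.sort_values(["source", "target"], inplace=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(net: CooccurrenceNetwork, path,
                  omit_isolated: bool = True) -> None:
    g = net.graph
    if omit_isolated:
        g = g.subgraph([v for v in g if g.degree(v) > 0])
    nx.write_graphml(g, str(path))


def write_modules(modules: list[NetworkModule], path) -> None:
    rows = [{"module": i + 1, "mcode_score": m.mcode_score, "n_nodes": len(m.members),
             "n_edges": m.n_edges, "density": m.density, "seed": m.seed,
             "members": ",".join(map(str, m.members))}
            for i, m in enumerate(modules)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
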