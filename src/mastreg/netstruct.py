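"""Community structure of the master-TF network and gene-set enrichment.

The master-regulator network (TF-target edges from retained regulons)
is partitioned by greedy modularity maximization (Clauset-Newman-Moore
agglomeration: start from singletons, repeatedly merge the community
pair with the largest modularity gain, keep the partition with maximal
Q).  Each community's gene list is then characterized by
over-representation analysis (ORA): a one-sided hypergeometric test of
the overlap with every user-supplied gene set, BH-corrected within the
community.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import Regulon

logger = logging.getLogger(__name__)


def build_graph(
    regulons: list[Regulon],
    meta: pd.DataFrame | None = None,
    weighted: bool = False,
) -> nx.Graph:
    """Undirected TF-target graph from regulons.

    With ``weighted=True`` edge weights are |z_combined| looked up in
    ``meta`` (falling back to the regulon likelihood when absent).
    Self-loops are excluded by the regulon invariant; duplicate edges
    collapse.
    """
    g = nx.Graph()
    zlut = {}
    if meta is not None:
        zlut = {
            (row.tf, row.target): abs(float(row.z_combined))
            for row in meta.itertuples()
        }
    for reg in regulons:
        g.add_node(reg.tf)
        for target, row in reg.targets.iterrows():
            w = zlut.get((reg.tf, target), float(row["likelihood"])) if weighted else 1.0
            g.add_edge(reg.tf, target, weight=w)
    return g


def modularity(g: nx.Graph, communities, weighted: bool = False) -> float:
    """Newman modularity Q of a partition (0 by convention on edgeless graphs)."""
    if g.number_of_edges() == 0:
        return 0.0
    return float(
        nx.community.modularity(g, communities, weight="weight" if weighted else None)
    )


def greedy_communities(g: nx.Graph, weighted: bool = False) -> tuple[pd.Series, float]:
    """Greedy modularity (CNM) partition of a graph.

    Returns a node -> community-index Series (communities numbered by
    decreasing size, nodes sorted within) and the modularity Q of the
    returned partition.  An edgeless graph yields singletons with
    Q = 0 (logged).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        logger.warning("edgeless graph: every node is its own community, Q = 0")
        part = pd.Series(
            {node: i for i, node in enumerate(sorted(g.nodes()))}, name="community"
        )
        part.index.name = "node"
        return part, 0.0
    comms = nx.community.greedy_modularity_communities(
        g, weight="weight" if weighted else None
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
    assignment = {}
    for i, members in enumerate(comms):
        for node in members:
            assignment[node] = i
    part = pd.Series(assignment, name="community")
    part.index.name = "node"
    q = modularity(g, [set(c) for c in comms], weighted=weighted)
    return part, q


def ora_enrich(
    community_genes,
    collection: dict[str, set[str]],
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    With a universe of N genes, a community of n and a set of K genes
    (both intersected with the universe), the p-value is
    ``P[X >= k], X ~ Hypergeom(N, K, n)`` for an observed overlap k.
    q-values are BH across the sets tested for this community; rows are
    sorted by p.
    """
    universe = set(universe)
    community = set(community_genes)
    if not universe:
        raise ValueError("empty universe")
    if not community:
        raise ValueError("empty community")
    stray = community - universe
    if stray:
        raise ValueError(f"community genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(universe)
    n_comm = len(community)
    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        if not members:
            continue
        k = len(community & members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members), n_comm))
        rows.append((name, k, len(members), min(1.0, p)))
    if not rows:
        return pd.DataFrame(columns=["set", "overlap", "set_size", "p", "q"])
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def enrich_communities(
    partition: pd.Series,
    collection: dict[str, set[str]],
    universe=None,
) -> pd.DataFrame:
    """ORA for every community in a partition; universe defaults to all nodes."""
    universe = set(partition.index) if universe is None else set(universe)
    frames = []
    for comm in sorted(partition.unique()):
        genes = set(partition.index[partition == comm]) & universe
        if not genes:
            continue
        tab = ora_enrich(genes, collection, universe)
        tab.insert(0, "community", comm)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["community", "set", "overlap", "set_size", "p", "q"])
    return pd.concat(frames, ignore_index=True)
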