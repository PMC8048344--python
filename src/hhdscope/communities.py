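"""Similarity-network community detection.

All-against-all local-alignment E-values are turned into a weighted
adjacency graph — pairs above the significance cutoff are dropped, the
remaining E-values enter as -log10(E) so stronger similarity means a
heavier edge — and communities are found by Louvain modularity
optimisation. Tiny graphs (at most eight nodes) are solved exactly by
enumerating all partitions, so the returned assignment is the global
modularity optimum there.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("hhdscope.communities")

EXACT_MAX_NODES = 8


class InputError(ValueError):
    pass


@dataclass
class CommunityAssignment:
    """Node -> community labels with the achieved modularity."""

    assignment: dict[str, int]
    modularity: float
    n_iterations: int
    seed: int

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, []).append(node)
        return {k: sorted(v) for k, v in out.items()}


def build_adjacency(
    evalue_table: pd.DataFrame,
    e_cutoff: float = 1e-4,
    floor: float = 1e-180,
    ids: list[str] | None = None,
) -> nx.Graph:
    """Weighted graph of significant pairwise similarities.

    Pairs with E > ``e_cutoff`` contribute no edge; edge weight is
    -log10(max(E, floor)). Nodes with no significant pair are retained
    as isolated nodes.
    """
    for col in ("id_a", "id_b", "evalue"):
        if col not in evalue_table.columns:
            raise InputError(f"e-value table lacks column {col!r}")
    if (evalue_table["evalue"] <= 0).any():
        raise InputError("non-positive E-values in input")
    g = nx.Graph()
    nodes = ids if ids is not None else sorted(
        set(evalue_table["id_a"]) | set(evalue_table["id_b"])
    )
    g.add_nodes_from(nodes)
    sig = evalue_table[evalue_table["evalue"] <= e_cutoff]
    for a, b, e in zip(sig["id_a"], sig["id_b"], sig["evalue"]):
        if a == b:
            continue
        w = -np.log10(max(float(e), floor))
        g.add_edge(a, b, weight=w)
    return g


def _exact_louvain(graph: nx.Graph, resolution: float) -> tuple[list[set], float]:
    """Exhaustive maximum-modularity partition for tiny graphs."""
    nodes = sorted(graph.nodes)
    best: tuple[float, list[set]] | None = None

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1:]
            yield [[head]] + part

    for part in partitions(nodes):
        blocks = [set(p) for p in part]
        q = nx.community.modularity(graph, blocks, weight="weight",
                                    resolution=resolution)
        if best is None or q > best[0] + 1e-12:
            best = (q, blocks)
    return best[1], best[0]


def louvain(
    graph: nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 8,
) -> CommunityAssignment:
    """Louvain community detection with seeded restarts.

    Runs the greedy modularity optimisation ``n_restarts`` times with
    seed-derived node-order shuffles and keeps the best partition; on
    graphs with at most eight nodes the partition space is enumerated
    instead, so the result is the exact modularity optimum. Isolated
    nodes become singleton communities. Labels are dense integers by
    decreasing community size.
    """
    if graph.number_of_nodes() == 0:
        raise InputError("empty graph")
    if graph.number_of_edges() == 0:
        comms = [{n} for n in sorted(graph.nodes)]
        q, iters = 0.0, 0
    elif graph.number_of_nodes() <= EXACT_MAX_NODES:
        comms, q = _exact_louvain(graph, resolution)
        iters = 1
    else:
        best_q, comms = -np.inf, None
        rng = np.random.default_rng([seed, 307])
        for r in range(n_restarts):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            candidate = nx.community.louvain_communities(
                graph, weight="weight", resolution=resolution, seed=sub_seed
            )
            q_cand = nx.community.modularity(
                graph, candidate, weight="weight", resolution=resolution
            )
            if q_cand > best_q:
                best_q, comms = q_cand, candidate
        q, iters = float(best_q), n_restarts
    ordered = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    assignment = {n: k for k, comm in enumerate(ordered) for n in comm}
    if graph.number_of_edges() > 0:
        q = float(nx.community.modularity(
            graph, [set(c) for c in ordered], weight="weight", resolution=resolution
        ))
    return CommunityAssignment(assignment, q, iters, seed)


def heatmap_order(
    evalue_table: pd.DataFrame, assignment: CommunityAssignment
) -> tuple[list[str], np.ndarray, list[int]]:
    """Order ids by community for block-structured heatmap export.

    Ids are grouped by community (communities by decreasing size); the
    returned matrix holds -log10(E) for significant and non-significant
    pairs alike (0 on missing pairs), and the boundary list gives the
    cumulative block edges — the frame of the community squares.
    """
    ids = sorted(assignment.assignment)
    missing = [i for i in set(evalue_table["id_a"]) | set(evalue_table["id_b"])
               if i not in assignment.assignment]
    if missing:
        raise InputError(f"assignment lacks ids: {missing[:5]}")
    comms = assignment.communities()
    order: list[str] = []
    boundaries: list[int] = []
    for label in sorted(comms, key=lambda k: (-len(comms[k]), comms[k][0])):
        order.extend(comms[label])
        boundaries.append(len(order))
    index = {sid: k for k, sid in enumerate(order)}
    mat = np.zeros((len(order), len(order)))
    for a, b, e in zip(evalue_table["id_a"], evalue_table["id_b"],
                       evalue_table["evalue"]):
        if a in index and b in index:
            w = -np.log10(max(float(e), 1e-180))
            mat[index[a], index[b]] = mat[index[b], index[a]] = max(w, 0.0)
    return order, mat, boundaries
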