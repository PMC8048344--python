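"""Identity-threshold graph clustering and redundancy reduction.

Three operations used to organise domain hits into families:

* single-linkage clustering at a fixed identity threshold (edges require
  both an identity and a reciprocal-coverage minimum, connected
  components are the clusters);
* the incremental split procedure: the inclusion threshold is raised in
  small steps and a trace records every point where a tracked cluster
  splits into parts that are each a meaningful fraction of their parent
  — the way subfamilies are discovered at their emergence threshold;
* greedy representative selection (longest-first, join the first
  representative above the identity threshold), the classical redundancy
  reduction used before phylogeny and logo construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .core_io import Sequence
from .pairwise_align import SubstitutionMatrix, global_align, percent_identity

logger = logging.getLogger("hhdscope.clustering")


class InputError(ValueError):
    pass


@dataclass
class Partition:
    """A clustering of sequence ids at one identity threshold."""

    threshold: float
    assignment: dict[str, int]   # id -> dense cluster label, by size desc
    outliers: list[str]          # ids isolated at this threshold

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, label in self.assignment.items():
            out.setdefault(label, []).append(sid)
        return {k: sorted(v) for k, v in out.items()}


@dataclass
class TraceNode:
    """One cluster in the incremental-threshold trace."""

    node_id: int
    threshold: float       # threshold at emergence
    members: frozenset[str]
    parent: int | None
    children: list[int] = field(default_factory=list)
    label: str | None = None


@dataclass
class ClusterTrace:
    """Hierarchy of cluster splits as the inclusion threshold rises."""

    nodes: dict[int, TraceNode]
    root_ids: list[int]

    def splits(self) -> list[tuple[int, float, list[int]]]:
        """(parent_id, split threshold, child ids) for every recorded split."""
        out = []
        for node in self.nodes.values():
            if node.children:
                t = self.nodes[node.children[0]].threshold
                out.append((node.node_id, t, list(node.children)))
        return sorted(out, key=lambda x: x[1])

    def depth(self) -> int:
        def walk(nid: int) -> int:
            node = self.nodes[nid]
            return 1 + max((walk(c) for c in node.children), default=0)
        return max(walk(r) for r in self.root_ids)

    def annotate(self, labels: dict[str, str]) -> None:
        """Name nodes by the majority annotation of their members."""
        for node in self.nodes.values():
            tags = [labels[m] for m in node.members if m in labels]
            if tags:
                node.label = max(sorted(set(tags)), key=tags.count)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "roots": self.root_ids,
            "nodes": [
                {
                    "id": n.node_id,
                    "threshold": round(n.threshold, 6),
                    "size": len(n.members),
                    "members": sorted(n.members),
                    "parent": n.parent,
                    "children": n.children,
                    "label": n.label,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _edge_view(
    pair_table: pd.DataFrame,
    ids: list[str],
    identity_threshold: float,
    coverage_threshold: float,
) -> nx.Graph:
    known = set(ids)
    for col in ("id_a", "id_b", "identity"):
        if col not in pair_table.columns:
            raise InputError(f"pair table lacks column {col!r}")
    unknown = (set(pair_table["id_a"]) | set(pair_table["id_b"])) - known
    if unknown:
        raise InputError(f"pair table references unknown ids: {sorted(unknown)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(ids)
    sel = pair_table["identity"] >= identity_threshold
    if "coverage_a" in pair_table.columns:
        cov = pair_table[["coverage_a", "coverage_b"]].min(axis=1)
        sel &= cov >= coverage_threshold
    elif "coverage" in pair_table.columns:
        sel &= pair_table["coverage"] >= coverage_threshold
    sub = pair_table[sel]
    g.add_edges_from(zip(sub["id_a"], sub["id_b"]))
    return g


def identity_graph_partition(
    ids: list[str],
    pair_table: pd.DataFrame,
    identity_threshold: float,
    coverage_threshold: float = 0.8,
) -> Partition:
    """Single-linkage clusters at a fixed inclusion threshold.

    An edge joins two sequences when identity >= ``identity_threshold``
    and reciprocal coverage >= ``coverage_threshold``; clusters are the
    connected components, labelled densely by decreasing size (ties by
    smallest member id); components of size one are the outliers.
    """
    g = _edge_view(pair_table, ids, identity_threshold, coverage_threshold)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    assignment = {sid: k for k, comp in enumerate(comps) for sid in comp}
    outliers = [c[0] for c in comps if len(c) == 1]
    return Partition(identity_threshold, assignment, sorted(outliers))


def incremental_partition(
    ids: list[str],
    pair_table: pd.DataFrame,
    threshold_step: float = 0.01,
    min_cluster_frac: float = 0.05,
    split_frac: float = 0.10,
    coverage_threshold: float = 0.8,
) -> ClusterTrace:
    """Raise the inclusion threshold stepwise and record cluster splits.

    Starting from one root holding all ids, the threshold is increased
    by ``threshold_step``. Whenever a tracked cluster's members now fall
    into several components, the qualifying components (for the root:
    at least ``min_cluster_frac`` of the full set; deeper: at least
    ``split_frac`` of the parent) become child nodes at the current
    threshold, provided at least two qualify. Members falling into
    non-qualifying fragments are shed from the tracked set without
    creating nodes, so each cluster is isolated at its emergence
    threshold.
    """
    if not 0 < threshold_step <= 0.1:
        raise InputError("threshold_step must be in (0, 0.1]")
    n_total = len(ids)
    nodes: dict[int, TraceNode] = {}
    next_id = 0

    def new_node(threshold, members, parent) -> TraceNode:
        nonlocal next_id
        node = TraceNode(next_id, threshold, frozenset(members), parent)
        nodes[next_id] = node
        next_id += 1
        return node

    root = new_node(0.0, ids, None)
    # active: node id -> currently tracked member set (may shrink)
    active: dict[int, set[str]] = {root.node_id: set(ids)}
    t = 0.0
    while t < 1.0 + 1e-9 and active:
        comps_all = {
            frozenset(c)
            for c in nx.connected_components(
                _edge_view(pair_table, ids, t, coverage_threshold)
            )
        }
        for nid, members in list(active.items()):
            parts = sorted(
                (sorted(c & members) for c in comps_all if c & members),
                key=lambda c: (-len(c), c[0]),
            )
            is_root = nodes[nid].parent is None
            min_size = (min_cluster_frac * n_total) if is_root else (
                split_frac * len(nodes[nid].members)
            )
            # dissolving into singletons produces outliers, not clusters
            min_size = max(min_size, 2)
            qualifying = [p for p in parts if len(p) >= min_size]
            if len(qualifying) >= 2:
                del active[nid]
                for part in qualifying:
                    child = new_node(round(t, 10), part, nid)
                    nodes[nid].children.append(child.node_id)
                    active[child.node_id] = set(part)
            elif len(qualifying) == 1:
                active[nid] = set(qualifying[0])  # shed outliers silently
            else:
                del active[nid]  # cluster dissolved below minimum size
        t = round(t + threshold_step, 10)
    return ClusterTrace(nodes, [root.node_id])


def reduce_redundancy(
    seqs: list[Sequence],
    identity_threshold: float,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[list[Sequence], dict[str, list[str]]]:
    """Greedy longest-first representative selection.

    Sequences are visited by decreasing length (ties by id); each joins
    the first existing representative with identity >= threshold
    (identity over the shorter sequence, global alignment), otherwise it
    becomes a representative itself. Returns the representatives and a
    representative-id -> member-ids map.
    """
    if not 0.4 < identity_threshold <= 1.0:
        raise InputError("identity_threshold must be in (0.4, 1.0]")
    matrix = matrix or SubstitutionMatrix()
    order = sorted(seqs, key=lambda s: (-len(s.ungapped), s.id))
    reps: list[Sequence] = []
    membership: dict[str, list[str]] = {}
    for seq in order:
        placed = False
        for rep in reps:
            res = global_align(seq.ungapped, rep.ungapped, matrix)
            if percent_identity(res, "shorter_seq") >= identity_threshold:
                membership[rep.id].append(seq.id)
                placed = True
                break
        if not placed:
            reps.append(seq)
            membership[seq.id] = [seq.id]
    return reps, membership
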