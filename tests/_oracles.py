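"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming or
graph-library code paths: alignment scores come from exhaustive
enumeration of gapped alignments, modularity optima from explicit
partition enumeration, and transfer distances from pairwise bipartition
comparison on frozensets.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_global(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Best global affine-gap score by exhaustive alignment enumeration.

    A gap of length L costs gap_open + L*gap_extend (both negative);
    the first residue of a gap run pays gap_open + gap_extend.
    """
    best = -(10**9)

    def rec(i: int, j: int, prev: str, acc: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + score(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open + gap_extend
            rec(i + 1, j, "U", acc + cost)
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open + gap_extend
            rec(i, j + 1, "L", acc + cost)

    rec(0, 0, "S", 0)
    return best


def brute_force_local(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Best local affine-gap score by enumeration from every anchor pair.

    Tracks the running best at every aligned column, so alignments may
    end anywhere; the empty alignment scores 0.
    """
    best = 0

    def rec(i: int, j: int, prev: str, acc: int) -> None:
        nonlocal best
        if i < len(a) and j < len(b):
            ns = acc + score(a[i], b[j])
            best = max(best, ns)
            rec(i + 1, j + 1, "M", ns)
        if prev != "S":
            if i < len(a):
                cost = gap_extend if prev == "U" else gap_open + gap_extend
                rec(i + 1, j, "U", acc + cost)
            if j < len(b):
                cost = gap_extend if prev == "L" else gap_open + gap_extend
                rec(i, j + 1, "L", acc + cost)

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, "S", 0)
    return best


def set_partitions(items: list):
    """All partitions of a list into non-empty blocks."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[head] + part[k]] + part[k + 1:]
        yield [[head]] + part


def modularity_from_scratch(nodes, edges, partition, resolution=1.0) -> float:
    """Weighted modularity computed directly from its definition."""
    label = {}
    for k, block in enumerate(partition):
        for n in block:
            label[n] = k
    two_m = sum(2 * w for _, _, w in edges)
    if two_m == 0:
        return 0.0
    degree = {n: 0.0 for n in nodes}
    for u, v, w in edges:
        degree[u] += w
        degree[v] += w
    q = 0.0
    for u, v, w in edges:
        if label[u] == label[v]:
            q += 2 * w / two_m
    for block in partition:
        d = sum(degree[n] for n in block)
        q -= resolution * (d / two_m) ** 2
    return q


def best_modularity(nodes, edges, resolution=1.0) -> float:
    """Global modularity optimum by exhaustive partition enumeration."""
    best = -np.inf
    for part in set_partitions(list(nodes)):
        q = modularity_from_scratch(nodes, edges, part, resolution)
        best = max(best, q)
    return best


def random_additive_matrix(n_leaves: int, seed: int):
    """A random tree and the exactly additive distances it induces.

    Returns (dendropy tree, taxon ids, distance ndarray).
    """
    import random as _random

    import dendropy

    rng = _random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        taxon_namespace=taxa, rng=rng,
    )
    rng2 = np.random.default_rng(seed)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng2.uniform(0.1, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    ids = [t.label for t in taxa]
    m = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                m[i, j] = m[j, i] = pdm.distance(a, b)
    return tree, ids, m


def tree_bipartitions(tree) -> set[frozenset]:
    """Non-trivial bipartitions of a dendropy tree as lighter-side sets."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        comp = frozenset(set(leaves) - clade)
        if 1 < len(clade) < len(leaves) - 1:
            out.add(min(clade, comp, key=lambda s: (len(s), sorted(s))))
    return out


def all_branch_sides(tree) -> list[frozenset]:
    """One leaf-set per branch of a dendropy tree (trivial ones included)."""
    return [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]


def transfer_distance_oracle(bipartition: frozenset, replicate_tree, leaves: set) -> int:
    """Minimum Hamming distance of a bipartition to any replicate branch,
    via explicit set arithmetic over every bipartition pair."""
    best = len(leaves)
    for side in all_branch_sides(replicate_tree):
        d1 = len(bipartition.symmetric_difference(side))
        d2 = len(leaves) - d1
        best = min(best, d1, d2)
    return best
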