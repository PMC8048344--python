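"""Distance-based phylogeny with bootstrap and transfer supports.

Neighbor-joining trees from p-distances (optionally Poisson-corrected)
with nonparametric column-resampling bootstrap. Branch support comes in
two flavours: the classical Felsenstein bootstrap proportion (FBP, the
fraction of replicate trees containing the bipartition exactly) and the
Transfer Bootstrap Expectation (TBE), 1 minus the mean normalised
transfer distance of the bipartition to its closest match in each
replicate. TBE is computed exactly — the minimum over all replicate
branches of the Hamming distance between bipartition indicator vectors,
up to complementation — and therefore never falls below FBP. Trees from
external inference tools can be imported as Newick and passed to the
support calculation unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .core_io import GAP, Msa

logger = logging.getLogger("hhdscope.phylogeny")

D_MAX = 5.0  # saturation cap for Poisson-corrected distances


class RootingError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over a fixed taxon order."""

    ids: list[str]
    values: np.ndarray
    correction: str = "p_distance"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.diag(v).any():
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)], self.correction)


def distance_matrix(msa: Msa, correction: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap columns.

    p-distance is mismatches over compared (both-ungapped) columns;
    ``poisson`` applies d = -ln(1 - p), capped at 5 (with a warning)
    when p approaches saturation. A pair with zero comparable columns
    is an error naming the pair.
    """
    if len(msa.members) < 3:
        raise ValueError("need at least 3 sequences")
    if correction not in ("p_distance", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    chars = np.array([list(m.residues) for m in msa.members])
    gaps = chars == GAP
    n = len(msa.members)
    out = np.zeros((n, n))
    capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {msa.members[i].id} "
                    f"and {msa.members[j].id}"
                )
            p = float((chars[i][ok] != chars[j][ok]).sum()) / total
            if correction == "poisson":
                if p >= 1.0 - np.exp(-D_MAX):
                    d = D_MAX
                    capped += 1
                else:
                    d = -np.log(1.0 - p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    if capped:
        logger.warning("capped %d saturated distances at %.1f", capped, D_MAX)
    return DistanceMatrix([m.id for m in msa.members], out, correction)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor-joining (Q-criterion, Studier-Keppler updates).

    Ties in the Q matrix break on the lexicographically smallest taxon
    pair, where an internal node inherits the smallest leaf name in its
    cluster; negative branch lengths are clamped to zero with a warning.
    The returned tree is unrooted (trifurcating seed node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for name in dm.ids:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(name)
        nodes[name] = node
    # active cluster keys: smallest leaf label in the cluster
    active = list(dm.ids)
    dist = {(a, b): float(dm.values[i, j])
            for i, a in enumerate(dm.ids) for j, b in enumerate(dm.ids) if i < j}

    def d(a: str, b: str) -> float:
        if a == b:
            return 0.0
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    clamped = 0
    while len(active) > 3:
        r = {a: sum(d(a, b) for b in active) for a in active}
        m = len(active)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        va = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        vb = d(a, b) - va
        if va < 0 or vb < 0:
            clamped += 1
        va, vb = max(va, 0.0), max(vb, 0.0)
        parent = dendropy.Node()
        for child, length in ((nodes[a], va), (nodes[b], vb)):
            parent.add_child(child)
            child.edge.length = length
        key = min(a, b)
        nodes[key] = parent
        new_dists = {}
        for c in active:
            if c in (a, b):
                continue
            new_dists[c] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [key]
        active.sort()
        dist = {
            (x, y): (new_dists[y] if key == x else new_dists[x] if key == y else d(x, y))
            for i2, x in enumerate(active) for y in active[i2 + 1:]
        }
    # final three clusters join at the seed node (three-point formulas)
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = dendropy.Node()
    for name, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            clamped += 1
        root.add_child(nodes[name])
        nodes[name].edge.length = max(length, 0.0)
    if clamped:
        logger.warning("clamped %d negative branch lengths to 0", clamped)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def nj_tree(msa: Msa, correction: str = "p_distance") -> dendropy.Tree:
    return neighbor_joining(distance_matrix(msa, correction))


def bootstrap_trees(
    msa: Msa,
    n_replicates: int = 1000,
    seed: int = 0,
    correction: str = "p_distance",
) -> list[dendropy.Tree]:
    """Column-resampling bootstrap replicates, one NJ tree each."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng([seed, 401])
    chars = np.array([list(m.residues) for m in msa.members])
    ids = [m.id for m in msa.members]
    trees = []
    from .core_io import Sequence
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        resampled = Msa([
            Sequence(ids[i], "".join(chars[i, cols])) for i in range(len(ids))
        ])
        trees.append(nj_tree(resampled, correction))
    return trees


# ---------------------------------------------------------------------------
# branch supports


def _bipartitions(tree: dendropy.Tree, leaf_order: list[str]) -> list[tuple[np.ndarray, object]]:
    """Indicator vector per internal edge, in a fixed leaf order."""
    index = {name: i for i, name in enumerate(leaf_order)}
    n = len(leaf_order)
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        vec = np.zeros(n, dtype=bool)
        for leaf in node.leaf_iter():
            vec[index[leaf.taxon.label]] = True
        size = int(vec.sum())
        if size in (0, n):  # root edge artefacts
            continue
        out.append((vec, node))
    return out


def _all_edge_vectors(tree: dendropy.Tree, leaf_order: list[str]) -> np.ndarray:
    """Indicator vectors of every edge (trivial leaf edges included)."""
    index = {name: i for i, name in enumerate(leaf_order)}
    n = len(leaf_order)
    vecs = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        vec = np.zeros(n, dtype=bool)
        for leaf in node.leaf_iter():
            vec[index[leaf.taxon.label]] = True
        vecs.append(vec)
    return np.array(vecs)


def transfer_distance(b: np.ndarray, edge_vectors: np.ndarray) -> int:
    """Exact minimum Hamming distance of ``b`` to any edge bipartition.

    The minimum runs over every branch of the replicate tree and over
    complementation of the indicator vector.
    """
    ham = (edge_vectors != b[None, :]).sum(axis=1)
    return int(np.minimum(ham, len(b) - ham).min())


@dataclass
class BranchSupport:
    bipartition: frozenset[str]   # lighter side
    fbp: float
    tbe: float
    light_side_size: int


@dataclass
class SupportedTree:
    """A reference topology with per-internal-branch FBP and TBE."""

    tree: dendropy.Tree
    supports: list[BranchSupport]

    def support_of(self, taxa: set[str]) -> BranchSupport | None:
        """Support of the branch whose lighter side is ``taxa`` (or its
        complement)."""
        leaves = {l.taxon.label for l in self.tree.leaf_node_iter()}
        want = frozenset(taxa) if len(taxa) <= len(leaves) / 2 else frozenset(leaves - taxa)
        for s in self.supports:
            if s.bipartition == want or s.bipartition == frozenset(leaves - set(want)):
                return s
        return None


def tbe_support(
    reference: dendropy.Tree, replicates: list[dendropy.Tree]
) -> SupportedTree:
    """FBP and TBE supports of every internal reference branch.

    For branch b with lighter-side size p, TBE(b) = 1 - mean over
    replicates of delta(b, T)/(p-1) where delta is the exact minimum
    transfer distance; FBP(b) is the fraction of replicates containing
    the bipartition exactly. Supports are attached to the reference
    tree's edges (``edge.support`` carries the TBE, ``edge.fbp`` the
    classical proportion).
    """
    leaf_order = sorted(l.taxon.label for l in reference.leaf_node_iter())
    for t in replicates:
        rep_leaves = sorted(l.taxon.label for l in t.leaf_node_iter())
        if rep_leaves != leaf_order:
            raise ValueError("replicate leaf set differs from reference")
    ref_bips = _bipartitions(reference, leaf_order)
    rep_edges = [_all_edge_vectors(t, leaf_order) for t in replicates]
    rep_bipsets = []
    for t in replicates:
        bips = set()
        for vec, _ in _bipartitions(t, leaf_order):
            key = frozenset(np.where(vec)[0].tolist())
            comp = frozenset(np.where(~vec)[0].tolist())
            bips.add(min(key, comp, key=lambda s: (len(s), sorted(s))))
        rep_bipsets.append(bips)
    n = len(leaf_order)
    supports = []
    for vec, node in ref_bips:
        p = int(min(vec.sum(), n - vec.sum()))
        key = frozenset(np.where(vec)[0].tolist())
        comp = frozenset(np.where(~vec)[0].tolist())
        canon = min(key, comp, key=lambda s: (len(s), sorted(s)))
        fbp = float(np.mean([canon in bips for bips in rep_bipsets]))
        if p == 1:
            tbe = 1.0  # trivial branch, always transferable at zero cost
        else:
            deltas = [transfer_distance(vec, edges) for edges in rep_edges]
            tbe = float(1.0 - np.mean(deltas) / (p - 1))
        light = frozenset(
            leaf_order[i] for i in (key if len(key) <= n / 2 else comp)
        )
        node.edge.support = round(tbe, 6)
        node.edge.fbp = round(fbp, 6)
        supports.append(BranchSupport(light, fbp, tbe, p))
    return SupportedTree(reference, supports)


def root_between(tree: dendropy.Tree, outgroup: set[str]) -> dendropy.Tree:
    """Root the tree on the branch separating ``outgroup`` from the rest.

    The outgroup must form a clade in the unrooted topology; the root is
    placed at the midpoint of the separating branch and edge supports
    are preserved. On failure the error names the minimal set of taxa
    breaking monophyly.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if not outgroup or not outgroup <= leaves:
        raise RootingError("outgroup must be a non-empty subset of the leaf set")
    tree = tree.clone(depth=1)
    best_node, best_diff = None, None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        clade = {l.taxon.label for l in node.leaf_iter()}
        for side in (clade, leaves - clade):
            diff = side.symmetric_difference(outgroup)
            if best_diff is None or len(diff) < len(best_diff):
                best_node, best_diff = node, diff
    if best_diff:
        raise RootingError(
            f"outgroup is not a clade; conflicting taxa: {sorted(best_diff)}"
        )
    edge = best_node.edge
    length = edge.length or 0.0
    support = getattr(edge, "support", None)
    fbp = getattr(edge, "fbp", None)
    tree.reroot_at_edge(edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False)
    for child in tree.seed_node.child_nodes():
        if support is not None:
            child.edge.support = support
        if fbp is not None:
            child.edge.fbp = fbp
    tree.is_rooted = True
    return tree
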