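"""Distances, neighbor-joining, bootstrap, transfer supports, rooting."""

import math
import random

import dendropy
import numpy as np
import pytest

from _oracles import transfer_distance_oracle, tree_bipartitions
from hhdscope.core_io import Msa, Sequence, read_newick, write_newick
from hhdscope.phylogeny import (
    DistanceMatrix, RootingError, bootstrap_trees, distance_matrix,
    neighbor_joining, nj_tree, root_between, tbe_support,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_additive(n_leaves: int, seed: int):
    """A random tree and the exactly additive distance matrix it induces."""
    rng = random.Random(seed)
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
    return tree, DistanceMatrix(ids, m)


def test_identical_sequences_zero_distance():
    msa = Msa([Sequence(f"s{i}", "ACDEF") for i in range(3)])
    dm = distance_matrix(msa)
    assert np.all(dm.values == 0)


def test_poisson_closed_form():
    # 10% mismatches -> d = -ln(0.9)
    a = "A" * 90 + "C" * 10
    b = "A" * 90 + "D" * 10
    msa = Msa([Sequence("x", a), Sequence("y", b), Sequence("z", a)])
    dm = distance_matrix(msa, correction="poisson")
    i, j = dm.ids.index("x"), dm.ids.index("y")
    assert dm.values[i, j] == pytest.approx(-math.log(0.9), abs=1e-9)


def test_pairwise_deletion_and_empty_overlap_error():
    msa = Msa([Sequence("x", "AC--"), Sequence("y", "--DE"), Sequence("z", "ACDE")])
    with pytest.raises(ValueError, match="x.*y|y.*x"):
        distance_matrix(msa)


def test_saturated_distances_capped(caplog):
    a, b = "A" * 50, "C" * 50
    msa = Msa([Sequence("x", a), Sequence("y", b), Sequence("z", "D" * 50)])
    with caplog.at_level("WARNING"):
        dm = distance_matrix(msa, correction="poisson")
    assert dm.values.max() == pytest.approx(5.0)
    assert any("capped" in m for m in caplog.messages)


def test_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(ids, m))
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_four_taxon_additive_recovery():
    true, dm = random_additive(4, seed=2)
    est = neighbor_joining(dm)
    assert tree_bipartitions(est) == tree_bipartitions(true)
    # exact branch lengths on additive input
    pdm_est = est.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in est.taxon_namespace}
    for i, a in enumerate(dm.ids):
        for j, b in enumerate(dm.ids):
            if i < j:
                assert pdm_est.distance(taxa[a], taxa[b]) == pytest.approx(
                    dm.values[i, j], abs=1e-9)


def test_taxon_order_invariance():
    _, dm = random_additive(7, seed=5)
    perm = np.random.default_rng(1).permutation(len(dm.ids))
    shuffled = DistanceMatrix(
        [dm.ids[i] for i in perm], dm.values[np.ix_(perm, perm)]
    )
    assert tree_bipartitions(neighbor_joining(dm)) == tree_bipartitions(
        neighbor_joining(shuffled))


def two_clade_msa(n_per_clade=5, n_cols=60, seed=0):
    """Two deeply separated clades with a long internal branch."""
    rng = np.random.default_rng(seed)
    rootA = rng.choice(AA, n_cols)
    rootB = rng.choice(AA, n_cols)
    members = []
    for g, root in (("A", rootA), ("B", rootB)):
        for i in range(n_per_clade):
            seq = root.copy()
            flip = rng.random(n_cols) < 0.05
            seq[flip] = rng.choice(AA, int(flip.sum()))
            members.append(Sequence(f"{g}{i}", "".join(seq)))
    return Msa(members)


def test_bootstrap_replicates_deterministic():
    msa = two_clade_msa()
    t1 = [t.as_string(schema="newick") for t in bootstrap_trees(msa, 5, seed=3)]
    t2 = [t.as_string(schema="newick") for t in bootstrap_trees(msa, 5, seed=3)]
    assert t1 == t2
    single = bootstrap_trees(msa, 1, seed=1)
    assert len(single) == 1


def test_deep_split_strongly_supported():
    msa = two_clade_msa()
    ref = nj_tree(msa)
    reps = bootstrap_trees(msa, 200, seed=7)
    st = tbe_support(ref, reps)
    deep = st.support_of({f"A{i}" for i in range(5)})
    assert deep is not None
    assert deep.fbp >= 0.95
    assert deep.tbe >= 0.95


def test_identical_replicates_give_full_support():
    msa = two_clade_msa(seed=4)
    ref = nj_tree(msa)
    st = tbe_support(ref, [ref.clone(depth=1) for _ in range(7)])
    assert all(s.tbe == 1.0 and s.fbp == 1.0 for s in st.supports)


def test_tbe_at_least_fbp_and_cherry_equality():
    msa = two_clade_msa(n_per_clade=6, seed=9)
    ref = nj_tree(msa)
    reps = bootstrap_trees(msa, 60, seed=11)
    st = tbe_support(ref, reps)
    for s in st.supports:
        assert s.tbe >= s.fbp - 1e-12
        if s.light_side_size == 2:
            assert s.tbe == pytest.approx(s.fbp)


def test_tbe_matches_bipartition_oracle():
    rng = np.random.default_rng(21)
    for trial in range(5):
        members = [
            Sequence(f"L{i}", "".join(rng.choice(AA, 30))) for i in range(8)
        ]
        msa = Msa(members)
        ref = nj_tree(msa)
        reps = bootstrap_trees(msa, 25, seed=trial)
        st = tbe_support(ref, reps)
        leaves = {m.id for m in members}
        for s in st.supports:
            p = s.light_side_size
            if p < 2:
                continue
            deltas = [
                transfer_distance_oracle(s.bipartition, t, leaves) for t in reps
            ]
            expect = 1.0 - np.mean(deltas) / (p - 1)
            assert s.tbe == pytest.approx(expect, abs=1e-12)


def test_leaf_set_mismatch_rejected():
    msa = two_clade_msa()
    ref = nj_tree(msa)
    other = nj_tree(Msa(msa.members[:-1]))
    with pytest.raises(ValueError, match="leaf set"):
        tbe_support(ref, [other])


def test_rooting_on_central_branch(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:1):1,(c:1,d:1):1);\n")
    tree = read_newick(p)
    rooted = root_between(tree, {"a", "b"})
    sides = [frozenset(l.taxon.label for l in c.leaf_iter())
             for c in rooted.seed_node.child_nodes()]
    assert frozenset({"a", "b"}) in sides
    assert frozenset({"c", "d"}) in sides


def test_rooting_on_single_leaf():
    msa = two_clade_msa()
    tree = nj_tree(msa)
    rooted = root_between(tree, {"A0"})
    sides = [frozenset(l.taxon.label for l in c.leaf_iter())
             for c in rooted.seed_node.child_nodes()]
    assert frozenset({"A0"}) in sides


def test_non_clade_outgroup_names_conflict():
    msa = two_clade_msa()
    tree = nj_tree(msa)
    with pytest.raises(RootingError, match="A1|B0"):
        root_between(tree, {"A0", "B0"})


def test_supports_survive_newick_round_trip(tmp_path):
    msa = two_clade_msa(seed=6)
    ref = nj_tree(msa)
    st = tbe_support(ref, bootstrap_trees(msa, 20, seed=2))
    p = tmp_path / "supported.nwk"
    write_newick(st.tree, p)
    back = read_newick(p, numeric_labels_as_support=True)
    expect = sorted(round(s.tbe, 6) for s in st.supports)
    got = sorted(
        n.edge.support for n in back.preorder_internal_node_iter()
        if getattr(n.edge, "support", None) is not None
    )
    assert got == pytest.approx(expect)
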