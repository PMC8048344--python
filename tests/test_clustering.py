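"""Single-linkage identity clustering, split traces, redundancy reduction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hhdscope.clustering import (
    InputError, identity_graph_partition, incremental_partition,
    reduce_redundancy,
)
from hhdscope.core_io import Sequence


def pair_table(identities: dict[tuple[str, str], float]) -> pd.DataFrame:
    rows = [{"id_a": a, "id_b": b, "identity": v, "coverage_a": 1.0,
             "coverage_b": 1.0} for (a, b), v in identities.items()]
    return pd.DataFrame(rows)


def two_family_table(within=0.8, between=0.3):
    ids = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
    table = {}
    for a, b in itertools.combinations(ids, 2):
        table[(a, b)] = within if a[0] == b[0] else between
    return ids, pair_table(table)


def test_zero_threshold_single_cluster():
    ids, table = two_family_table()
    part = identity_graph_partition(ids, table, 0.0)
    assert len(set(part.assignment.values())) == 1
    assert part.outliers == []


def test_two_planted_families_recovered_exactly():
    from sklearn.metrics import adjusted_rand_score
    ids, table = two_family_table(within=0.8, between=0.3)
    part = identity_graph_partition(ids, table, 0.5)
    truth = [i[0] for i in ids]
    pred = [part.assignment[i] for i in ids]
    assert adjusted_rand_score(truth, pred) == 1.0


def test_full_threshold_all_outliers():
    ids, table = two_family_table(within=0.8, between=0.3)
    part = identity_graph_partition(ids, table, 1.0)
    assert sorted(part.outliers) == sorted(ids)


def test_coverage_gate_blocks_edges():
    ids = ["x", "y"]
    table = pd.DataFrame([{"id_a": "x", "id_b": "y", "identity": 0.9,
                           "coverage_a": 0.5, "coverage_b": 1.0}])
    part = identity_graph_partition(ids, table, 0.5, coverage_threshold=0.8)
    assert len(set(part.assignment.values())) == 2


def test_unknown_ids_rejected():
    table = pd.DataFrame([{"id_a": "x", "id_b": "zz", "identity": 0.9}])
    with pytest.raises(InputError, match="zz"):
        identity_graph_partition(["x"], table, 0.5)


def test_threshold_refinement_property():
    rng = np.random.default_rng(8)
    ids = [f"s{i}" for i in range(12)]
    table = pair_table({
        (a, b): float(rng.uniform(0, 1))
        for a, b in itertools.combinations(ids, 2)
    })
    prev = identity_graph_partition(ids, table, 0.2)
    for t in (0.4, 0.6, 0.8):
        cur = identity_graph_partition(ids, table, t)
        # refinement: members of one current cluster share a previous cluster
        for members in cur.clusters().values():
            assert len({prev.assignment[m] for m in members}) == 1
        prev = cur


def test_trace_single_family_has_no_splits():
    ids = [f"s{i}" for i in range(10)]
    table = pair_table({(a, b): 0.9 for a, b in itertools.combinations(ids, 2)})
    trace = incremental_partition(ids, table)
    assert trace.splits() == []
    assert trace.depth() == 1


def test_trace_records_split_at_emergence_threshold():
    # families diverge at 0.55: the cross edges die first past 0.55
    ids = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
    table = {}
    for a, b in itertools.combinations(ids, 2):
        table[(a, b)] = 0.8 if a[0] == b[0] else 0.55
    trace = incremental_partition(ids, pair_table(table), threshold_step=0.01)
    splits = trace.splits()
    assert len(splits) == 1
    _, threshold, children = splits[0]
    assert threshold == pytest.approx(0.56, abs=1e-9)
    child_sets = [set(trace.nodes[c].members) for c in children]
    assert sorted(len(s) for s in child_sets) == [6, 6]
    assert {frozenset(s) for s in child_sets} == {
        frozenset(i for i in ids if i[0] == "A"),
        frozenset(i for i in ids if i[0] == "B"),
    }


def test_trace_three_nested_levels():
    # 16 ids: top split at 0.31, then each half splits again at 0.61
    ids = [f"{g}{i}" for g in "ABCD" for i in range(4)]
    table = {}
    for a, b in itertools.combinations(ids, 2):
        if a[0] == b[0]:
            table[(a, b)] = 0.9
        elif {a[0], b[0]} <= {"A", "B"} or {a[0], b[0]} <= {"C", "D"}:
            table[(a, b)] = 0.6
        else:
            table[(a, b)] = 0.3
    trace = incremental_partition(ids, pair_table(table))
    assert trace.depth() == 3
    thresholds = sorted(t for _, t, _ in trace.splits())
    assert thresholds == pytest.approx([0.31, 0.61, 0.61])
    sizes = sorted(len(n.members) for n in trace.nodes.values())
    assert sizes == [4, 4, 4, 4, 8, 8, 16]


def test_trace_determinism():
    ids, table = two_family_table()
    t1 = incremental_partition(ids, table).to_json()
    t2 = incremental_partition(ids, table).to_json()
    assert t1 == t2


def test_trace_annotation_majority():
    ids, table = two_family_table()
    trace = incremental_partition(ids, table)
    trace.annotate({i: ("alpha" if i[0] == "A" else "beta") for i in ids})
    leaf_labels = {n.label for n in trace.nodes.values() if not n.children}
    assert leaf_labels == {"alpha", "beta"}


def test_invalid_step_rejected():
    ids, table = two_family_table()
    with pytest.raises(InputError):
        incremental_partition(ids, table, threshold_step=0.5)


def test_redundancy_identical_collapse():
    seqs = [Sequence(f"s{i}", "ACDEFGHIKLMNPQRSTVWY") for i in range(50)]
    reps, members = reduce_redundancy(seqs, 0.95)
    assert len(reps) == 1
    assert len(members[reps[0].id]) == 50


def test_redundancy_all_distinct_kept():
    rng = np.random.default_rng(4)
    seqs = [Sequence(f"s{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40)))
            for i in range(10)]
    reps, _ = reduce_redundancy(seqs, 0.95)
    assert len(reps) == 10


def test_redundancy_five_variant_groups():
    rng = np.random.default_rng(9)
    variants = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
                for _ in range(5)]
    seqs = [Sequence(f"v{k}_{i}", variants[k]) for k in range(5) for i in range(10)]
    reps, members = reduce_redundancy(seqs, 0.95)
    assert len(reps) == 5
    assert sorted(len(v) for v in members.values()) == [10] * 5


def test_redundancy_threshold_range_checked():
    with pytest.raises(InputError):
        reduce_redundancy([Sequence("a", "ACD")], 0.3)
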