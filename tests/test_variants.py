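"""Variant-to-column mapping, annotation rules, batch processing."""

import numpy as np
import pandas as pd
import pytest

from hhdscope.conservation import conservation_profile
from hhdscope.core_io import Msa, Sequence
from hhdscope.profile_hmm import DomainHit
from hhdscope.variants import (
    NOTE_BINDING, NOTE_STABILITY, NOTE_UNCLEAR, ProvenanceError,
    VariantRecord, annotate_variant, batch_annotate, map_variant,
)


@pytest.fixture()
def toy_domain():
    """A 10-residue domain embedded at protein positions 21-30."""
    domain = "ARNDCEQGHI"
    msa = Msa([Sequence("prot1/21-30", domain),
               Sequence("other", "ARNDCEQGHL")])
    hit = DomainHit("prot1", 21, 30, 50.0, 1e-20, 1, 10)
    return domain, msa, hit


def test_variant_maps_through_column_map(toy_domain):
    domain, msa, hit = toy_domain
    v = VariantRecord("prot1", ref="C", position=25, alt="Y")
    assert map_variant(v, hit, msa, "prot1/21-30") == 5


def test_master_numbering_applied(toy_domain):
    domain, msa, hit = toy_domain
    v = VariantRecord("prot1", ref="C", position=25, alt="Y")
    numbers = list(range(11, 21))
    assert map_variant(v, hit, msa, "prot1/21-30", numbers) == 15


def test_variant_outside_envelope_is_unmapped(toy_domain):
    _, msa, hit = toy_domain
    v = VariantRecord("prot1", ref="M", position=5, alt="T")
    assert map_variant(v, hit, msa, "prot1/21-30") is None


def test_ref_mismatch_is_provenance_error(toy_domain):
    _, msa, hit = toy_domain
    v = VariantRecord("prot1", ref="W", position=25, alt="Y")
    with pytest.raises(ProvenanceError, match="version"):
        map_variant(v, hit, msa, "prot1/21-30")


def test_gapped_member_mapping():
    msa = Msa([Sequence("p/1-4", "AR-ND"), Sequence("q", "ARWND")])
    hit = DomainHit("p", 1, 4, 10.0, 1e-9, 1, 4)
    v = VariantRecord("p", ref="N", position=3, alt="K")
    # third residue sits in alignment column 4 (column 3 is a gap)
    assert map_variant(v, hit, msa, "p/1-4") == 4


def test_round_trip_on_benchmark(benchmark, benchmark_hits):
    """column -> domain-local index -> protein position is the inverse
    of the mapping, for variants planted at every tenth domain position."""
    from hhdscope.pipeline import profile_align
    from hhdscope.profile_hmm import build_profile, calibrate
    by_id = {s.id: s for s in benchmark.database}
    checked = 0
    for hit in benchmark_hits[:40]:
        protein = by_id[hit.target_id]
        domain = protein.residues[hit.start - 1: hit.end]
        msa = Msa([Sequence(f"{hit.target_id}/{hit.start}-{hit.end}", domain)])
        member_id = msa.members[0].id
        for pos in range(hit.start, hit.end + 1, 10):
            ref = protein.residues[pos - 1]
            alt = "K" if ref != "K" else "R"
            v = VariantRecord(hit.target_id, ref, pos, alt)
            col = map_variant(v, hit, msa, member_id)
            assert col is not None
            back = hit.start + msa.column_maps[member_id].residue_of(col) - 1
            assert back == pos
            checked += 1
    assert checked > 100


def conserved_profile_with(columns: dict[int, str]):
    """A tiny alignment whose listed columns are purely one residue."""
    width = 78
    rows = []
    rng = np.random.default_rng(1)
    for i in range(12):
        row = [str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))) for _ in range(width)]
        for col, res in columns.items():
            row[col - 1] = res
        rows.append(Sequence(f"s{i}", "".join(row)))
    return conservation_profile(Msa(rows))


def test_conserved_pair_member_notes_stability():
    prof = conserved_profile_with({62: "R"})
    v = VariantRecord("p", "R", 100, "W")
    ann = annotate_variant(v, 62, prof)
    assert "stabilizing pair" in ann.roles
    assert ann.conservation_class == "cationic"
    assert ann.note == NOTE_STABILITY


def test_groove_lining_notes_binding():
    prof = conserved_profile_with({})  # column 28 not conserved
    v = VariantRecord("p", "D", 447, "H")
    ann = annotate_variant(v, 28, prof)
    assert "groove lining" in ann.roles
    assert ann.note == NOTE_BINDING


def test_unremarkable_position_is_unclear():
    prof = conserved_profile_with({})
    v = VariantRecord("p", "R", 490, "H")
    ann = annotate_variant(v, 72, prof)
    assert ann.roles == []
    assert ann.note == NOTE_UNCLEAR


def test_annotation_is_pure():
    prof = conserved_profile_with({62: "R"})
    v = VariantRecord("p", "R", 100, "W")
    a1 = annotate_variant(v, 62, prof)
    a2 = annotate_variant(v, 62, prof)
    assert a1 == a2


def test_invalid_variant_records():
    with pytest.raises(ValueError):
        VariantRecord("p", "A", 5, "A")
    with pytest.raises(ValueError):
        VariantRecord("p", "A", 0, "C")


def test_batch_empty_table():
    table = pd.DataFrame(columns=["protein_id", "ref", "pos", "alt",
                                  "classification"])
    out, summary = batch_annotate(table, [], {}, {}, {})
    assert out.empty
    assert summary["mapped"] == 0 and summary["unmapped"] == 0


def test_batch_duplicates_dropped_and_errors_collected(toy_domain):
    domain, msa, hit = toy_domain
    table = pd.DataFrame([
        {"protein_id": "prot1", "ref": "C", "pos": 25, "alt": "Y",
         "classification": "VUS"},
        {"protein_id": "prot1", "ref": "C", "pos": 25, "alt": "Y",
         "classification": "VUS"},
        {"protein_id": "prot1", "ref": "A", "pos": 5, "alt": "A",
         "classification": "VUS"},  # ref == alt: malformed
    ])
    context = {"prot1/21-30": (msa, "prot1/21-30", None)}
    out, summary = batch_annotate(table, [hit], context, {}, {})
    assert summary["n_errors"] == 1
    assert len(out) == 1
    assert out.iloc[0]["column"] == 5


def test_batch_counts_inside_and_outside(benchmark, benchmark_hits):
    from hhdscope.pipeline import synthetic_variant_table
    table = synthetic_variant_table(benchmark, benchmark_hits,
                                    n_variants=10, seed=1)
    by_id = {s.id: s for s in benchmark.database}
    context = {}
    for h in benchmark_hits:
        key = f"{h.target_id}/{h.start}-{h.end}"
        protein = by_id[h.target_id]
        msa = Msa([Sequence(key, protein.residues[h.start - 1: h.end])])
        context[key] = (msa, key, None)
    out, summary = batch_annotate(table, benchmark_hits, context, {}, {})
    assert summary["mapped"] == 4
    assert summary["unmapped"] == 6
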