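"""Mapping missense variants onto master-alignment columns.

A protein-level variant (ref residue, position, alt residue) is located
inside a detected domain envelope, translated to the domain-local
residue index, and carried through the cluster alignment's column map
onto the master coordinate frame. The mapped column is then annotated
with its conservation class and any structural role its position set
implies (stabilizing pair, binding-groove background or lining, helix
interface, supramodule surface), yielding one of three interpretive
notes: a conserved stabilizing-pair member may impair domain stability,
a groove-lining position may affect partner binding, anything else is
left as unclear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .conservation import POSITION_SETS, STABILIZING_PAIRS, ConservationProfile
from .core_io import Msa
from .profile_hmm import DomainHit

logger = logging.getLogger("hhdscope.variants")

_PAIR_POSITIONS = {a for a, b, *_ in STABILIZING_PAIRS} | {
    b for a, b, *_ in STABILIZING_PAIRS
}

NOTE_STABILITY = "may impair domain stability"
NOTE_BINDING = "may affect partner binding"
NOTE_UNCLEAR = "effect unclear"

_ROLE_OF_SET = {
    "groove_background": "groove background",
    "groove_lining": "groove lining",
    "a2_a3_interface": "a2-a3 interface",
    "supramodule_surface": "supramodule surface",
}


class ProvenanceError(ValueError):
    """The stored domain sequence disagrees with the variant's ref residue."""


@dataclass
class VariantRecord:
    """One missense variant on a protein."""

    protein_id: str
    ref: str
    position: int  # 1-based on the protein
    alt: str
    classification: str = "unknown"  # pathogenic / VUS / unknown

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt residues must differ")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class VariantAnnotation:
    """A variant placed on the master alignment frame."""

    variant: VariantRecord
    column: int | None
    in_domain: bool
    conservation_class: str | None = None
    roles: list[str] = field(default_factory=list)
    note: str = ""


def map_variant(
    variant: VariantRecord,
    hit: DomainHit,
    msa: Msa,
    member_id: str,
    column_numbers: list[int] | None = None,
) -> int | None:
    """Master-frame column of a variant, or None with a logged reason.

    The variant's protein position must fall inside the hit envelope;
    it is translated to the domain-local residue index, validated
    against the stored domain sequence, and mapped through the member's
    column map. ``column_numbers`` renumbers alignment columns into the
    master frame (defaults to 1..n_cols).
    """
    if hit.target_id != variant.protein_id:
        raise ValueError("hit and variant refer to different proteins")
    if not hit.start <= variant.position <= hit.end:
        logger.info(
            "variant %s:%s%d%s outside domain envelope [%d, %d]",
            variant.protein_id, variant.ref, variant.position, variant.alt,
            hit.start, hit.end,
        )
        return None
    local = variant.position - hit.start + 1  # 1-based within the domain
    member = msa.member(member_id)
    domain_seq = member.ungapped
    if local > len(domain_seq):
        return None
    if domain_seq[local - 1] != variant.ref.upper():
        raise ProvenanceError(
            f"{variant.protein_id} position {variant.position}: stored domain "
            f"residue {domain_seq[local - 1]} != variant ref {variant.ref} "
            "(sequence version conflict?)"
        )
    col = msa.column_maps[member_id].column_of(local)
    if column_numbers is not None:
        col = column_numbers[col - 1]
    return col


def annotate_variant(
    variant: VariantRecord,
    column: int | None,
    profile: ConservationProfile | None,
) -> VariantAnnotation:
    """Conservation class, structural roles and note for a mapped column."""
    if column is None:
        return VariantAnnotation(variant, None, False, note=NOTE_UNCLEAR)
    roles = [
        _ROLE_OF_SET[name]
        for name, positions in POSITION_SETS.items()
        if column in positions
    ]
    if column in _PAIR_POSITIONS:
        roles.insert(0, "stabilizing pair")
    klass = profile.klass(column) if profile is not None else None
    conserved = profile.is_conserved(column) if profile is not None else False
    if conserved and "stabilizing pair" in roles:
        note = NOTE_STABILITY
    elif "groove lining" in roles:
        note = NOTE_BINDING
    else:
        note = NOTE_UNCLEAR
    return VariantAnnotation(variant, column, True, klass, roles, note)


def batch_annotate(
    table: pd.DataFrame,
    hits: list[DomainHit],
    domain_context: dict[str, tuple[Msa, str, list[int] | None]],
    profiles: dict[str, ConservationProfile],
    profile_of: dict[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Annotate a variant table against detected domains.

    ``table`` needs columns (protein_id, ref, pos, alt, classification).
    ``domain_context`` maps a hit key ``"{target_id}/{start}-{end}"`` to
    (cluster alignment, member id, master column numbers);
    ``profile_of`` maps the same key to a profile name in ``profiles``.
    Malformed rows are collected and reported, processing continues;
    duplicate variant rows are dropped with a warning. Returns the
    annotated table and a summary with per-classification counts.
    """
    required = ["protein_id", "ref", "pos", "alt", "classification"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    before = len(table)
    table = table.drop_duplicates(subset=["protein_id", "ref", "pos", "alt"])
    if len(table) < before:
        logger.warning("dropped %d duplicate variant rows", before - len(table))
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.target_id, []).append(h)
    rows, errors = [], []
    counts = {"mapped": 0, "unmapped": 0, "by_classification": {}}
    for _, row in table.iterrows():
        try:
            variant = VariantRecord(
                str(row["protein_id"]), str(row["ref"]).upper(),
                int(row["pos"]), str(row["alt"]).upper(),
                str(row.get("classification", "unknown")),
            )
        except (ValueError, TypeError) as exc:
            errors.append({"row": dict(row), "error": str(exc)})
            continue
        column, ann = None, None
        for h in hits_by_protein.get(variant.protein_id, []):
            if h.start <= variant.position <= h.end:
                key = f"{h.target_id}/{h.start}-{h.end}"
                msa, member_id, numbers = domain_context[key]
                column = map_variant(variant, h, msa, member_id, numbers)
                profile = profiles.get(profile_of.get(key, ""), None)
                ann = annotate_variant(variant, column, profile)
                break
        if ann is None:
            ann = VariantAnnotation(variant, None, False, note=NOTE_UNCLEAR)
        counts["mapped" if ann.column is not None else "unmapped"] += 1
        cls = variant.classification
        counts["by_classification"][cls] = counts["by_classification"].get(cls, 0) + 1
        rows.append({
            "protein_id": variant.protein_id,
            "ref": variant.ref,
            "pos": variant.position,
            "alt": variant.alt,
            "classification": variant.classification,
            "column": ann.column if ann.column is not None else "",
            "in_domain": ann.in_domain,
            "cons_class": ann.conservation_class or "",
            "roles": ";".join(ann.roles),
            "note": ann.note,
        })
    summary = {"n_input": before, "n_errors": len(errors),
               "errors": errors, **counts}
    return pd.DataFrame(rows), summary
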