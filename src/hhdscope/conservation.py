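"""Per-column conservation profiling of domain-family alignments.

Residues are pooled into ten physicochemical groups for conservation
calculation; a column is *represented* when enough sequences carry a
residue there, and *conserved* when one group dominates the non-gap
residues. Named position sets on the master 1-78 coordinate frame score
candidate functional surfaces (binding-groove background and lining,
helix-interface and supramodule surfaces) and three cross-helix
stabilizing pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, GAP
from .core_io import Msa, Sequence

logger = logging.getLogger("hhdscope.conservation")

#: The ten residue groups used for conservation calculation.
RESIDUE_GROUPS: tuple[str, ...] = (
    "AVILM", "FY", "TS", "QN", "ED", "RKH", "W", "C", "P", "G",
)

#: Display class per group. W and C are not part of the standard color key;
#: they are shown with their chemical neighbours (purely presentational).
DISPLAY_CLASS: dict[str, str] = {
    "AVILM": "hydrophobic",
    "FY": "hydrophobic",
    "RKH": "cationic",
    "ED": "anionic",
    "TS": "polar",
    "QN": "polar",
    "P": "pro_gly",
    "G": "pro_gly",
    "W": "hydrophobic",
    "C": "polar",
}

#: Residue -> group lookup.
GROUP_OF: dict[str, str] = {aa: g for g in RESIDUE_GROUPS for aa in g}

assert sorted("".join(RESIDUE_GROUPS)) == sorted(AMINO_ACIDS)

#: Named position sets on the master alignment frame (columns 1-78).
POSITION_SETS: dict[str, frozenset[int]] = {
    "groove_background": frozenset({7, 11, 27, 61}),
    "groove_lining": frozenset({4, 5, 8, 12, 17, 20, 21, 24, 25, 28, 31}),
    "a2_a3_interface": frozenset({17, 18, 21, 22, 25, 28, 29, 38, 39, 42, 43, 46}),
    "supramodule_surface": frozenset({45, 50, 51, 55, 58, 59, 74, 75}),
}

#: Cross-helix stabilizing pairs: (column A, column B, requirement A, B).
#: A requirement is either a residue group (exact dominant group required)
#: or a set of display classes. Pair (30, 69) is an aromatic-to-charged
#: interaction, so position 30 must be dominated by [FY] while position 69
#: accepts either charge class; the two others are salt bridges.
STABILIZING_PAIRS: tuple[tuple[int, int, object, object], ...] = (
    (30, 69, "FY", frozenset({"cationic", "anionic"})),
    (19, 54, frozenset({"anionic"}), frozenset({"cationic"})),
    (62, 74, frozenset({"cationic"}), frozenset({"anionic"})),
)


class EmptyAlignmentError(ValueError):
    """Filtering removed every sequence."""


class CoordinateError(ValueError):
    """A required master-frame column is not present in the profile."""


@dataclass
class ColumnConservation:
    """Conservation summary of one alignment column (master numbering)."""

    column: int
    representation: float
    dominant_group: str | None
    dominant_frequency: float
    klass: str  # 'grayed', 'unconserved' or a display class
    frequencies: dict[str, float]  # residue -> frequency among non-gap


@dataclass
class ConservationProfile:
    """Per-column conservation of a (cluster) alignment.

    Columns keep their master-frame numbers so that per-cluster profiles
    extracted from a common overall alignment stay comparable.
    """

    columns: dict[int, ColumnConservation]
    n_sequences: int
    represent_threshold: float = 0.80
    conserve_threshold: float = 0.75

    def is_conserved(self, column: int) -> bool:
        col = self.columns.get(column)
        return col is not None and col.klass not in ("grayed", "unconserved")

    def klass(self, column: int) -> str | None:
        col = self.columns.get(column)
        return None if col is None else col.klass


def classify_column(
    representation: float,
    dominant_frequency: float,
    dominant_group: str | None,
    represent_threshold: float = 0.80,
    conserve_threshold: float = 0.75,
) -> str:
    """Class of a column as a pure function of its fractions.

    Grayed when represented in fewer than ``represent_threshold`` of the
    sequences; otherwise colored with the dominant group's display class
    when that group exceeds ``conserve_threshold`` of the non-gap
    residues; otherwise unconserved.
    """
    if representation < represent_threshold:
        return "grayed"
    if dominant_group is not None and dominant_frequency > conserve_threshold:
        return DISPLAY_CLASS[dominant_group]
    return "unconserved"


def filter_alignment(
    msa: Msa, max_col_gap: float = 0.90, max_seq_gap: float = 0.20
) -> tuple[Msa, dict]:
    """Remove hyper-gapped columns, then hyper-gapped sequences.

    Columns with more than ``max_col_gap`` gaps are dropped first; then
    sequences gapped for more than ``max_seq_gap`` of the remaining
    positions are dropped. Returns the filtered alignment and a removal
    log mapping the surviving columns to their original numbers.
    """
    mat = np.array([list(m.residues) for m in msa.members])
    gap_frac_col = (mat == GAP).mean(axis=0)
    keep_cols = np.where(gap_frac_col <= max_col_gap)[0]
    removed_cols = [int(c) + 1 for c in np.where(gap_frac_col > max_col_gap)[0]]
    mat = mat[:, keep_cols]
    gap_frac_seq = (mat == GAP).mean(axis=1) if mat.size else np.ones(len(msa.members))
    keep_rows = np.where(gap_frac_seq <= max_seq_gap)[0]
    removed_seqs = [msa.members[i].id for i in np.where(gap_frac_seq > max_seq_gap)[0]]
    if len(keep_rows) == 0:
        raise EmptyAlignmentError("gap filtering removed every sequence")
    members = [
        Sequence(
            msa.members[i].id,
            "".join(mat[i]),
            msa.members[i].description,
            msa.members[i].taxon,
        )
        for i in keep_rows
    ]
    log = {
        "removed_columns": removed_cols,
        "removed_sequences": removed_seqs,
        "column_numbers": [int(c) + 1 for c in keep_cols],
    }
    if removed_cols or removed_seqs:
        logger.info(
            "filter_alignment: removed %d columns, %d sequences",
            len(removed_cols), len(removed_seqs),
        )
    return Msa(members), log


def conservation_profile(
    msa: Msa,
    represent_threshold: float = 0.80,
    conserve_threshold: float = 0.75,
    column_numbers: list[int] | None = None,
    count_gaps_in_denominator: bool = False,
) -> ConservationProfile:
    """Per-column representation, dominant group and display class.

    ``column_numbers`` supplies master-frame numbers for the alignment's
    columns (defaults to 1..n_cols). By default the conservation
    denominator is the non-gap residue count at the column; setting
    ``count_gaps_in_denominator`` divides by all sequences instead.
    """
    n = len(msa.members)
    cols = column_numbers or list(range(1, msa.n_cols + 1))
    if len(cols) != msa.n_cols:
        raise ValueError("column_numbers length must equal alignment width")
    out: dict[int, ColumnConservation] = {}
    for j, master in enumerate(cols, start=1):
        residues = [c for c in msa.column(j) if c != GAP]
        representation = len(residues) / n
        freqs: dict[str, float] = {}
        group_counts: dict[str, int] = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0) + 1
            if c in GROUP_OF:
                g = GROUP_OF[c]
                group_counts[g] = group_counts.get(g, 0) + 1
        denom = n if count_gaps_in_denominator else max(len(residues), 1)
        freqs = {c: k / max(len(residues), 1) for c, k in freqs.items()}
        if group_counts:
            dominant = max(sorted(group_counts), key=lambda g: group_counts[g])
            dom_freq = group_counts[dominant] / denom
        else:
            dominant, dom_freq = None, 0.0
        out[master] = ColumnConservation(
            column=master,
            representation=representation,
            dominant_group=dominant,
            dominant_frequency=dom_freq,
            klass=classify_column(
                representation, dom_freq, dominant, represent_threshold, conserve_threshold
            ),
            frequencies=freqs,
        )
    return ConservationProfile(out, n, represent_threshold, conserve_threshold)


@dataclass
class PairReport:
    """Presence of one stabilizing pair in one profile."""

    pair: tuple[int, int]
    status: str  # 'present', 'absent' or 'not_evaluable'
    class_a: str | None
    class_b: str | None


def detect_pairs(profile: ConservationProfile) -> list[PairReport]:
    """Score the three cross-helix stabilizing pairs against a profile.

    A pair is present when both positions are conserved with compatible
    classes; pairs with either column missing from the profile (e.g. a
    truncated four-helix outgroup family) are reported not evaluable.
    """
    def _meets(column: int, want: object) -> bool:
        if not profile.is_conserved(column):
            return False
        if isinstance(want, str):  # exact residue-group requirement
            return profile.columns[column].dominant_group == want
        return profile.klass(column) in want

    reports = []
    for a, b, want_a, want_b in STABILIZING_PAIRS:
        if a not in profile.columns or b not in profile.columns:
            reports.append(PairReport((a, b), "not_evaluable", None, None))
            continue
        present = _meets(a, want_a) and _meets(b, want_b)
        reports.append(
            PairReport((a, b), "present" if present else "absent",
                       profile.klass(a), profile.klass(b))
        )
    return reports


def score_position_set(profile: ConservationProfile, set_name: str) -> tuple[int, int]:
    """Count conserved columns in a named position set.

    Returns (conserved count, set size); columns absent from the profile
    count as not conserved but still contribute to the set size.
    """
    if set_name not in POSITION_SETS:
        raise KeyError(f"unknown position set {set_name!r}")
    positions = sorted(POSITION_SETS[set_name])
    missing = [p for p in positions if p not in profile.columns]
    if len(missing) == len(positions):
        raise CoordinateError(f"profile lacks every column of set {set_name!r}")
    conserved = sum(1 for p in positions if profile.is_conserved(p))
    return conserved, len(positions)


def logo_frequencies(profile: ConservationProfile) -> "pd.DataFrame":
    """Per-column residue frequency table for logo rendering.

    Rows are master-frame columns, columns the 20 amino acids; each row
    sums to 1 over the residues present at that column.
    """
    import pandas as pd

    rows = {}
    for master, col in sorted(profile.columns.items()):
        rows[master] = {aa: col.frequencies.get(aa, 0.0) for aa in AMINO_ACIDS}
    return pd.DataFrame.from_dict(rows, orient="index")


def profile_rows(profile: ConservationProfile) -> list[dict]:
    """Flat row form of a profile for TSV export."""
    return [
        {
            "column": c.column,
            "representation": round(c.representation, 4),
            "group": c.dominant_group or "",
            "frequency": round(c.dominant_frequency, 4),
            "class": c.klass,
        }
        for c in sorted(profile.columns.values(), key=lambda c: c.column)
    ]
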