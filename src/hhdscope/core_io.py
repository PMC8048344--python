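"""Sequence / alignment / tree data model and readers-writers.

Coordinates are 1-based and inclusive throughout the package, matching the
convention of the alignment-position numbering used in the domain-family
literature ("position 62 of the alignment"). The canonical gap character is
``-``; ``.`` is accepted on input and converted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import dendropy
from Bio import AlignIO, SeqIO

from .alphabet import AMINO_ACIDS, GAP, UNKNOWN

logger = logging.getLogger("hhdscope.core_io")

_VALID = set(AMINO_ACIDS) | {UNKNOWN}


class FastaFormatError(ValueError):
    """Malformed FASTA input (carries the offending line number)."""


class AlignmentFormatError(ValueError):
    """Ragged or otherwise invalid alignment input."""


class NewickFormatError(ValueError):
    """Unparseable Newick input."""


@dataclass
class Sequence:
    """A protein sequence record.

    ``residues`` is over the 20-letter amino-acid alphabet plus ``X``;
    unknown letters are mapped to ``X`` on ingest with a logged warning.
    Aligned records may additionally contain ``-`` gaps.
    """

    id: str
    residues: str
    description: str = ""
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        self.residues = _sanitize(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def _sanitize(residues: str, seq_id: str) -> str:
    s = residues.upper().replace(".", GAP)
    bad = sorted({c for c in s if c not in _VALID and c != GAP})
    if bad:
        logger.warning(
            "sequence %s: unknown letters %s mapped to %s", seq_id, "".join(bad), UNKNOWN
        )
        s = "".join(c if c in _VALID or c == GAP else UNKNOWN for c in s)
    return s


@dataclass
class ColumnMap:
    """Bijection between ungapped residue indices and alignment columns.

    Both sides are 1-based. ``residue_to_column[i-1]`` gives the alignment
    column of the i-th residue; the inverse is defined on non-gap columns.
    """

    residue_to_column: list[int]
    _col_to_res: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        cols = self.residue_to_column
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("column map must be strictly increasing")
        self._col_to_res = {c: i + 1 for i, c in enumerate(cols)}

    def column_of(self, residue_index: int) -> int:
        return self.residue_to_column[residue_index - 1]

    def residue_of(self, column: int) -> int | None:
        """Ungapped residue index at ``column``, or None for a gap column."""
        return self._col_to_res.get(column)

    def __len__(self) -> int:
        return len(self.residue_to_column)


def column_map(aligned: str) -> ColumnMap:
    """Column map of one aligned string (gaps ``-``)."""
    return ColumnMap([i + 1 for i, c in enumerate(aligned) if c != GAP])


@dataclass
class Msa:
    """A multiple sequence alignment with per-member column maps."""

    members: list[Sequence]

    def __post_init__(self) -> None:
        if not self.members:
            raise AlignmentFormatError("alignment has no members")
        lengths = {len(m.residues) for m in self.members}
        if len(lengths) != 1:
            ragged = [m.id for m in self.members if len(m.residues) != len(self.members[0].residues)]
            raise AlignmentFormatError(f"ragged alignment lengths for members: {ragged}")
        for m in self.members:
            if not m.ungapped:
                raise AlignmentFormatError(f"member {m.id} is all gaps")
        self.column_maps: dict[str, ColumnMap] = {
            m.id: column_map(m.residues) for m in self.members
        }

    @property
    def n_cols(self) -> int:
        return len(self.members[0].residues)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col`` across members."""
        return "".join(m.residues[col - 1] for m in self.members)

    def member(self, seq_id: str) -> Sequence:
        for m in self.members:
            if m.id == seq_id:
                return m
        raise KeyError(seq_id)


def _dedupe_ids(records: list[Sequence]) -> list[Sequence]:
    seen: dict[str, int] = {}
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}_{seen[rec.id]}"
            logger.warning("duplicate id %s renamed to %s", rec.id, new_id)
            rec.id = new_id
        else:
            seen[rec.id] = 0
    return records


def _validate_fasta_lines(path: Path) -> None:
    """Light structural validation so format errors carry a line number."""
    in_record = False
    body_seen = False
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if in_record and not body_seen:
                    raise FastaFormatError(
                        f"{path}: record starting at line {header_line} has an empty body"
                    )
                in_record, body_seen, header_line = True, False, lineno
            else:
                if not in_record:
                    raise FastaFormatError(
                        f"{path}: line {lineno} precedes any '>' header"
                    )
                body_seen = True
    if not in_record:
        raise FastaFormatError(f"{path}: no FASTA records found")
    if not body_seen:
        raise FastaFormatError(
            f"{path}: record starting at line {header_line} has an empty body"
        )


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`, order preserved.

    Ids are the first whitespace-delimited header token; duplicates are
    suffixed and logged; lowercase letters are uppercased.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = [
        Sequence(id=rec.id, residues=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return _dedupe_ids(records)


def write_fasta(records: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, format: str = "fasta") -> Msa:
    """Read an MSA (``fasta`` or ``stockholm``) into an :class:`Msa`.

    Stockholm annotation lines (``#=GC`` etc.) are ignored; per-member
    column maps are computed on construction.
    """
    path = Path(path)
    if format not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format: {format}")
    if format == "fasta":
        _validate_fasta_lines(path)
        raw = list(SeqIO.parse(str(path), "fasta"))
        lengths = {len(r.seq) for r in raw}
        if len(lengths) > 1:
            longest = max(lengths)
            ragged = [r.id for r in raw if len(r.seq) != longest]
            raise AlignmentFormatError(f"{path}: ragged alignment, offending ids {ragged}")
        members = [Sequence(r.id, str(r.seq), r.description) for r in raw]
    else:
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise AlignmentFormatError(f"{path}: {exc}") from exc
        members = [Sequence(r.id, str(r.seq), r.description) for r in aln]
    return Msa(_dedupe_ids(members))


def write_alignment(msa: Msa, path: str | Path) -> None:
    write_fasta(msa.members, path)


_NUMERIC = re.compile(r"^\d+(\.\d+)?$")


def read_newick(path: str | Path, numeric_labels_as_support: bool = False) -> dendropy.Tree:
    """Parse a Newick tree.

    With ``numeric_labels_as_support`` internal-node labels that look
    numeric are interpreted as branch supports (stored on
    ``node.edge.support``) instead of node names.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickFormatError(f"{path}: {exc}") from exc
    if numeric_labels_as_support:
        for node in tree.preorder_internal_node_iter():
            if node.label is not None and _NUMERIC.match(node.label):
                node.edge.support = float(node.label)
                node.label = None
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree, emitting any ``edge.support`` values as internal labels."""
    tree = tree.clone(depth=1)
    for node in tree.preorder_internal_node_iter():
        support = getattr(node.edge, "support", None)
        if support is not None and node.label is None:
            node.label = format(support, ".6g")
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def write_tsv(rows: list[dict], path: str | Path, columns: TSequence[str]) -> None:
    """Write a list of dict rows as UTF-8 TSV with a header row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
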