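"""Readers and writers for the pipeline's external formats.

Sequences travel as :class:`SequenceRecord` (plain amino-acid strings over
the 20-letter alphabet plus ``X``), multiple alignments as
:class:`MultipleAlignment`, and trees as :class:`dendropy.Tree`.  FASTA and
Clustal parsing is delegated to Biopython; Newick to dendropy.  The readers
validate the invariants this pipeline relies on (unique ids, legal residues,
rectangular alignments) and never silently drop records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import AlignIO, SeqIO

#: The residue alphabet accepted everywhere downstream.  ``X`` is the only
#: ambiguity code admitted; it scores 0 against everything so dynamic
#: programming stays well defined.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)
GAP = "-"


class FormatError(ValueError):
    """Raised for malformed input files (empty, ragged, illegal residues...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence, the universal currency of the pipeline."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record must have a non-empty id")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal residue(s) "
                f"{sorted(bad)!r}; allowed alphabet is {ALPHABET}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int, suffix: str = "") -> "SequenceRecord":
        """Sub-record over the 0-based half-open interval [start, end)."""
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {self.id!r} "
                f"(length {len(self.residues)})"
            )
        new_id = f"{self.id}{suffix}" if suffix else self.id
        return SequenceRecord(new_id, self.residues[start:end], self.description)


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


@dataclass
class MultipleAlignment:
    """A rectangular gapped alignment; rows ungap to valid records."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("an alignment needs at least 2 rows")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            offender = next(
                rid for rid, r in self.rows if len(r) != len(self.rows[0][1])
            )
            raise FormatError(
                f"ragged alignment: row {offender!r} has a different length"
            )
        normalised = []
        for rid, row in self.rows:
            row = row.upper()
            # ungapping must yield a valid SequenceRecord (validates residues)
            SequenceRecord(rid, row.replace(GAP, ""))
            normalised.append((rid, row))
        self.rows = normalised
        _check_unique_ids([SequenceRecord(rid, r.replace(GAP, "")) for rid, r in self.rows])

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def ungapped(self) -> list[SequenceRecord]:
        return [SequenceRecord(rid, row.replace(GAP, "")) for rid, row in self.rows]

    def column(self, j: int) -> str:
        return "".join(row[j] for _, row in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)

    def slice_columns(self, cols: Iterable[int]) -> "MultipleAlignment":
        cols = list(cols)
        return MultipleAlignment(
            [(rid, "".join(row[j] for j in cols)) for rid, row in self.rows]
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Headers are split at the first whitespace into id and description.
    Raises :class:`FormatError` on empty files, duplicate ids, or illegal
    residue characters (reported with the offending line number).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    # locate illegal characters with a line number before handing to Biopython
    current_ok = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            current_ok = True
            continue
        if not current_ok:
            raise FormatError(f"{path}:{lineno}: sequence data before first header")
        bad = set(stripped.upper()) - _ALPHABET_SET
        if bad:
            raise FormatError(
                f"{path}:{lineno}: illegal residue character(s) {sorted(bad)!r}"
            )
    records = []
    for seq in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = seq.description.split(None, 1)
        description = desc[1] if len(desc) > 1 else ""
        records.append(SequenceRecord(seq.id, str(seq.seq), description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    _check_unique_ids(records)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (60 columns by default)."""
    _check_unique_ids(list(records))
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> MultipleAlignment:
    """Read an MSA in aligned-FASTA or Clustal dialect.

    ClustalX conservation lines are ignored; interleaved blocks are
    concatenated per id.  Ragged rows raise :class:`FormatError` naming the
    offending id.
    """
    path = Path(path)
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if fmt == "fasta":
        # parse as plain FASTA so ragged rows reach our own validator
        text = path.read_text()
        rows = []
        for seq in SeqIO.parse(io.StringIO(text), "fasta"):
            rows.append((seq.id, str(seq.seq)))
        if not rows:
            raise FormatError(f"{path}: no alignment rows found")
        return MultipleAlignment(rows)
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return MultipleAlignment([(r.id, str(r.seq)) for r in aln])


def write_alignment(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    """Write an MSA as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a string or file path.

    Unbalanced parentheses raise :class:`FormatError` with the position of
    the first imbalance.
    """
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str)
        and "(" not in text_or_path
        and Path(text_or_path).exists()
    ):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise FormatError(f"unbalanced '(': {depth} unclosed at end of input")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to one-line Newick with branch lengths."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Tabular output helpers

def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    """Write a list of dicts as a TSV with a fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
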