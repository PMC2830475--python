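"""Anchored multiple sequence alignments: reading, validation, anchor reduction.

The analyses in this package operate on an MSA that has been *anchored* to a
target protein: every column where the anchor sequence carries a gap is
discarded, and the surviving columns are numbered consecutively in the anchor
protein's own residue numbering (e.g. a kinase catalytic domain running
249-500).  This module provides the alignment container, the aligned-FASTA and
plain aligned-block readers, the anchor-reduction step and per-column
amino-acid counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AA_ALPHABET",
    "AA_INDEX",
    "GAP",
    "Alignment",
    "ColumnMap",
    "ColumnCounts",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "reduce_to_anchor",
    "column_counts",
    "counts_matrix",
]

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
GAP = "-"

#: Characters normalised to the gap symbol in all modes.
_GAP_CHARS = {"-", "."}
#: Ambiguity / non-standard codes: rejected in strict mode, gapped in lenient.
_AMBIGUOUS = set("XBZJUO*")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad characters, bad anchor)."""


def _normalize_row(row: str, record_id: str, strict: bool) -> str:
    out = []
    for pos, ch in enumerate(row.upper()):
        if ch in _GAP_CHARS:
            out.append(GAP)
        elif ch in AA_INDEX:
            out.append(ch)
        elif ch in _AMBIGUOUS and not strict:
            out.append(GAP)
        else:
            raise AlignmentError(
                f"illegal character {ch!r} at column {pos} of record {record_id!r}"
            )
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """A validated alignment over the 20 amino acids plus the gap symbol.

    Rows are upper-case strings of identical length; ``anchor_index`` names the
    target sequence whose residue numbering the analysis reports.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_index: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.rows:
            raise AlignmentError("empty alignment")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"record {rid!r} has length {len(row)}, expected {width}"
                )
        if not (0 <= self.anchor_index < len(self.rows)):
            raise AlignmentError(f"anchor_index {self.anchor_index} out of range")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def anchor_id(self) -> str:
        return self.ids[self.anchor_index]

    @property
    def anchor_row(self) -> str:
        return self.rows[self.anchor_index]

    def to_indices(self) -> np.ndarray:
        """Encode as an (n_sequences, n_columns) int8 array; 0-19 amino acids, -1 gap.

        The encoding is cached on first use.
        """
        cached = self.__dict__.get("_indices")
        if cached is None:
            lut = np.full(128, -1, dtype=np.int8)
            for aa, i in AA_INDEX.items():
                lut[ord(aa)] = i
            raw = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
            cached = lut[raw].reshape(self.n_sequences, self.n_columns)
            object.__setattr__(self, "_indices", cached)
        return cached

    def take_rows(self, row_indices: Sequence[int]) -> "Alignment":
        """Sub-alignment of the given rows (order preserved).

        The anchor is kept as anchor if it survives the selection; otherwise the
        first retained row becomes the nominal anchor.
        """
        row_indices = list(row_indices)
        try:
            new_anchor = row_indices.index(self.anchor_index)
        except ValueError:
            new_anchor = 0
        return Alignment(
            ids=tuple(self.ids[i] for i in row_indices),
            rows=tuple(self.rows[i] for i in row_indices),
            anchor_index=new_anchor,
        )

    def take_columns(self, col_indices: Sequence[int]) -> "Alignment":
        cols = list(col_indices)
        return Alignment(
            ids=self.ids,
            rows=tuple("".join(row[c] for c in cols) for row in self.rows),
            anchor_index=self.anchor_index,
        )


@dataclass(frozen=True)
class ColumnMap:
    """Map from retained (anchor-reduced) columns back to the original alignment.

    ``retained_columns[k]`` is the original column index of retained column ``k``
    and ``anchor_residue_numbers[k]`` its residue number in the anchor protein.
    """

    retained_columns: tuple[int, ...]
    anchor_residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.retained_columns) != len(self.anchor_residue_numbers):
            raise AlignmentError("ColumnMap lists differ in length")
        nums = self.anchor_residue_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise AlignmentError("anchor residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.retained_columns)

    def column_of_residue(self, residue_number: int) -> int:
        """Retained-column index of an anchor residue number."""
        try:
            return self.anchor_residue_numbers.index(residue_number)
        except ValueError:
            raise KeyError(f"residue number {residue_number} not in column map") from None


@dataclass(frozen=True)
class ColumnCounts:
    """Amino-acid occurrence counts at one alignment column (gaps excluded)."""

    counts: np.ndarray  # shape (20,), int
    n_effective: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_effective:
            raise AlignmentError("counts do not sum to n_effective")

    def frequency(self, residue: str) -> float:
        """Fraction of non-gap characters equal to ``residue``; 0 if the column is empty."""
        if self.n_effective == 0:
            return 0.0
        return float(self.counts[AA_INDEX[residue]]) / self.n_effective


# ---------------------------------------------------------------------------
# I/O


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    rid = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if rid is not None:
                records.append((rid, "".join(chunks)))
            rid = line[1:].split()[0] if line[1:].strip() else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if rid is not None:
        records.append((rid, "".join(chunks)))
    return records


def _parse_aligned_block(text: str, delimiter: str | None) -> list[tuple[str, str]]:
    """Plain aligned-text dialect: one ``identifier  aligned-sequence`` pair per line.

    Tolerant by design: blank lines and ``#`` comments are skipped, and repeated
    identifiers have their segments concatenated, which also accepts interleaved
    (clustal-like) blocks without a header line.
    """
    order: list[str] = []
    parts: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        fields = line.split(delimiter) if delimiter else line.split()
        if len(fields) < 2:
            raise AlignmentError(f"cannot parse aligned-block line: {line!r}")
        rid, seq = fields[0], "".join(fields[1:])
        if rid not in parts:
            order.append(rid)
            parts[rid] = []
        parts[rid].append(seq)
    return [(rid, "".join(parts[rid])) for rid in order]


def read_alignment(
    path: str | Path,
    anchor: str | int = 0,
    *,
    strict: bool = True,
    delimiter: str | None = None,
) -> Alignment:
    """Read an aligned FASTA file or a plain aligned-block text file.

    Parameters
    ----------
    path:
        File to read.  Files whose first non-blank character is ``>`` are parsed
        as aligned FASTA; anything else as a plain aligned block (identifier,
        whitespace or ``delimiter``, aligned string; one or more lines per
        sequence).
    anchor:
        Identifier or row index of the anchor (target) sequence.
    strict:
        If True, ambiguity codes (X/B/Z/J/U/O) raise; if False they are read as
        gaps.  ``-`` and ``.`` are both accepted as gaps and normalised to ``-``.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        raw = _parse_fasta(text)
    else:
        raw = _parse_aligned_block(text, delimiter)
    if not raw:
        raise AlignmentError(f"no sequences found in {path}")
    ids = tuple(rid for rid, _ in raw)
    rows = tuple(_normalize_row(seq, rid, strict) for rid, seq in raw)
    if isinstance(anchor, int):
        anchor_index = anchor
        if not (-len(ids) <= anchor_index < len(ids)):
            raise AlignmentError(f"anchor index {anchor} out of range")
        anchor_index %= len(ids)
    else:
        try:
            anchor_index = ids.index(anchor)
        except ValueError:
            raise AlignmentError(f"anchor {anchor!r} not found among sequence ids") from None
    return Alignment(ids=ids, rows=rows, anchor_index=anchor_index)


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write as aligned FASTA with ``-`` gaps."""
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for start in range(0, len(row), width):
                fh.write(row[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# Anchor reduction and counting


def reduce_to_anchor(aln: Alignment, first_residue_number: int) -> tuple[Alignment, ColumnMap]:
    """Drop every column where the anchor has a gap; number the rest consecutively.

    Residue numbers start at ``first_residue_number`` and increase by one per
    retained column, i.e. insertions of the anchor protein relative to the
    construct must already be absorbed into the offset by the caller.
    """
    keep = [c for c in range(aln.n_columns) if aln.anchor_row[c] != GAP]
    if not keep:
        raise AlignmentError("anchor row consists entirely of gaps")
    cmap = ColumnMap(
        retained_columns=tuple(keep),
        anchor_residue_numbers=tuple(first_residue_number + k for k in range(len(keep))),
    )
    return aln.take_columns(keep), cmap


def counts_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column amino-acid counts for the whole alignment.

    Returns ``(counts, n_effective)`` with shapes ``(n_columns, 20)`` and
    ``(n_columns,)``; gaps are excluded from both.
    """
    idx = aln.to_indices()
    counts = np.zeros((aln.n_columns, 20), dtype=np.int64)
    for a in range(20):
        counts[:, a] = (idx == a).sum(axis=0)
    n_eff = (idx >= 0).sum(axis=0).astype(np.int64)
    return counts, n_eff


def column_counts(aln: Alignment, column: int) -> ColumnCounts:
    """Counts of the 20 amino acids at one column; gaps excluded."""
    if not (0 <= column < aln.n_columns):
        raise IndexError(f"column {column} out of range for {aln.n_columns} columns")
    idx = aln.to_indices()[:, column]
    counts = np.bincount(idx[idx >= 0], minlength=20).astype(np.int64)
    return ColumnCounts(counts=counts, n_effective=int((idx >= 0).sum()))
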