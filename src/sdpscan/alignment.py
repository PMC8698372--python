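"""Reading, validating and interrogating multiple sequence alignments.

Alignments are held as immutable rows of uppercase symbols over the 20
standard residues plus the gap character ``-``.  Nonstandard residue
codes (B, J, O, U, X, Z and anything else unrecognised) are demoted to
gaps on input — the scoring rules only ever distinguish "standard
residue" from "gap" — and a warning with counts is logged.

Columns are 1-based in every user-facing interface, matching the
residue-number conventions of alignment viewers and of the reports this
package produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import AlignmentError
from .scales import AA_INDEX, AMINO_ACIDS

logger = logging.getLogger(__name__)

GAP = "-"
#: Integer code used for gaps in :meth:`Alignment.codes` (residues are 0..19).
GAP_CODE = -1

_VALID = set(AMINO_ACIDS) | {GAP}


@dataclass(frozen=True)
class Column:
    """One alignment column: its 1-based index and per-protein symbols."""

    index: int
    residues: tuple[str, ...]

    @property
    def gap_fraction(self) -> float:
        return self.residues.count(GAP) / len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An immutable protein multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique protein identifiers, one per row.
    rows
        Aligned sequences of identical length over residues and ``-``.
    reference
        Row index (0-based) of the sequence used for residue numbering;
        defaults to the first row.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.ids) != len(self.rows):
            raise AlignmentError(
                f"{len(self.ids)} identifiers for {len(self.rows)} sequences")
        if len(self.rows) < 3:
            raise AlignmentError(
                "an alignment of fewer than 3 sequences has too few protein"
                " pairs for a rank correlation")
        if len(set(self.ids)) != len(self.ids):
            dups = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate identifiers: {dups}")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError("alignment has zero columns")
        for name, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(row)}, expected {length}")
            bad = set(row) - _VALID
            if bad:
                raise AlignmentError(
                    f"sequence {name!r} contains invalid symbols {sorted(bad)}"
                    " (normalise input through read_alignment)")
        if not 0 <= self.reference < len(self.rows):
            raise AlignmentError(f"reference index {self.reference} out of range")

    # -- basic geometry -------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def column(self, k: int) -> Column:
        """The ``k``-th column (1-based)."""
        if not 1 <= k <= self.length:
            raise AlignmentError(f"column {k} out of range 1..{self.length}")
        return Column(index=k, residues=tuple(row[k - 1] for row in self.rows))

    def gap_fraction(self, k: int) -> float:
        return self.column(k).gap_fraction

    def codes(self) -> np.ndarray:
        """Integer encoding, shape (n_sequences, length): 0..19 residues, -1 gaps."""
        out = np.full((self.n_sequences, self.length), GAP_CODE, dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i, :] = [AA_INDEX.get(ch, GAP_CODE) for ch in row]
        return out

    # -- reference numbering --------------------------------------------

    def with_reference(self, ref_id: str) -> "Alignment":
        """A copy using the sequence named ``ref_id`` for residue numbering."""
        try:
            idx = self.ids.index(ref_id)
        except ValueError:
            raise AlignmentError(f"reference id {ref_id!r} not in alignment") from None
        return Alignment(ids=self.ids, rows=self.rows, reference=idx)

    def reference_numbering(self) -> dict[int, int | None]:
        """Map 1-based column -> 1-based ungapped residue number of the reference.

        Columns where the reference sequence is gapped map to ``None``.
        The defined part of the mapping is strictly increasing.
        """
        numbering: dict[int, int | None] = {}
        counter = 0
        for k, ch in enumerate(self.rows[self.reference], start=1):
            if ch == GAP:
                numbering[k] = None
            else:
                counter += 1
                numbering[k] = counter
        return numbering

    def reference_residue(self, k: int) -> str | None:
        ch = self.rows[self.reference][k - 1]
        return None if ch == GAP else ch


def _normalize(seq: str, demoted: dict[str, int]) -> str:
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        if ch not in _VALID:
            demoted[ch] = demoted.get(ch, 0) + 1
            ch = GAP
        out.append(ch)
    return "".join(out)


def _records_to_alignment(records: Iterable[tuple[str, str]]) -> Alignment:
    ids, rows = [], []
    demoted: dict[str, int] = {}
    for name, seq in records:
        ids.append(name)
        rows.append(_normalize(seq, demoted))
    if demoted:
        total = sum(demoted.values())
        logger.warning(
            "demoted %d nonstandard residue(s) to gaps: %s", total,
            ", ".join(f"{ch}x{n}" for ch, n in sorted(demoted.items())))
    if len(rows) >= 2:
        length = len(rows[0])
        for name, row in zip(ids, rows):
            if len(row) != length:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(row)}, expected {length};"
                    " input is not a flush alignment")
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def read_alignment(source: str | Path | IO[str], format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    Letters are uppercased, ``.`` is normalised to ``-`` and nonstandard
    residue codes are demoted to gaps (logged with counts).
    """
    fmt = format.lower()
    if fmt not in {"fasta", "clustal"}:
        raise AlignmentError(f"unsupported alignment format {format!r}")
    handle = open(source) if not hasattr(source, "read") else source
    try:
        if fmt == "fasta":
            # SeqIO rather than AlignIO so ragged input fails with the
            # offending sequence named instead of a generic shape error.
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
        else:
            try:
                msa = AlignIO.read(handle, "clustal")
            except ValueError as exc:
                raise AlignmentError(f"could not parse Clustal input: {exc}") from exc
            records = [(rec.id, str(rec.seq)) for rec in msa]
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise AlignmentError("no sequences found in input")
    return _records_to_alignment(records)


def write_alignment(alignment: Alignment, dest: str | Path | IO[str]) -> None:
    """Write an alignment as aligned FASTA (60-column wrapped)."""
    handle = open(dest, "w") if not hasattr(dest, "write") else dest
    try:
        for name, row in zip(alignment.ids, alignment.rows):
            handle.write(f">{name}\n")
            for i in range(0, len(row), 60):
                handle.write(row[i:i + 60] + "\n")
    finally:
        if handle is not dest:
            handle.close()
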