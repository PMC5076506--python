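"""Multiple sequence alignment container with reference-numbering map."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

from allokin.curation import AMINO_ACIDS, GAP, SequenceRecord

# Integer codes: 0..19 amino acids, 20 = gap or ambiguity ('X' is treated as
# missing data in column statistics, like a gap).
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MISSING_CODE = len(AMINO_ACIDS)


@dataclass
class Alignment:
    """Equal-length aligned sequences plus an optional reference numbering.

    ``column_map`` assigns a reference residue number to each column where the
    designated reference row has a residue; unmapped (reference-gap) columns
    carry None.  Mapped numbers are strictly increasing left to right.
    """

    records: list[SequenceRecord]
    reference_id: str | None = None
    reference_start: int = 1
    column_map: list[int | None] = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one record")
        length = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != length:
                raise ValueError(
                    f"row {rec.id} has length {len(rec.residues)}, expected {length}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        self.column_map = self._build_column_map()

    def _build_column_map(self) -> list[int | None]:
        if self.reference_id is None:
            return [None] * self.n_columns
        ref = self[self.reference_id].residues
        if "X" in ref:
            raise ValueError("reference row contains ambiguity characters")
        out: list[int | None] = []
        num = self.reference_start
        for ch in ref:
            if ch == GAP:
                out.append(None)
            else:
                out.append(num)
                num += 1
        return out

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def __contains__(self, seq_id: str) -> bool:
        return any(rec.id == seq_id for rec in self.records)

    def encoded(self) -> np.ndarray:
        """Integer-coded matrix, shape (n_rows, n_columns), dtype uint8."""
        mat = np.full((self.n_rows, self.n_columns), MISSING_CODE, dtype=np.uint8)
        for r, rec in enumerate(self.records):
            for c, ch in enumerate(rec.residues):
                mat[r, c] = AA_INDEX.get(ch, MISSING_CODE)
        return mat

    def column(self, col: int) -> str:
        if not (0 <= col < self.n_columns):
            raise IndexError(f"column {col} out of range 0..{self.n_columns - 1}")
        return "".join(rec.residues[col] for rec in self.records)

    def column_for_residue(self, residue_number: int) -> int:
        """Alignment column carrying the given reference residue number."""
        try:
            return self.column_map.index(residue_number)
        except ValueError:
            raise KeyError(
                f"reference residue {residue_number} is not mapped in this alignment"
            ) from None

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        fmt: str = "fasta",
        reference_id: str | None = None,
        reference_start: int = 1,
    ) -> "Alignment":
        """Read an MSA from FASTA or Stockholm."""
        aln = AlignIO.read(str(path), fmt)
        records = [
            SequenceRecord(id=r.id, residues=str(r.seq), description=r.description)
            for r in aln
        ]
        return cls(records, reference_id=reference_id, reference_start=reference_start)

    @classmethod
    def from_records(
        cls,
        records: Sequence[SequenceRecord],
        reference_id: str | None = None,
        reference_start: int = 1,
    ) -> "Alignment":
        return cls(list(records), reference_id=reference_id, reference_start=reference_start)
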