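"""Sequence curation: redundancy pruning and fragment filtering.

Reproduces the pre-alignment hygiene steps used for large motor-protein
sequence sets: exact/near duplicates above a pairwise-identity threshold are
collapsed to one representative and fragmentary records (truncated at either
terminus) are dropped.  Database cross-reference checks require live queries
and are recorded in the report as not applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
# 'X' is tolerated on input and always scored as a mismatch.
VALID_CHARS = frozenset(AMINO_ACIDS + "X" + GAP)

IdentityMode = Literal["auto", "aligned", "global"]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: accession id, free-text description, residues.

    Residues are upper-cased on construction and restricted to the 20-letter
    amino-acid alphabet plus 'X' (ambiguity) and '-' (gap, for pre-aligned
    input).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        seq = self.residues.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - VALID_CHARS
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)!r}")
        object.__setattr__(self, "residues", seq)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CurationReport:
    """Book-keeping for a curation run; counts always reconcile."""

    n_input: int = 0
    n_removed_unreferenced: int = 0
    n_removed_fragment: int = 0
    n_removed_redundant: int = 0
    n_output: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        removed = (
            self.n_removed_unreferenced
            + self.n_removed_fragment
            + self.n_removed_redundant
        )
        if self.n_input != self.n_output + removed:
            raise AssertionError(
                f"curation counts do not reconcile: {self.n_input} != "
                f"{self.n_output} + {removed}"
            )
        if len(self.removed_ids) != removed:
            raise AssertionError("removed_ids length does not match counts")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        payload = {
            "n_input": self.n_input,
            "n_removed_unreferenced": self.n_removed_unreferenced,
            "n_removed_fragment": self.n_removed_fragment,
            "n_removed_redundant": self.n_removed_redundant,
            "n_output": self.n_output,
            "removed_ids": [list(pair) for pair in self.removed_ids],
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _global_aligner()


def pairwise_identity(
    a: SequenceRecord, b: SequenceRecord, mode: IdentityMode = "auto"
) -> float:
    """Fraction of identical residues between two sequences, in [0, 1].

    Two conventions are supported and the choice is explicit:

    - ``aligned``: the sequences are rows of the same alignment; identity is
      matches / number of columns where neither sequence has a gap.
    - ``global``: the sequences are unaligned; a global pairwise alignment
      (BLOSUM62, affine gaps) is computed and identity is matches / total
      alignment length, gap columns included in the denominator.
    - ``auto`` (default): ``aligned`` when the raw strings have equal length,
      else ``global``.

    'X' never matches anything, including another 'X'.  The function is
    symmetric in its arguments under both conventions.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot compute identity of an empty sequence")
    if mode == "auto":
        mode = "aligned" if len(a.residues) == len(b.residues) else "global"

    if mode == "aligned":
        if len(a.residues) != len(b.residues):
            raise ValueError(
                "aligned identity requires equal-length sequences "
                f"({a.id}: {len(a)}, {b.id}: {len(b)})"
            )
        matches = 0
        columns = 0
        for x, y in zip(a.residues, b.residues):
            if x == GAP or y == GAP:
                continue
            columns += 1
            if x == y and x != "X":
                matches += 1
        if columns == 0:
            return 0.0
        return matches / columns

    sa, sb = a.ungapped, b.ungapped
    alignment = _ALIGNER.align(sa, sb)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x not in (GAP, "X")
    )
    return matches / len(aligned_a)


def prune_redundant(
    seqs: Sequence[SequenceRecord],
    threshold: float = 0.95,
    mode: IdentityMode = "auto",
) -> tuple[list[SequenceRecord], CurationReport]:
    """Greedy removal of near-duplicate sequences.

    Sequences are scanned in input order; a record is kept iff its identity to
    every already-kept record is <= ``threshold``.  First-seen-kept makes the
    result deterministic.  Records whose identity to some kept record exceeds
    the threshold are removed with reason ``redundant``.
    """
    if not seqs:
        raise ValueError("prune_redundant requires at least one sequence")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique within a dataset")

    kept: list[SequenceRecord] = []
    report = CurationReport(n_input=len(seqs))

    lengths = {len(s.residues) for s in seqs}
    if mode in ("auto", "aligned") and len(lengths) == 1:
        # vectorized path, identical to the scalar aligned convention
        mat = np.array([list(s.residues) for s in seqs])
        is_res = (mat != GAP) & (mat != "X")
        kept_idx: list[int] = []
        for r in range(len(seqs)):
            redundant = False
            for k in kept_idx:
                both = is_res[r] & (mat[k] != GAP)
                informative = (mat[r] != GAP) & (mat[k] != GAP)
                ncols = int(informative.sum())
                if ncols == 0:
                    continue
                matches = int((informative & is_res[r] & (mat[r] == mat[k])).sum())
                if matches / ncols > threshold:
                    redundant = True
                    break
            if redundant:
                report.removed_ids.append((seqs[r].id, "redundant"))
                report.n_removed_redundant += 1
            else:
                kept_idx.append(r)
        kept = [seqs[r] for r in kept_idx]
    else:
        for seq in seqs:
            if any(
                pairwise_identity(seq, ref, mode=mode) > threshold for ref in kept
            ):
                report.removed_ids.append((seq.id, "redundant"))
                report.n_removed_redundant += 1
            else:
                kept.append(seq)
    report.n_output = len(kept)
    report.validate()
    return kept, report


def filter_fragments(
    seqs: Sequence[SequenceRecord], min_fraction_of_median: float = 0.7
) -> tuple[list[SequenceRecord], CurationReport]:
    """Drop fragmentary records by ungapped length.

    A record is a fragment when its ungapped length is below
    ``min_fraction_of_median`` times the median ungapped length of the input
    set.  This operationalizes "incomplete at either terminus" without
    terminus-specific bookkeeping: truncations at either end shorten the
    sequence the same way.
    """
    if not seqs:
        raise ValueError("filter_fragments requires at least one sequence")
    lengths = np.array([len(s.ungapped) for s in seqs], dtype=float)
    cutoff = min_fraction_of_median * float(np.median(lengths))
    kept: list[SequenceRecord] = []
    report = CurationReport(n_input=len(seqs))
    for seq, n in zip(seqs, lengths):
        if n < cutoff:
            report.removed_ids.append((seq.id, "fragment"))
            report.n_removed_fragment += 1
        else:
            kept.append(seq)
    report.n_output = len(kept)
    report.validate()
    return kept, report


def curate(
    seqs: Sequence[SequenceRecord],
    identity_threshold: float = 0.95,
    min_length_fraction: float = 0.7,
    mode: IdentityMode = "auto",
) -> tuple[list[SequenceRecord], CurationReport]:
    """Full curation: fragment filter, then redundancy pruning.

    The database cross-reference filter (removal of unreferenced entries)
    needs live queries and is recorded in the report notes as not applied.
    """
    full, frag_report = filter_fragments(seqs, min_length_fraction)
    kept, red_report = prune_redundant(full, identity_threshold, mode=mode)
    report = CurationReport(
        n_input=len(seqs),
        n_removed_fragment=frag_report.n_removed_fragment,
        n_removed_redundant=red_report.n_removed_redundant,
        n_output=len(kept),
        removed_ids=frag_report.removed_ids + red_report.removed_ids,
        notes=["unreferenced-entry filter not applied (requires database access)"],
    )
    report.validate()
    return kept, report


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=r.id, residues=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(seqs: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs),
        str(path),
        "fasta",
    )
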