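"""Map network positions onto 3-D coordinates; contact/distal classification.

Distances are Euclidean Calpha–Calpha separations in angstroms.  Two residues
are in tertiary-structure contact when d_ij < 6 A; pairs at 6 A or more are
distal.  The 6 A cut is deliberately generous relative to a van der Waals cut
(~4 A) so that residue pairs stay non-contacting even after side-chain
substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from allokin.network import AllosteryNetwork

CONTACT_CUTOFF = 6.0  # angstrom; contact iff d < cutoff


@dataclass
class StructureModel:
    """Calpha coordinates keyed by reference residue number."""

    coordinates: dict[int, np.ndarray]
    source_id: str = ""
    chain: str = "A"

    def is_resolved(self, residue: int) -> bool:
        return residue in self.coordinates

    @property
    def residues(self) -> list[int]:
        return sorted(self.coordinates)


def load_pdb(
    path: str | Path,
    chain: str = "A",
    numbering_offset: int = 0,
    source_id: str | None = None,
) -> StructureModel:
    """Read Calpha coordinates from a PDB file.

    First model only, one chain; altloc 'A' (or blank) preferred when a CA is
    duplicated.  ``numbering_offset`` is added to PDB residue numbers to bring
    them onto the reference numbering.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(source_id or Path(path).stem, str(path))
    model = next(structure.get_models())
    if chain not in model:
        raise KeyError(f"chain {chain!r} not present in {path}")
    coords: dict[int, np.ndarray] = {}
    for residue in model[chain]:
        hetflag, resnum, _icode = residue.id
        if hetflag.strip():
            continue
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            try:
                atom = atom.disordered_get("A")
            except KeyError:
                atom = atom.disordered_get_list()[0]
        coords[resnum + numbering_offset] = np.asarray(atom.coord, dtype=float)
    if not coords:
        raise ValueError(f"no Calpha atoms found in {path} chain {chain}")
    return StructureModel(
        coordinates=coords, source_id=source_id or Path(path).stem, chain=chain
    )


def ca_distance(model: StructureModel, i: int, j: int) -> float:
    """Calpha–Calpha distance in angstroms; NaN if either residue is
    unresolved (check with ``is_resolved`` for an explicit flag)."""
    if not model.is_resolved(i) or not model.is_resolved(j):
        return float("nan")
    d = float(np.linalg.norm(model.coordinates[i] - model.coordinates[j]))
    return d


def classify_pair(d: float) -> str:
    """'contact' iff d < 6 A, else 'distal'.  Exactly 6 A is distal."""
    if d < 0 or not np.isfinite(d):
        raise ValueError(f"distance must be finite and non-negative, got {d}")
    return "contact" if d < CONTACT_CUTOFF else "distal"


@dataclass
class DistanceHistogram:
    """Stratified Calpha–Calpha distance histogram over network edges."""

    bin_edges: np.ndarray  # length n_bins + 1
    counts: dict[str, np.ndarray]  # per stratum, length n_bins
    n_edges: int
    n_excluded: int  # edges with an unresolved endpoint
    fraction_distal: float
    distances: pd.DataFrame = field(repr=False, default=None)

    @property
    def total_counts(self) -> np.ndarray:
        return sum(self.counts.values())


def distance_histogram(
    net: AllosteryNetwork,
    model: StructureModel,
    bin_width: float = 4.0,
    n_bins: int = 10,
    bin_start: float = 4.0,
) -> DistanceHistogram:
    """Bin edge distances per coupling stratum.

    Bins are half-open [lo, hi) of ``bin_width`` angstroms starting at
    ``bin_start``; distances outside the binned range are clipped into the
    first/last bin so that counts conserve the number of classifiable edges.
    Edges with an unresolved endpoint are excluded and tallied separately;
    if every edge is excluded this is an error.
    """
    edges = np.arange(n_bins + 1, dtype=float) * bin_width + bin_start
    strata = sorted({s for _, _, _, s in net.edges})
    counts = {s: np.zeros(n_bins, dtype=int) for s in strata}
    rows = []
    n_excluded = 0
    n_distal = 0
    n_classified = 0
    for i, j, energy, stratum in net.edges:
        d = ca_distance(model, i, j)
        if np.isnan(d):
            n_excluded += 1
            continue
        n_classified += 1
        cls = classify_pair(d)
        if cls == "distal":
            n_distal += 1
        idx = int(np.clip(np.floor((d - bin_start) / bin_width), 0, n_bins - 1))
        counts[stratum][idx] += 1
        rows.append(
            {"i": i, "j": j, "ddg_stat_kt": energy, "stratum": stratum,
             "distance_A": d, "class": cls}
        )
    if n_classified == 0:
        raise ValueError("no network edge has both endpoints resolved")
    return DistanceHistogram(
        bin_edges=edges,
        counts=counts,
        n_edges=n_classified,
        n_excluded=n_excluded,
        fraction_distal=n_distal / n_classified,
        distances=pd.DataFrame(rows),
    )
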