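"""Allosteric residue network built from the SCA coupling matrix.

Positions with at least one coupling at or above the energy threshold
(default 1.0 kT*) become network nodes; each supra-threshold pair is an
undirected edge labelled with a coupling stratum — intermediate for energies
in [1.0, 1.4) kT*, high for >= 1.4 kT* (the printed stratum bounds 1–1.39 and
1.4–2.4 are treated as rounded bin edges).  Degree is the number of distinct
coupled partners; hub residues have degree >= 9.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from allokin.alignment import Alignment
from allokin.curation import GAP
from allokin.sca import CouplingMatrix

INTERMEDIATE_MAX = 1.4  # exclusive upper edge of the intermediate stratum, kT*


def _stratum(energy: float, threshold: float) -> str:
    return "intermediate" if energy < INTERMEDIATE_MAX else "high"


@dataclass
class AllosteryNetwork:
    """Thresholded residue-coupling graph.

    nodes: reference residue numbers (alignment column indices when the
    coupling matrix carries no numbering map).
    edges: (i, j, energy kT*, stratum), i < j, undirected, no multiplicity.
    """

    nodes: list[int]
    edges: list[tuple[int, int, float, str]]
    threshold: float = 1.0
    sectors: dict[int, dict] = field(default_factory=dict)

    @property
    def degrees(self) -> dict[int, int]:
        deg = {n: 0 for n in self.nodes}
        for i, j, _, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["i", "j", "ddg_stat_kt", "stratum"]
        )

    def node_table(self, hub_min_degree: int = 9) -> pd.DataFrame:
        deg = self.degrees
        hubs = set(classify_hubs(self, hub_min_degree))
        rows = []
        for n in self.nodes:
            sec = self.sectors.get(n, {})
            rows.append(
                {
                    "residue": n,
                    "degree": deg[n],
                    "hub": n in hubs,
                    "sector": sec.get("sector"),
                    "co_sector": sec.get("co_sector"),
                }
            )
        return pd.DataFrame(rows)


def build_network(cm: CouplingMatrix, threshold: float = 1.0) -> AllosteryNetwork:
    """Threshold the coupling matrix into an AllosteryNetwork.

    Uses the symmetrized matrix; masked pairs never contribute edges.  Columns
    without a reference number are labelled by their column index.  An empty
    result is a valid network (with a warning), not an error.
    """
    labels = [
        p if p is not None else c for c, p in enumerate(cm.positions)
    ]
    supra = cm.valid & (np.nan_to_num(cm.ddg_stat, nan=-np.inf) >= threshold)
    edges = []
    for i, j in zip(*np.where(np.triu(supra, k=1))):
        e = float(cm.ddg_stat[i, j])
        edges.append((labels[i], labels[j], e, _stratum(e, threshold)))
    node_cols = np.where(supra.any(axis=1))[0]
    nodes = [labels[c] for c in node_cols]
    if not nodes:
        warnings.warn("no couplings at or above threshold; network is empty")
    return AllosteryNetwork(nodes=nodes, edges=edges, threshold=threshold)


def classify_hubs(net: AllosteryNetwork, min_degree: int = 9) -> list[int]:
    """Nodes coupled to at least ``min_degree`` other residues."""
    return sorted(n for n, d in net.degrees.items() if d >= min_degree)


def degree_histogram(net: AllosteryNetwork) -> tuple[dict[int, int], int | None]:
    """Counts of nodes per degree value, plus the modal degree.

    One bin per occupied integer degree; the bin masses sum to the node
    count.  The mode is None for an empty network; degree ties are broken
    toward the smaller degree.
    """
    counts = Counter(net.degrees.values())
    hist = dict(sorted(counts.items()))
    if not hist:
        return {}, None
    mode = max(hist, key=lambda d: (hist[d], -d))
    return hist, mode


def divergence_at_positions(
    aln: Alignment, id_a: str, id_b: str, positions: list[int]
) -> tuple[int, pd.DataFrame]:
    """Count network positions whose residues differ between two sequences.

    Comparison happens in alignment columns (homologous coordinates), mapped
    from reference residue numbers via the alignment's column map.  A
    gap-versus-residue column counts as divergent and is flagged; gap-versus-
    gap does not count as divergent.  Unmapped positions raise an error that
    lists them.
    """
    unmapped = [p for p in positions if p not in aln.column_map]
    if unmapped:
        raise KeyError(f"positions not mapped in alignment: {unmapped}")
    seq_a = aln[id_a].residues
    seq_b = aln[id_b].residues
    rows = []
    for pos in positions:
        col = aln.column_for_residue(pos)
        ra, rb = seq_a[col], seq_b[col]
        gap_involved = GAP in (ra, rb)
        divergent = ra != rb or (ra == GAP and rb != GAP) or (rb == GAP and ra != GAP)
        if ra == GAP and rb == GAP:
            divergent = False
        rows.append(
            {
                "position": pos,
                "column": col,
                "residue_a": ra,
                "residue_b": rb,
                "divergent": divergent,
                "gap_involved": gap_involved,
            }
        )
    table = pd.DataFrame(rows)
    return int(table["divergent"].sum()), table
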