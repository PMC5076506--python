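"""Synthetic alignments, Calpha traces, and ATPase titrations.

Every generator takes an explicit seed and is bit-reproducible.  The MSA
generator emulates the statistical structure SCA needs — independent
background columns plus a small set of planted co-varying column pairs —
without phylogenetic correlation (a star phylogeny): each sequence is an
independent draw.  Redundant near-duplicate clusters and terminal fragments
can be injected to exercise the curation stage.

The covariation scheme per planted pair (i, j): two compatible residue
combinations (a1, b1) and (a2, b2) are fixed; with probability epsilon a
sequence adopts one combination (coin flip between the two), otherwise both
columns are drawn independently from the background.  epsilon = 0 is
independence, epsilon = 1 deterministic compensatory covariation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from allokin.alignment import Alignment
from allokin.curation import AMINO_ACIDS, SequenceRecord
from allokin.structure import StructureModel
from allokin.kinetics import KineticDataset


@dataclass
class MSASimSpec:
    """Ground-truth description of a synthetic MSA.

    Defaults mirror a mid-sized curated motor-domain family: 800 sequences,
    120 columns, four planted pairs at mixing strength 0.8.
    """

    n_sequences: int = 800
    n_columns: int = 120
    planted_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(5, 60, 0.8), (20, 90, 0.8), (33, 70, 0.8), (45, 110, 0.8)]
    )
    background: np.ndarray | None = None  # length-20; uniform when None
    redundancy_clusters: tuple[int, float] = (0, 0.98)  # (count, within-identity)
    cluster_size: int = 4
    fragment_fraction: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        cols = [c for i, j, _ in self.planted_pairs for c in (i, j)]
        if len(set(cols)) != len(cols):
            raise ValueError("planted pairs must be disjoint")
        if any(
            not (0 <= i < self.n_columns and 0 <= j < self.n_columns)
            for i, j, _ in self.planted_pairs
        ):
            raise ValueError("planted pair column out of range")
        if any(not (0.0 <= eps <= 1.0) for _, _, eps in self.planted_pairs):
            raise ValueError("mixing strength must be in [0, 1]")


def _background(spec: MSASimSpec) -> np.ndarray:
    if spec.background is None:
        return np.full(20, 1 / 20)
    q = np.asarray(spec.background, float)
    if q.shape != (20,) or not np.isclose(q.sum(), 1.0):
        raise ValueError("background must be a length-20 frequency vector")
    return q


def simulate_msa(spec: MSASimSpec) -> tuple[Alignment, dict]:
    """Generate an alignment plus its ground-truth record.

    The truth dict records planted pair columns and combinations, injected
    redundancy cluster members, and fragment row ids.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    q = _background(spec)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    base = rng.choice(20, size=(spec.n_sequences, spec.n_columns), p=q)

    combos: dict[tuple[int, int], tuple] = {}
    for i, j, eps in spec.planted_pairs:
        # two compatible residue combinations, four distinct amino acids
        picks = rng.choice(20, size=4, replace=False)
        (a1, b1, a2, b2) = (int(v) for v in picks)
        combos[(i, j)] = ((a1, b1), (a2, b2))
        consistent = rng.random(spec.n_sequences) < eps
        which = rng.random(spec.n_sequences) < 0.5
        base[consistent & which, i] = a1
        base[consistent & which, j] = b1
        base[consistent & ~which, i] = a2
        base[consistent & ~which, j] = b2

    chars = aa[base]
    if spec.gap_rate > 0:
        gaps = rng.random(chars.shape) < spec.gap_rate
        chars[gaps] = "-"

    records = [
        SequenceRecord(id=f"seq{r:04d}", residues="".join(chars[r]))
        for r in range(spec.n_sequences)
    ]
    truth: dict = {
        "planted_pairs": [(i, j, eps) for i, j, eps in spec.planted_pairs],
        "combinations": {f"{i},{j}": v for (i, j), v in combos.items()},
        "redundant_ids": [],
        "fragment_ids": [],
    }

    n_clusters, within_ident = spec.redundancy_clusters
    extra: list[SequenceRecord] = []
    if n_clusters > 0:
        # each cluster: copies of one base row with just enough substitutions
        # to sit at or above the target within-cluster identity
        n_mut = max(0, int(round(spec.n_columns * (1.0 - within_ident))))
        members = rng.choice(spec.n_sequences, size=n_clusters, replace=False)
        for c, row in enumerate(members):
            for k in range(spec.cluster_size - 1):
                dup = chars[row].copy()
                if n_mut:
                    sites = rng.choice(spec.n_columns, size=n_mut, replace=False)
                    dup[sites] = aa[rng.choice(20, size=n_mut)]
                rid = f"dup{c:02d}_{k}"
                extra.append(SequenceRecord(id=rid, residues="".join(dup)))
                truth["redundant_ids"].append(rid)
            truth.setdefault("cluster_seeds", []).append(f"seq{row:04d}")

    if spec.fragment_fraction > 0:
        n_frag = int(round(spec.fragment_fraction * spec.n_sequences))
        rows = rng.choice(spec.n_sequences, size=n_frag, replace=False)
        for k, row in enumerate(rows):
            frag = chars[row].copy()
            # truncate ~60% of the sequence at a random terminus
            cut = int(0.6 * spec.n_columns)
            if rng.random() < 0.5:
                frag[:cut] = "-"
            else:
                frag[-cut:] = "-"
            fid = f"frag{k:03d}"
            extra.append(SequenceRecord(id=fid, residues="".join(frag)))
            truth["fragment_ids"].append(fid)

    aln = Alignment.from_records(records + extra)
    return aln, truth


@dataclass
class KineticSimSpec:
    """True kinetic parameters and assay design for titration simulation.

    The default concentration grid is 12 points log-spaced over the assay
    range 238 nM to 1 mM.  Noise is additive Gaussian with sd proportional
    to the noiseless rate.
    """

    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"WT": (0.05, 2.0e-7)}
    )  # mutant -> (k_cat s^-1, K_m M)
    concentrations_M: np.ndarray = field(
        default_factory=lambda: np.geomspace(2.38e-7, 1.0e-3, 12)
    )
    noise_sd_rel: float = 0.05
    replicates: int = 3
    seed: int = 0


def simulate_titrations(spec: KineticSimSpec) -> dict[str, KineticDataset]:
    """Michaelis-Menten titrations with multiplicative-scale Gaussian noise."""
    conc = np.asarray(spec.concentrations_M, float)
    if np.any(conc <= 0):
        raise ValueError("concentration grid must be positive")
    rng = np.random.default_rng(spec.seed)
    out: dict[str, KineticDataset] = {}
    for mid, (k_cat, k_m) in spec.params.items():
        obs = []
        for rep in range(spec.replicates):
            clean = k_cat * conc / (k_m + conc)
            noisy = clean + rng.normal(0.0, spec.noise_sd_rel, conc.size) * clean
            obs.extend(
                (float(c), float(v), f"r{rep}") for c, v in zip(conc, noisy)
            )
        out[mid] = KineticDataset(mutant_id=mid, observations=obs)
    return out


# Ideal-geometry Calpha trace parameters.  The alpha-helix uses radius 2.3 A,
# rise 1.5 A per residue, twist 100 degrees per residue, which gives the
# canonical ~3.8 A spacing of consecutive Calphas.
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
EXTENDED_SPACING = 3.5  # A per residue along a straight strand
COIL_STEP = 3.8  # A per bond in the self-avoiding-ish random walk


def simulate_structure(
    n_residues: int, motif: str = "helix", seed: int = 0
) -> StructureModel:
    """Deterministic Calpha trace: 'helix', 'extended', or 'random-coil'."""
    if n_residues < 2:
        raise ValueError("need at least two residues")
    if motif == "helix":
        t = np.arange(n_residues)
        ang = np.deg2rad(HELIX_TWIST_DEG) * t
        xyz = np.column_stack(
            [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * t]
        )
    elif motif == "extended":
        t = np.arange(n_residues)
        xyz = np.column_stack([EXTENDED_SPACING * t, np.zeros_like(t), np.zeros_like(t)])
    elif motif == "random-coil":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n_residues - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        xyz = np.vstack([[0.0, 0.0, 0.0], np.cumsum(COIL_STEP * steps, axis=0)])
    else:
        raise ValueError(f"unknown motif {motif!r}")
    coords = {i + 1: xyz[i].astype(float) for i in range(n_residues)}
    return StructureModel(coordinates=coords, source_id=f"synthetic-{motif}")


def write_pdb(model: StructureModel, path) -> None:
    """Write a Calpha-only trace in PDB format (synthetic output)."""
    with open(path, "w") as fh:
        for k, (resnum, xyz) in enumerate(sorted(model.coordinates.items()), 1):
            fh.write(
                f"ATOM  {k:5d}  CA  ALA {model.chain}{resnum:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
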