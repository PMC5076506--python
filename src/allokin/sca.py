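"""Statistical coupling analysis (SCA).

Quantifies residue co-evolution in an MSA in statistical energy units (kT*,
set to 1).  The per-column conservation energy measures how far the
amino-acid distribution at a column departs from the family background; the
pairwise coupling energy measures how much that distribution at column i
shifts when the alignment is restricted to sequences carrying the dominant
residue at column j (a perturbation experiment on the alignment).

Energies use a root-sum-square over the 20 amino acids of log probability
ratios.  Writing n for the number of informative rows of the (sub)alignment,
observed probabilities carry a pseudocount lambda = pseudocount_scale / n:

    P_x = (c_x + lambda) / (n + 20 lambda)

and the background is passed through the same transform,
q'_x = (q_x n + lambda) / (n + 20 lambda), so a column whose observed
frequencies equal the background has conservation energy exactly zero.

    dG_stat(i)      = kT* sqrt( sum_x ln^2( P_{x,i} / q'_x ) )
    ddG_stat(i|dj)  = kT* sqrt( sum_x ln^2( P_{x,i|dj} / P_{x,i} ) )

where P_{x,i|dj} is computed on the subalignment of rows whose residue at j
is the most frequent one there.  A perturbation is admissible only when that
subalignment is large enough to estimate frequencies (see SCAParams); pairs
without an admissible direction are masked as missing, never reported as 0.
The reported matrix is the mean of the admissible directions, which makes it
symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from allokin.alignment import MISSING_CODE, Alignment

N_AA = 20


@dataclass(frozen=True)
class SCAParams:
    """Tunable constants of the SCA computation.

    kt: the statistical energy unit kT* (dimensionless, default 1).
    pseudocount_scale: lambda = pseudocount_scale / n_informative per residue.
    min_subalignment_fraction: a perturbation at column j is admissible only
        if the subalignment keeps at least this fraction of all rows.
    min_subalignment_rows: additionally, at least this many rows when the
        alignment itself has that many (ignored for smaller alignments).
    max_gap_fraction: columns gappier than this are excluded outright.
    """

    kt: float = 1.0
    pseudocount_scale: float = 1.0
    min_subalignment_fraction: float = 0.25
    min_subalignment_rows: int = 100
    max_gap_fraction: float = 0.5

    def min_rows_required(self, n_rows: int) -> int:
        req = math.ceil(self.min_subalignment_fraction * n_rows)
        if n_rows >= self.min_subalignment_rows:
            req = max(req, self.min_subalignment_rows)
        return max(req, 1)


@dataclass
class ColumnStats:
    """Amino-acid tally for one alignment column.

    counts: occurrences of each of the 20 amino acids (gaps and 'X' excluded).
    n_effective: number of rows contributing (non-gap, non-ambiguous).
    frequencies: counts / n_effective (zeros if the column is all gap).
    background: family-wide amino-acid frequencies of the parent alignment.
    gap_fraction: fraction of rows not contributing.
    """

    counts: np.ndarray
    n_effective: int
    frequencies: np.ndarray
    background: np.ndarray
    gap_fraction: float

    @property
    def is_informative(self) -> bool:
        return self.n_effective > 0


@dataclass
class CouplingMatrix:
    """Pairwise statistical coupling energies over alignment columns.

    ddg_stat: (L, L) symmetrized coupling energies, NaN where masked.
    ddg_directional: (L, L) raw energies, entry [i, j] = ddG(i | dj).
    dg_stat: (L,) per-column conservation energies, NaN for excluded columns.
    valid: (L, L) bool, True where at least one direction was admissible and
        neither column is excluded.
    column_ok: (L,) bool, False for all-gap or over-gapped columns.
    positions: reference residue number per column (None if unmapped).
    """

    ddg_stat: np.ndarray
    ddg_directional: np.ndarray
    dg_stat: np.ndarray
    valid: np.ndarray
    column_ok: np.ndarray
    positions: list[int | None]
    params: SCAParams = field(default_factory=SCAParams)

    @property
    def n_columns(self) -> int:
        return self.ddg_stat.shape[0]

    def to_tsv(self, path) -> None:
        header = "\t".join(
            str(p) if p is not None else f"col{c}"
            for c, p in enumerate(self.positions)
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for row in self.ddg_stat:
                fh.write("\t".join("" if np.isnan(v) else f"{v:.6f}" for v in row))
                fh.write("\n")


def _counts_matrix(encoded: np.ndarray) -> np.ndarray:
    """Per-column amino-acid counts, shape (L, 20)."""
    n_rows, n_cols = encoded.shape
    counts = np.zeros((n_cols, N_AA), dtype=np.int64)
    for code in range(N_AA):
        counts[:, code] = (encoded == code).sum(axis=0)
    return counts


def _pseudo_probs(counts: np.ndarray, params: SCAParams) -> np.ndarray:
    """Pseudocounted probabilities per column; rows of `counts` are columns."""
    n_eff = counts.sum(axis=1, keepdims=True).astype(float)
    lam = np.where(n_eff > 0, params.pseudocount_scale / np.maximum(n_eff, 1), 0.0)
    return (counts + lam) / (n_eff + N_AA * lam)


def _adjust_background(q: np.ndarray, n_eff: float, params: SCAParams) -> np.ndarray:
    lam = params.pseudocount_scale / n_eff
    return (q * n_eff + lam) / (n_eff + N_AA * lam)


def background_frequencies(aln: Alignment) -> np.ndarray:
    """Family-wide amino-acid frequencies over all informative cells."""
    encoded = aln.encoded()
    counts = np.array([(encoded == code).sum() for code in range(N_AA)], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no amino acids")
    return counts / total


def column_statistics(aln: Alignment, col: int, background: np.ndarray | None = None) -> ColumnStats:
    """Tally one column.  All-gap columns return zero frequencies and are
    flagged uninformative (and excluded from coupling downstream)."""
    column = aln.column(col)  # raises IndexError when out of range
    if background is None:
        background = background_frequencies(aln)
    encoded_col = aln.encoded()[:, col]
    counts = np.array([(encoded_col == code).sum() for code in range(N_AA)])
    n_eff = int(counts.sum())
    freqs = counts / n_eff if n_eff > 0 else np.zeros(N_AA)
    return ColumnStats(
        counts=counts,
        n_effective=n_eff,
        frequencies=freqs,
        background=background,
        gap_fraction=1.0 - n_eff / aln.n_rows,
    )


def conservation_energy(stats: ColumnStats, params: SCAParams | None = None) -> float:
    """Per-column statistical energy: departure from background, in kT*."""
    params = params or SCAParams()
    if not stats.is_informative:
        raise ValueError("conservation energy undefined for an all-gap column")
    p = _pseudo_probs(stats.counts[None, :], params)[0]
    q = _adjust_background(stats.background, stats.n_effective, params)
    return float(params.kt * np.sqrt(np.sum(np.log(p / q) ** 2)))


def _directional_energies(
    encoded: np.ndarray, params: SCAParams, perturb_cols=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All perturbation energies at once.

    Returns (E, admissible_perturbation, column_ok) where E[i, j] is
    ddG(i | dj) in kT*, NaN when the perturbation at j is inadmissible or a
    column is excluded.  ``perturb_cols`` restricts which columns j are
    perturbed (others stay NaN).
    """
    n_rows, n_cols = encoded.shape
    counts = _counts_matrix(encoded)  # (L, 20)
    n_eff = counts.sum(axis=1)
    column_ok = (n_eff / n_rows) >= (1.0 - params.max_gap_fraction)
    column_ok &= n_eff > 0

    p_full = _pseudo_probs(counts, params)  # (L, 20)
    min_rows = params.min_rows_required(n_rows)

    energies = np.full((n_cols, n_cols), np.nan)
    admissible = np.zeros(n_cols, dtype=bool)
    columns = range(n_cols) if perturb_cols is None else perturb_cols
    for j in columns:
        if not column_ok[j]:
            continue
        # dominant residue at j; ties broken toward the lower amino-acid code
        dom = int(np.argmax(counts[j]))
        mask = encoded[:, j] == dom
        n_sub = int(mask.sum())
        if n_sub < min_rows:
            continue
        admissible[j] = True
        sub_counts = _counts_matrix(encoded[mask])  # (L, 20)
        p_sub = _pseudo_probs(sub_counts, params)
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.log(p_sub / p_full)
        e = params.kt * np.sqrt(np.nansum(logratio**2, axis=1))
        e[~column_ok] = np.nan
        # columns that are all-gap inside the subalignment are inestimable
        e[sub_counts.sum(axis=1) == 0] = np.nan
        energies[:, j] = e
    return energies, admissible, column_ok


def coupling_energy(
    aln: Alignment, i: int, j: int, params: SCAParams | None = None
) -> float:
    """Symmetrized coupling energy between columns i and j, in kT*.

    Raises ValueError when neither perturbation direction is admissible.
    """
    if i == j:
        raise ValueError("coupling energy requires two distinct columns")
    params = params or SCAParams()
    directional, _, _ = _directional_energies(
        aln.encoded(), params, perturb_cols=(i, j)
    )
    both = np.array([directional[i, j], directional[j, i]])
    if np.isnan(both).all():
        raise ValueError(
            f"no admissible perturbation for columns {i}, {j} "
            "(subalignment too small or column over-gapped)"
        )
    return float(np.nanmean(both))


def coupling_matrix(aln: Alignment, params: SCAParams | None = None) -> CouplingMatrix:
    """Full symmetric coupling matrix with validity mask.

    Deterministic for fixed input; invariant to row order.  Pairs whose
    perturbations are both inadmissible are masked (NaN + valid False).
    """
    params = params or SCAParams()
    encoded = aln.encoded()
    directional, admissible, column_ok = _directional_energies(encoded, params)

    # mean of admissible directions; NaN when neither is admissible
    fwd, rev = directional, directional.T
    n_ok = (~np.isnan(fwd)).astype(int) + (~np.isnan(rev)).astype(int)
    total = np.nan_to_num(fwd) + np.nan_to_num(rev)
    with np.errstate(invalid="ignore"):
        sym = np.where(n_ok > 0, total / np.maximum(n_ok, 1), np.nan)
    valid = ~np.isnan(sym)
    np.fill_diagonal(valid, False)
    np.fill_diagonal(sym, np.nan)

    q = background_frequencies(aln)
    counts = _counts_matrix(encoded)
    dg = np.full(aln.n_columns, np.nan)
    for c in range(aln.n_columns):
        if column_ok[c]:
            stats = ColumnStats(
                counts=counts[c],
                n_effective=int(counts[c].sum()),
                frequencies=counts[c] / counts[c].sum(),
                background=q,
                gap_fraction=1.0 - counts[c].sum() / aln.n_rows,
            )
            dg[c] = conservation_energy(stats, params)

    return CouplingMatrix(
        ddg_stat=sym,
        ddg_directional=directional,
        dg_stat=dg,
        valid=valid,
        column_ok=column_ok,
        positions=list(aln.column_map),
        params=params,
    )


def extract_sectors(
    cm: CouplingMatrix, threshold: float = 1.0, k_sectors: int = 3
) -> dict[int, dict]:
    """Cluster supra-threshold network positions into sectors.

    Positions with at least one valid coupling >= threshold enter the network;
    they are clustered by average-linkage agglomeration on the distance
    1 - ddG/max(ddG) (couplings below threshold or masked count as distance 1).
    A position is flagged co-sector when it has a supra-threshold coupling to
    a position assigned to a different sector.

    Returns {column_index: {"sector": int, "co_sector": bool, "position": ref
    number or None}}.
    """
    supra = cm.valid & (np.nan_to_num(cm.ddg_stat, nan=-np.inf) >= threshold)
    members = np.where(supra.any(axis=1))[0]
    if len(members) < k_sectors:
        raise ValueError(
            f"only {len(members)} network positions but {k_sectors} sectors requested"
        )
    sub = cm.ddg_stat[np.ix_(members, members)].copy()
    sub_supra = supra[np.ix_(members, members)]
    sub[~sub_supra] = 0.0
    peak = np.nanmax(sub)
    if peak <= 0:
        raise ValueError("degenerate coupling submatrix")
    dist = 1.0 - sub / peak
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k_sectors, criterion="maxclust") - 1

    out: dict[int, dict] = {}
    for local, col in enumerate(members):
        partners = np.where(sub_supra[local])[0]
        co = any(labels[p] != labels[local] for p in partners)
        out[int(col)] = {
            "sector": int(labels[local]),
            "co_sector": bool(co),
            "position": cm.positions[col],
        }
    return out
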