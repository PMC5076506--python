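"""SCA energies: column statistics, conservation, coupling, sectors.

The longhand oracle re-derives the documented energy formulas with plain
Python loops, independently of the vectorized implementation.
"""

import math

import numpy as np
import pytest

from allokin.alignment import Alignment
from allokin.curation import AMINO_ACIDS, SequenceRecord
from allokin.sca import (
    CouplingMatrix,
    SCAParams,
    background_frequencies,
    column_statistics,
    conservation_energy,
    coupling_energy,
    coupling_matrix,
    extract_sectors,
)
from allokin.simulate import MSASimSpec, simulate_msa

AAI = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def aln_from(rows, **kw):
    return Alignment.from_records(
        [SequenceRecord(id=f"r{i}", residues=s) for i, s in enumerate(rows)], **kw
    )


# ---------------------------------------------------------------- oracle


def oracle_probs(column, background_lambda_n):
    """Pseudocounted amino-acid probabilities of one column string."""
    informative = [c for c in column if c in AAI]
    n = len(informative)
    lam = 1.0 / n
    probs = []
    for aa in AMINO_ACIDS:
        c = informative.count(aa)
        probs.append((c + lam) / (n + 20 * lam))
    return probs, n


def oracle_conservation(column, q):
    probs, n = oracle_probs(column, None)
    lam = 1.0 / n
    total = 0.0
    for p, qx in zip(probs, q):
        q_adj = (qx * n + lam) / (n + 20 * lam)
        total += math.log(p / q_adj) ** 2
    return math.sqrt(total)


def oracle_coupling(rows, i, j):
    """Symmetrized ddG(i,j) by direct enumeration over the two directions."""

    def direction(target, perturbed):
        col_p = [r[perturbed] for r in rows]
        counts = {aa: col_p.count(aa) for aa in AMINO_ACIDS}
        dom = max(AMINO_ACIDS, key=lambda aa: counts[aa])  # low index wins ties
        sub = [r for r in rows if r[perturbed] == dom]
        full_col = [r[target] for r in rows]
        sub_col = [r[target] for r in sub]
        if not any(c in AAI for c in sub_col):
            return None, len(sub)
        p_full, _ = oracle_probs(full_col, None)
        p_sub, _ = oracle_probs(sub_col, None)
        total = sum(math.log(ps / pf) ** 2 for ps, pf in zip(p_sub, p_full))
        return math.sqrt(total), len(sub)

    params = SCAParams()
    n = len(rows)
    vals = []
    for t, p in ((i, j), (j, i)):
        e, n_sub = direction(t, p)
        if e is not None and n_sub >= params.min_rows_required(n):
            vals.append(e)
    return sum(vals) / len(vals) if vals else None


# ------------------------------------------------------------- unit tests


class TestColumnStatistics:
    def test_uniform_column(self):
        aln = aln_from(["G"] * 100)
        stats = column_statistics(aln, 0)
        assert stats.frequencies[AAI["G"]] == 1.0
        assert stats.n_effective == 100

    def test_fifty_fifty(self):
        aln = aln_from(["A"] * 50 + ["V"] * 50)
        stats = column_statistics(aln, 0)
        assert stats.frequencies[AAI["A"]] == pytest.approx(0.5)
        assert stats.frequencies[AAI["V"]] == pytest.approx(0.5)

    def test_random_column_matches_hand_tally(self, rng):
        letters = rng.choice(list(AMINO_ACIDS), 60)
        aln = aln_from(["".join(letters[k] for _ in range(1)) for k in range(60)])
        stats = column_statistics(aln, 0)
        for aa in AMINO_ACIDS:
            assert stats.counts[AAI[aa]] == list(letters).count(aa)

    def test_gaps_excluded_from_normalization(self):
        aln = aln_from(["A", "A", "-", "-"])
        stats = column_statistics(aln, 0)
        assert stats.n_effective == 2
        assert stats.gap_fraction == pytest.approx(0.5)
        assert stats.frequencies.sum() == pytest.approx(1.0)

    def test_all_gap_column_flagged(self):
        aln = aln_from(["-A", "-C"])
        stats = column_statistics(aln, 0)
        assert not stats.is_informative
        with pytest.raises(ValueError):
            conservation_energy(stats)


class TestConservationEnergy:
    def test_zero_when_frequencies_equal_background(self):
        # 20 rows, one of each amino acid; background is uniform by construction
        aln = aln_from([aa for aa in AMINO_ACIDS])
        stats = column_statistics(aln, 0)
        assert conservation_energy(stats) == pytest.approx(0.0, abs=1e-12)

    def test_conserved_rare_residue_scores_higher_than_common(self):
        # family where W is rare and A common; both test columns fully conserved
        rows = ["AW" + "A" * 8] * 9 + ["AW" + "W" * 8]
        aln = aln_from(rows)
        q = background_frequencies(aln)
        e_common = conservation_energy(column_statistics(aln, 0, q))  # all A
        e_rare = conservation_energy(column_statistics(aln, 1, q))  # all W
        assert q[AAI["W"]] < q[AAI["A"]]
        assert e_rare > e_common

    def test_matches_longhand_on_tiny_alignment(self):
        rows = ["ACD", "ACD", "AVD", "GCD", "ACE"]
        aln = aln_from(rows)
        q = background_frequencies(aln)
        for col in range(3):
            expected = oracle_conservation([r[col] for r in rows], list(q))
            got = conservation_energy(column_statistics(aln, col, q))
            assert got == pytest.approx(expected, rel=1e-12)


class TestCouplingEnergy:
    def test_perfect_covariation_beats_independent_pairs(self, rng):
        # columns 0,1 perfectly covary (two compatible combinations);
        # columns 2,3 independent uniform draws
        n = 400
        rows = []
        for k in range(n):
            combo = ("A", "W") if k % 2 == 0 else ("V", "D")
            rows.append(
                combo[0] + combo[1]
                + "".join(rng.choice(list(AMINO_ACIDS), 2))
            )
        aln = aln_from(rows)
        coupled = coupling_energy(aln, 0, 1)
        independent = coupling_energy(aln, 0, 2)
        assert coupled > independent

    def test_independent_columns_give_small_energy(self):
        # both columns conserved and independent: subalignment = full rows
        aln = aln_from(["AC"] * 200)
        assert coupling_energy(aln, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_inadmissible_perturbation_raises_never_zero(self):
        # 4 rows, dominant residue at col 1 present once: below the 25% x 4 = 1
        # requirement is impossible, so force it via params by gapping
        aln = aln_from(["A-", "AC", "AD", "AE"])
        # column 1 dominant 'C' subalignment has 1 row -> admissible at n=4?
        # min_rows_required(4) = 1, so instead use an over-gapped column
        aln2 = aln_from(["A-", "A-", "A-", "AC"])
        with pytest.raises(ValueError):
            coupling_energy(aln2, 0, 1)  # col 1 is 75% gaps -> excluded

    def test_planted_pairs_rank_above_background(self, small_planted_msa):
        aln, truth = small_planted_msa
        cm = coupling_matrix(aln)
        i, j, _ = truth["planted_pairs"][0]
        planted = cm.ddg_stat[i, j]
        iu = np.triu_indices(cm.n_columns, 1)
        others = [
            v
            for a, b, v in zip(*iu, cm.ddg_stat[iu])
            if {a, b} != {i, j} and np.isfinite(v)
        ]
        assert planted > np.percentile(others, 95)


class TestCouplingMatrix:
    def test_two_column_toy(self):
        rows = ["AW"] * 6 + ["VD"] * 6
        aln = aln_from(rows)
        cm = coupling_matrix(aln)
        assert cm.ddg_stat.shape == (2, 2)
        assert cm.valid[0, 1]
        assert cm.ddg_stat[0, 1] == pytest.approx(coupling_energy(aln, 0, 1))

    def test_row_permutation_invariance(self, rng, small_planted_msa):
        aln, _ = small_planted_msa
        cm1 = coupling_matrix(aln)
        perm = rng.permutation(aln.n_rows)
        shuffled = Alignment.from_records([aln.records[p] for p in perm])
        cm2 = coupling_matrix(shuffled)
        np.testing.assert_allclose(cm1.ddg_stat, cm2.ddg_stat, equal_nan=True)

    def test_symmetry_and_nonnegativity(self, small_planted_msa):
        aln, _ = small_planted_msa
        cm = coupling_matrix(aln)
        np.testing.assert_allclose(cm.ddg_stat, cm.ddg_stat.T, equal_nan=True)
        finite = cm.ddg_stat[np.isfinite(cm.ddg_stat)]
        assert (finite >= 0).all()

    def test_matches_longhand_oracle_on_small_alignments(self, rng):
        """<=10 rows x <=6 columns: every entry equals the longhand value."""
        for trial in range(8):
            n_rows = int(rng.integers(4, 11))
            n_cols = int(rng.integers(2, 7))
            rows = [
                "".join(rng.choice(list("ACDWY"), n_cols)) for _ in range(n_rows)
            ]
            aln = aln_from(rows)
            cm = coupling_matrix(aln)
            for i in range(n_cols):
                for j in range(i + 1, n_cols):
                    expected = oracle_coupling(rows, i, j)
                    if expected is None:
                        assert not cm.valid[i, j]
                    else:
                        assert cm.ddg_stat[i, j] == pytest.approx(
                            expected, rel=1e-12
                        ), (rows, i, j)

    def test_false_positive_rate_under_independence(self):
        """eps=0 at N=700: under 5% of pairs reach 1.0 kT*."""
        aln, _ = simulate_msa(
            MSASimSpec(n_sequences=700, n_columns=60, planted_pairs=[], seed=7)
        )
        cm = coupling_matrix(aln)
        iu = np.triu_indices(60, 1)
        vals = np.nan_to_num(cm.ddg_stat[iu], nan=0.0)
        assert np.mean(vals >= 1.0) < 0.05


class TestExtractSectors:
    @staticmethod
    def block_matrix(blocks, noise=0.1):
        """CouplingMatrix with planted block-diagonal structure."""
        n = sum(len(b) for b in blocks)
        m = np.full((n, n), noise)
        for block in blocks:
            for a in block:
                for b in block:
                    if a != b:
                        m[a, b] = 2.0
        np.fill_diagonal(m, np.nan)
        valid = np.ones((n, n), bool)
        np.fill_diagonal(valid, False)
        return CouplingMatrix(
            ddg_stat=m,
            ddg_directional=m.copy(),
            dg_stat=np.ones(n),
            valid=valid,
            column_ok=np.ones(n, bool),
            positions=[None] * n,
        )

    def test_three_planted_blocks_recovered_exactly(self):
        blocks = [list(range(0, 5)), list(range(5, 9)), list(range(9, 14))]
        cm = self.block_matrix(blocks)
        sectors = extract_sectors(cm, threshold=1.0, k_sectors=3)
        labels = [sectors[c]["sector"] for c in range(14)]
        for block in blocks:
            assert len({labels[c] for c in block}) == 1
        assert len(set(labels)) == 3
        assert not any(sectors[c]["co_sector"] for c in sectors)

    def test_single_clique_single_sector(self):
        cm = self.block_matrix([list(range(6))])
        sectors = extract_sectors(cm, threshold=1.0, k_sectors=1)
        assert {v["sector"] for v in sectors.values()} == {0}

    def test_too_few_positions_errors(self):
        cm = self.block_matrix([[0, 1]])
        with pytest.raises(ValueError):
            extract_sectors(cm, threshold=1.0, k_sectors=3)

    def test_cross_sector_coupling_flagged(self):
        blocks = [list(range(0, 4)), list(range(4, 8)), list(range(8, 12))]
        cm = self.block_matrix(blocks)
        cm.ddg_stat[0, 4] = cm.ddg_stat[4, 0] = 1.5  # bridge two sectors
        sectors = extract_sectors(cm, threshold=1.0, k_sectors=3)
        assert sectors[0]["co_sector"] and sectors[4]["co_sector"]
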