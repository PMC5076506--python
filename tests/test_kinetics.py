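"""Michaelis-Menten fitting and double-mutant-cycle thermodynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allokin.kinetics import (
    KineticDataset,
    MutantCycle,
    additivity_offset,
    classify_epistasis,
    coupling_energy_therm,
    ddg_of_mutation,
    fit_michaelis_menten,
)
from allokin.simulate import KineticSimSpec, simulate_titrations

finite = st.floats(-5, 5, allow_nan=False)


def dataset(k_cat, k_m, noise=0.0, seed=0, replicates=1):
    spec = KineticSimSpec(
        params={"m": (k_cat, k_m)},
        noise_sd_rel=noise,
        replicates=replicates,
        seed=seed,
    )
    return simulate_titrations(spec)["m"]


class TestMichaelisMentenFit:
    def test_noiseless_exact_recovery(self):
        fit = fit_michaelis_menten(dataset(0.05, 2.0e-7))
        assert fit.k_cat == pytest.approx(0.05, rel=1e-8)
        assert fit.k_m == pytest.approx(2.0e-7, rel=1e-8)
        assert fit.efficiency == pytest.approx(fit.k_cat / fit.k_m)

    @pytest.mark.parametrize(
        "k_cat, k_m",
        [(0.004, 1.0e-3), (0.5, 2.0e-7), (0.05, 1.0e-5)],
    )
    def test_round_trip_across_parameter_scales(self, k_cat, k_m):
        """Noiseless generate-and-refit over the assayed kinetic range."""
        fit = fit_michaelis_menten(dataset(k_cat, k_m))
        assert fit.k_cat == pytest.approx(k_cat, rel=1e-6)
        assert fit.k_m == pytest.approx(k_m, rel=1e-6)

    def test_median_error_under_noise(self):
        """5% noise, 12 concentrations: k_cat median relative error < 5%.

        Condensed simulation study (80 draws here; the acceptance script
        runs the full 500)."""
        errors = []
        for seed in range(80):
            fit = fit_michaelis_menten(dataset(0.05, 2.0e-7, noise=0.05, seed=seed))
            errors.append(abs(fit.k_cat - 0.05) / 0.05)
        assert np.median(errors) < 0.05

    def test_standard_errors_reported(self):
        fit = fit_michaelis_menten(dataset(0.05, 2.0e-7, noise=0.05, seed=1))
        assert fit.k_cat_se > 0 and fit.k_m_se > 0

    def test_all_zero_rates_fail_explicitly(self):
        obs = [(c, 0.0, "r0") for c in np.geomspace(1e-7, 1e-3, 6)]
        ds = KineticDataset(mutant_id="dead", observations=obs)
        with pytest.raises(RuntimeError):
            fit_michaelis_menten(ds)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            KineticDataset(
                mutant_id="x", observations=[(1e-6, 0.01, "r0")] * 4
            )

    def test_replicates_averaged_before_fit(self):
        ds = dataset(0.05, 2.0e-7, noise=0.05, seed=3, replicates=5)
        fit_avg = fit_michaelis_menten(ds, average_replicates=True)
        assert fit_avg.n_points == 12


class TestDdgOfMutation:
    def test_equal_efficiencies_give_zero(self):
        assert ddg_of_mutation(1e5, 1e5) == 0.0

    def test_facilitating_mutation_value(self):
        """A 6.4-fold efficiency gain is -1.1 kcal/mol at 298 K."""
        assert ddg_of_mutation(1.6e6, 2.5e5) == pytest.approx(-1.1, abs=0.05)

    def test_mildly_impairing_double_mutant_value(self):
        assert ddg_of_mutation(1.8e5, 2.5e5) == pytest.approx(0.2, abs=0.05)

    def test_nonpositive_efficiency_rejected(self):
        with pytest.raises(ValueError):
            ddg_of_mutation(0.0, 1e5)

    @given(
        a=st.floats(1e2, 1e7),
        b=st.floats(1e2, 1e7),
    )
    def test_antisymmetry(self, a, b):
        assert ddg_of_mutation(a, b) == pytest.approx(-ddg_of_mutation(b, a), abs=1e-12)


class TestCouplingEnergyTherm:
    @pytest.mark.parametrize(
        "ddg1, ddg2, ddg12, expected",
        [(1.0, 1.0, 2.0, 0.0), (-1.0, 0.5, -2.5, 2.0)],
    )
    def test_arithmetic(self, ddg1, ddg2, ddg12, expected):
        assert coupling_energy_therm(ddg1, ddg2, ddg12) == pytest.approx(expected)

    @given(a=finite, b=finite, c=finite)
    def test_swap_invariance(self, a, b, c):
        assert coupling_energy_therm(a, b, c) == coupling_energy_therm(b, a, c)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            coupling_energy_therm(float("inf"), 0.0, 0.0)


def cycle(d1, d2, d12):
    return MutantCycle(pair_id="p", ddg_m1=d1, ddg_m2=d2, ddg_m1m2=d12)


class TestClassifyEpistasis:
    def test_small_ce_is_additive(self):
        # a 0.89 kcal/mol coupling energy is within experimental additivity
        c = cycle(2.0, 1.5, 2.61)
        assert c.ce_therm == pytest.approx(0.89)
        assert classify_epistasis(c) == "additive"

    def test_cooperative_nonadditive_is_antagonistic(self):
        # double effect below the larger single, away from either single:
        # the mutations counteract each other
        c = cycle(3.0, 3.0, 1.5)
        assert classify_epistasis(c) == "antagonistic"

    def test_double_exceeding_singles_is_synergistic(self):
        c = cycle(1.0, 1.0, 3.5)
        assert classify_epistasis(c) == "synergistic"

    def test_no_additional_effect(self):
        # double effect sits on one single's effect
        c = cycle(4.0, 2.0, 4.1)
        assert classify_epistasis(c) == "no-additional-effect"

    def test_partially_additive(self):
        # double between the larger single and the sum, same sign
        c = cycle(3.0, 2.6, 4.2)
        assert classify_epistasis(c) == "partially additive"

    def test_bound_is_configurable(self):
        c = cycle(2.0, 1.5, 2.2)  # ce = 1.3
        assert classify_epistasis(c, additivity_bound=1.0) != "additive"
        assert classify_epistasis(c, additivity_bound=1.5) == "additive"


class TestAdditivityOffset:
    def test_zero_offset_for_additive_cycles(self, rng):
        cycles = [
            cycle(a, b, a + b)
            for a, b in rng.normal(1.0, 0.5, size=(6, 2))
        ]
        fit = additivity_offset(cycles)
        assert fit.offset == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered_exactly(self, rng):
        cycles = [
            cycle(a, b, a + b - 1.7)
            for a, b in rng.normal(2.0, 0.5, size=(5, 2))
        ]
        fit = additivity_offset(cycles)
        assert fit.offset == pytest.approx(1.7, abs=1e-12)

    def test_noisy_offset_within_confidence_interval(self, rng):
        true = 2.0
        cycles = [
            cycle(a, b, a + b - true - float(rng.normal(0, 0.3)))
            for a, b in rng.normal(2.0, 1.0, size=(6, 2))
        ]
        fit = additivity_offset(cycles)
        lo, hi = fit.ci95
        assert lo <= true <= hi
        assert abs(fit.free_slope - 1.0) < 0.5  # diagnostic stays near unity

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(ValueError):
            additivity_offset([cycle(1, 1, 2)])


class TestCycleRoundTrip:
    def test_additive_by_construction_gives_zero_ce(self):
        """Titrations generated so efficiencies multiply: CE_therm ~ 0."""
        eff_wt, f1, f2 = 2.5e5, 0.3, 0.5
        k_m = 2.0e-7
        params = {
            "WT": (eff_wt * k_m, k_m),
            "M1": (eff_wt * f1 * k_m, k_m),
            "M2": (eff_wt * f2 * k_m, k_m),
            "M1M2": (eff_wt * f1 * f2 * k_m, k_m),
        }
        spec = KineticSimSpec(params=params, noise_sd_rel=0.0, replicates=1)
        fits = {
            mid: fit_michaelis_menten(ds)
            for mid, ds in simulate_titrations(spec).items()
        }
        wt = fits["WT"].efficiency
        ddg1 = ddg_of_mutation(fits["M1"].efficiency, wt)
        ddg2 = ddg_of_mutation(fits["M2"].efficiency, wt)
        ddg12 = ddg_of_mutation(fits["M1M2"].efficiency, wt)
        assert coupling_energy_therm(ddg1, ddg2, ddg12) == pytest.approx(0.0, abs=1e-6)
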