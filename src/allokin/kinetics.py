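"""Steady-state kinetics and double-mutant-cycle thermodynamics.

The ATPase titration of each construct is fit to the Michaelis-Menten form

    v([S]) = k_cat [S] / (K_m + [S])

by bounded non-linear least squares, giving k_cat (s^-1), K_m (M) and the
catalytic efficiency k_cat/K_m (M^-1 s^-1).  Efficiency ratios convert to
free energies of mutation,

    ddG_M = -R T ln( (k_cat/K_m)_mut / (k_cat/K_m)_wt )    [kcal/mol],

negative for a facilitating mutation.  For a residue pair probed with single
mutants M1, M2 and the double M1M2, the thermodynamic coupling energy is

    CE_therm = ddG_M1 + ddG_M2 - ddG_M1M2,

zero for energetically independent residues.  |CE_therm| below the
additivity bound (default 1.0 kcal/mol, configurable up to 1.5) is classed
additive; non-additive cycles are subdivided by comparing ddG_M1M2 against
the single-mutant effects (see ``classify_epistasis``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_ADDITIVITY_BOUND = 1.0  # kcal/mol

EPISTASIS_CLASSES = (
    "additive",
    "partially additive",
    "antagonistic",
    "no-additional-effect",
    "synergistic",
)


@dataclass
class KineticDataset:
    """ATPase titration for one construct.

    observations: (concentration_M, rate_per_s, replicate_id) triples.
    """

    mutant_id: str
    observations: list[tuple[float, float, str]]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _, _ in self.observations):
            raise ValueError(f"{self.mutant_id}: substrate concentrations must be > 0")
        if len({c for c, _, _ in self.observations}) < 5:
            raise ValueError(
                f"{self.mutant_id}: need >= 5 distinct concentrations for fitting"
            )

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-averaged (concentration, rate) arrays, sorted by conc."""
        df = pd.DataFrame(self.observations, columns=["conc", "rate", "rep"])
        agg = df.groupby("conc", sort=True)["rate"].mean()
        return agg.index.to_numpy(float), agg.to_numpy(float)

    def all_points(self) -> tuple[np.ndarray, np.ndarray]:
        conc = np.array([c for c, _, _ in self.observations], float)
        rate = np.array([r for _, r, _ in self.observations], float)
        order = np.argsort(conc)
        return conc[order], rate[order]


@dataclass
class KineticFit:
    mutant_id: str
    k_cat: float  # s^-1
    k_cat_se: float
    k_m: float  # M
    k_m_se: float
    n_points: int
    rss: float
    converged: bool = True

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency (specificity constant) k_cat/K_m, M^-1 s^-1."""
        return self.k_cat / self.k_m


def _mm(s: np.ndarray, k_cat: float, k_m: float) -> np.ndarray:
    return k_cat * s / (k_m + s)


def fit_michaelis_menten(
    data: KineticDataset, average_replicates: bool = True
) -> KineticFit:
    """Bounded least-squares Michaelis-Menten fit.

    Replicates are averaged per concentration by default.  Initial values:
    k_cat0 = max observed rate, K_m0 = concentration nearest half-max; on
    failure a log-spaced K_m grid restart is tried.  Positivity is enforced
    through bounds.  Non-convergence and all-zero rates raise RuntimeError
    with diagnostics.
    """
    conc, rate = data.averaged() if average_replicates else data.all_points()
    vmax = float(rate.max(initial=0.0))
    if vmax <= 0:
        raise RuntimeError(f"{data.mutant_id}: rates are all <= 0; nothing to fit")

    half = vmax / 2.0
    km0 = float(conc[int(np.argmin(np.abs(rate - half)))])
    starts = [(vmax, km0)] + [(vmax, g) for g in np.geomspace(conc.min(), conc.max(), 5)]
    last_err: Exception | None = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _mm,
                conc,
                rate,
                p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            perr = np.sqrt(np.diag(pcov))
            resid = rate - _mm(conc, *popt)
            return KineticFit(
                mutant_id=data.mutant_id,
                k_cat=float(popt[0]),
                k_cat_se=float(perr[0]),
                k_m=float(popt[1]),
                k_m_se=float(perr[1]),
                n_points=len(conc),
                rss=float(resid @ resid),
            )
        except RuntimeError as err:  # curve_fit non-convergence
            last_err = err
    raise RuntimeError(
        f"{data.mutant_id}: Michaelis-Menten fit failed after grid restarts "
        f"({last_err})"
    )


def ddg_of_mutation(
    eff_mut: float, eff_wt: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Free-energy change of mutation from catalytic efficiencies, kcal/mol.

    ddG = -R T ln(eff_mut / eff_wt); negative means the mutation lowered the
    free-energy barrier for catalysis relative to wild type.
    """
    if eff_mut <= 0 or eff_wt <= 0:
        raise ValueError("catalytic efficiencies must be positive")
    return -R_KCAL * temperature * math.log(eff_mut / eff_wt)


def coupling_energy_therm(ddg1: float, ddg2: float, ddg12: float) -> float:
    """Double-mutant-cycle coupling energy: ddG1 + ddG2 - ddG12, kcal/mol."""
    for v in (ddg1, ddg2, ddg12):
        if not math.isfinite(v):
            raise ValueError("ddG values must be finite")
    return ddg1 + ddg2 - ddg12


@dataclass
class MutantCycle:
    """One double-mutant cycle: wild type, two singles, and the double."""

    pair_id: str
    ddg_m1: float
    ddg_m2: float
    ddg_m1m2: float
    fits: dict[str, KineticFit] = field(default_factory=dict)
    distance_A: float | None = None

    @property
    def ce_therm(self) -> float:
        return coupling_energy_therm(self.ddg_m1, self.ddg_m2, self.ddg_m1m2)


def classify_epistasis(
    cycle: MutantCycle, additivity_bound: float = DEFAULT_ADDITIVITY_BOUND
) -> str:
    """Deterministic epistasis label for a completed cycle.

    With s = ddG_M1 + ddG_M2 and d = ddG_M1M2, the rules are applied in
    order:

    1. additive                 |s - d| < bound
    2. synergistic              |d| > |s| (the double exceeds the summed
                                singles)
    3. no-additional-effect     d is within bound of one single's effect
    4. partially additive       d between the larger single effect and the
                                sum (same sign as the sum)
    5. antagonistic             remaining non-additive cycles (cooperative:
                                sum of singles exceeds the double effect)
    """
    s = cycle.ddg_m1 + cycle.ddg_m2
    d = cycle.ddg_m1m2
    if abs(s - d) < additivity_bound:
        return "additive"
    if abs(d) > abs(s):
        return "synergistic"
    if min(abs(d - cycle.ddg_m1), abs(d - cycle.ddg_m2)) < additivity_bound:
        return "no-additional-effect"
    larger = max(abs(cycle.ddg_m1), abs(cycle.ddg_m2))
    if math.copysign(1.0, d) == math.copysign(1.0, s) and abs(d) > larger:
        return "partially additive"
    return "antagonistic"


@dataclass
class AdditivityFit:
    """Fixed-slope-1 fit of (ddG_M1 + ddG_M2) = ddG_M1M2 + offset."""

    offset: float  # kcal/mol; equals the mean CE_therm
    offset_se: float
    ci95: tuple[float, float]
    n: int
    free_slope: float
    free_intercept: float
    free_r: float


def additivity_offset(cycles: list[MutantCycle]) -> AdditivityFit:
    """Least-squares offset between summed-single and double ddG values.

    With the slope fixed at 1, the offset is the mean of CE_therm over the
    cycles; its 95% CI uses the t distribution.  A free-slope ordinary
    regression of (ddG1+ddG2) on ddG12 is reported as a diagnostic.
    """
    if len(cycles) < 2:
        raise ValueError("additivity_offset needs at least two cycles")
    ce = np.array([c.ce_therm for c in cycles], float)
    s = np.array([c.ddg_m1 + c.ddg_m2 for c in cycles], float)
    d = np.array([c.ddg_m1m2 for c in cycles], float)
    offset = float(ce.mean())
    se = float(ce.std(ddof=1) / math.sqrt(len(ce)))
    if se > 0:
        tcrit = stats.t.ppf(0.975, len(ce) - 1)
        ci = (offset - tcrit * se, offset + tcrit * se)
    else:
        ci = (offset, offset)
    if np.ptp(d) > 0:
        lr = stats.linregress(d, s)
        free = (float(lr.slope), float(lr.intercept), float(lr.rvalue))
    else:
        free = (float("nan"), float("nan"), float("nan"))
    return AdditivityFit(
        offset=offset,
        offset_se=se,
        ci95=ci,
        n=len(ce),
        free_slope=free[0],
        free_intercept=free[1],
        free_r=free[2],
    )


def read_titrations(path) -> dict[str, KineticDataset]:
    """Load a titration CSV (mutant, conc_M, rate_per_s, replicate)."""
    df = pd.read_csv(path)
    required = {"mutant", "conc_M", "rate_per_s", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    out = {}
    for mid, grp in df.groupby("mutant"):
        out[str(mid)] = KineticDataset(
            mutant_id=str(mid),
            observations=[
                (float(r.conc_M), float(r.rate_per_s), str(r.replicate))
                for r in grp.itertuples()
            ],
        )
    return out


def run_cycles(
    datasets: dict[str, KineticDataset],
    manifest: list[dict],
    temperature: float = DEFAULT_TEMPERATURE,
    additivity_bound: float = DEFAULT_ADDITIVITY_BOUND,
) -> pd.DataFrame:
    """Fit every construct and evaluate each cycle in the manifest.

    ``manifest`` rows need keys wt, m1, m2, m1m2 (construct ids present in
    ``datasets``) and may carry pair_id and distance_A.
    """
    fits = {mid: fit_michaelis_menten(ds) for mid, ds in datasets.items()}
    rows = []
    for entry in manifest:
        wt, m1, m2, m12 = (entry[k] for k in ("wt", "m1", "m2", "m1m2"))
        eff_wt = fits[wt].efficiency
        ddg1 = ddg_of_mutation(fits[m1].efficiency, eff_wt, temperature)
        ddg2 = ddg_of_mutation(fits[m2].efficiency, eff_wt, temperature)
        ddg12 = ddg_of_mutation(fits[m12].efficiency, eff_wt, temperature)
        cycle = MutantCycle(
            pair_id=entry.get("pair_id", f"{m1}/{m2}"),
            ddg_m1=ddg1,
            ddg_m2=ddg2,
            ddg_m1m2=ddg12,
            fits={k: fits[k] for k in (wt, m1, m2, m12)},
            distance_A=entry.get("distance_A"),
        )
        rows.append(
            {
                "pair_id": cycle.pair_id,
                "ddg_m1": ddg1,
                "ddg_m2": ddg2,
                "ddg_m1m2": ddg12,
                "ce_therm": cycle.ce_therm,
                "class": classify_epistasis(cycle, additivity_bound),
                "distance_A": cycle.distance_A,
            }
        )
    return pd.DataFrame(rows)
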