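# allokin

Residue co-evolution and thermodynamic-coupling analysis for kinesin motor
domains — and, more generally, for any protein family where you want to ask:
*which residues are energetically wired together, and does that statistical
wiring hold up thermodynamically?*

Kinesins convert the free energy of ATP hydrolysis into directed motion
along microtubules. The active site and the microtubule-binding site sit on
opposite faces of the motor domain, so catalysis must be allosterically
coupled to mechanics across 20–30 Å. `allokin` implements the two halves of
that investigation:

1. **Statistical coupling analysis (SCA).** Across a curated multiple
   sequence alignment, the conservation energy of column *i* is the
   root-sum-square departure of its amino-acid distribution from the family
   background, ΔG<sub>stat</sub>(i) = kT\*·√Σ<sub>x</sub> ln²(P<sub>x,i</sub>/q<sub>x</sub>).
   Perturbing column *j* — restricting the alignment to sequences carrying
   the dominant residue at *j* — shifts that distribution; the coupling
   energy ΔΔG<sub>stat</sub>(i,j) = kT\*·√Σ<sub>x</sub> ln²(P<sub>x,i|δj</sub>/P<sub>x,i</sub>)
   measures co-evolution. Thresholding the matrix at 1.0 kT\* yields an
   allosteric network with coupling strata (intermediate 1.0–1.39 kT\*, high
   1.4 kT\* and above), per-residue correlation counts, hub residues (≥ 9
   partners), and sectors from average-linkage clustering. Network positions
   map onto Cα coordinates; pairs with d<sub>ij</sub> ≥ 6 Å are *distal* (no
   tertiary contact).

2. **Double-mutant-cycle thermodynamics.** ATPase titrations fit to
   v = k<sub>cat</sub>[S]/(K<sub>m</sub>+[S]); catalytic efficiency
   k<sub>cat</sub>/K<sub>m</sub> converts to a free energy of mutation,
   ΔΔG<sub>M</sub> = −RT·ln(eff<sub>mut</sub>/eff<sub>wt</sub>). For a
   residue pair, CE<sub>therm</sub> = ΔΔG<sub>M1</sub> + ΔΔG<sub>M2</sub> −
   ΔΔG<sub>M1M2</sub> deviates from zero when the two sites are
   thermodynamically coupled; cycles are classified as additive, partially
   additive, antagonistic, no-additional-effect, or synergistic.

A synthetic-data module generates alignments with planted co-varying column
pairs, ideal-geometry Cα traces, and noisy Michaelis–Menten titrations with
known ground truth, so the entire chain is testable without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs (seed fixed in `01_simulate_inputs.py`); outputs land in `results/`.

```sh
python analysis/01_simulate_inputs.py
python analysis/02_curate_sequences.py
python analysis/03_coupling_network.py
python analysis/04_structure_distances.py
python analysis/05_mutant_cycles.py
```

prints

```
alignment: 855 rows x 120 columns (15 injected duplicates, 40 fragments)
...
input 855 -> kept 800 (fragments removed 40, redundant removed 15)
ground truth: 15/15 injected duplicates and 40/40 fragments removed
network: 81 nodes, 171 edges at >=1.0 kT*
planted pairs recovered as edges: 4/4
degree range 1-34, mode 2; hubs (>=9): [5, 20, 33, 45, 60, 70, 90, 110]
...
distal fraction (>=6 A): 0.96
ddG_M1 = +1.28, ddG_M2 = +1.00, ddG_M1M2 = +2.45 kcal/mol
CE_therm = -0.17 kcal/mol -> additive
```

Reading this: curation removed exactly the injected duplicates and
fragments; all four planted co-varying pairs surfaced as supra-threshold
network edges, and the eight planted columns are precisely the eight hub
residues; mapped onto a random-coil trace, 96% of coupled pairs are distal;
and a mutant cycle whose double mutant was simulated with independent
(multiplicative) efficiency effects comes out additive (CE_therm ≈ 0), as it
should.

The same stages are scriptable via the `allokin` CLI (`allokin curate`,
`allokin sca`, `allokin network`, `allokin map-structure`, `allokin cycles`,
`allokin simulate`, `allokin run --config pipeline.yaml`).

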