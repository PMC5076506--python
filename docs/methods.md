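# Methods

## Sequence curation

Curation runs two deterministic filters before any statistics are computed.

**Fragment filter.** A record is fragmentary when its ungapped length falls
below a configurable fraction (default 0.7) of the median ungapped length of
the input set. Truncation at either terminus shortens the chain the same
way, so a single length rule covers both. The fraction is a judgment call —
motor-domain sequences are single-domain and tightly length-distributed, so
0.7 comfortably separates genuine fragments from natural length variation.

**Redundancy pruning.** Sequences are scanned in input order and a record is
kept iff its identity to every already-kept record is at or below the
threshold (default 0.95). First-seen-kept is the whole keep-rule: it is
deterministic, order-dependent by design, and needs no objective function.
When within-cluster identity stays strictly above the threshold for every
pair, the greedy result coincides with one representative per transitive
cluster; for looser clusters the two can differ, which is why the redundancy
tests plant tight clusters.

**Identity conventions.** For pre-aligned rows, identity = matches / number
of columns where neither row has a gap. For unaligned inputs, a global
pairwise alignment (BLOSUM62, gap open −10, extend −0.5) is computed and
identity = matches / total alignment length, end gaps included. 'X' never
matches anything. The convention is selectable (`mode=` on every entry
point) because published pipelines differ and the original rule here was
unspecified.

A third published filter — removing entries without a database
cross-reference — requires live queries and is recorded in every
`CurationReport` as not applied.

## Statistical coupling analysis

All energies are in the statistical unit kT\*, set to 1.

For a column with amino-acid counts c_x over n informative (non-gap,
non-ambiguous) rows, probabilities carry a pseudocount λ = 1/n per residue:

    P_x = (c_x + λ) / (n + 20 λ)

The family background q_x (empirical frequencies over all informative cells
of the alignment) is passed through the same transform at the column's n, so
a column whose observed frequencies exactly match the background scores
exactly zero:

    ΔG_stat(i) = kT* sqrt( Σ_x ln²( P_{x,i} / q'_x ) )

The coupling energy perturbs column j by restricting the alignment to rows
carrying j's most frequent residue (ties broken toward the lower
alphabetical index) and measures the shift of column i's distribution:

    ΔΔG_stat(i|δj) = kT* sqrt( Σ_x ln²( P_{x,i|δj} / P_{x,i} ) )

The reported matrix is the mean of the admissible directions (i|δj) and
(j|δi), which makes it symmetric; both raw directions are retained.

**Admissibility.** A perturbation is only meaningful if the subalignment is
large enough to estimate 20 frequencies. The rule: the subalignment must
retain at least a fraction 0.25 of all rows, and at least 100 rows whenever
the alignment has 100. Below that, the pair is masked as missing — never
reported as zero, which would be indistinguishable from "uncoupled". A
consequence worth knowing: on the synthetic generator's default **uniform**
background, no background column's dominant residue approaches 25%
occupancy, so at mixing strength ε = 0 every perturbation is masked and the
supra-threshold false-positive rate is exactly zero by masking. Planted
columns concentrate ~ε/2 + (1−ε)/20 of the rows on each compatible residue
and are comfortably admissible at ε ≥ 0.5.

**Gap handling.** Gaps are excluded from frequency normalization; columns
with more than 50% gaps are excluded from the matrix entirely (alignment
regions dominated by indels are not informative for this statistic).

**Magnitudes.** With λ = 1/n, strong planted covariation can reach tens of
kT\* because residues absent from a subalignment receive probability ≈ 1/n²;
the energies are ordinal measures of co-evolution strength, and thresholds
(1.0 kT\*) should be read against the family being analyzed, not across
formulations of the statistic.

**Sectors.** Positions with at least one coupling ≥ threshold are clustered
by average-linkage agglomeration on the distance 1 − ΔΔG/max(ΔΔG)
(sub-threshold and masked pairs at distance 1), cut at k = 3 clusters by
default. Positions with supra-threshold couplings into another sector are
flagged co-sector. k is configurable; with fewer network positions than k
the call errors rather than degenerating silently.

## Network construction

Nodes are positions with ≥ 1 supra-threshold coupling (reported in reference
numbering when the alignment designates a reference row; column indices
otherwise); each supra-threshold pair is one undirected edge. Degree counts
distinct partners. Strata: intermediate for energies in [1.0, 1.4) kT\*,
high for ≥ 1.4 kT\* — printed stratum bounds like "1.0–1.39" are treated as
rounded edges of the half-open convention [1.0, 1.4) / [1.4, ∞), so an
energy of 1.395 is still intermediate. Hub
residues have degree ≥ 9 (configurable). Raising the threshold can only
remove nodes and edges (monotonicity, property-tested).

Divergence between two family members at a set of network positions is
counted in alignment columns (homologous coordinates), not by structural
superposition. Gap-versus-residue counts as divergent and is flagged;
gap-versus-gap does not.

## Structure mapping

Cα coordinates come from the first model of a PDB file, one chain, altloc
'A' preferred; a numbering offset maps PDB numbering onto the reference
numbering. Contact means Cα–Cα distance < 6 Å; exactly 6 Å is distal (the
boundary is pinned by a unit test). The 6 Å cut (rather than a ~4 Å van der
Waals cut) keeps a pair non-contacting even after side-chain substitutions
in a double mutant. Distance histograms use half-open 4 Å bins from 4 Å,
ten bins by default; out-of-range distances are clipped into the edge bins
so that bin mass equals the number of classifiable edges, and edges with an
unresolved endpoint are excluded but tallied.

## Kinetics and double-mutant cycles

Michaelis–Menten fits use bounded trust-region least squares
(`scipy.optimize.curve_fit`, bounds ≥ 0, tight tolerances), on
replicate-averaged points by default (fit-all-points is an option). Initial
values: k_cat⁰ = max observed rate, K_m⁰ = concentration nearest half-max,
with a log-spaced K_m grid restart on failure. Parameter standard errors
come from the fit covariance. Non-convergence and all-zero rates raise with
diagnostics rather than returning numbers.

Free energies use R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298 K by default
(the temperature is exposed everywhere it enters). ΔΔG_M =
−RT ln(eff_mut/eff_wt); CE_therm = ΔΔG_M1 + ΔΔG_M2 − ΔΔG_M1M2, positive for
cooperative pairs.

**Epistasis classes.** The literature names five interaction classes without
numeric boundaries, so the rule set here is explicit. With s = ΔΔG_M1 +
ΔΔG_M2 and d = ΔΔG_M1M2, applied in order:

1. *additive*: |s − d| < bound (default 1.0 kcal/mol, configurable to 1.5 —
   coupling energies below 1–1.5 kcal/mol are within experimental error of
   additive);
2. *synergistic*: |d| > |s|;
3. *no-additional-effect*: d within the bound of one single's effect;
4. *partially additive*: d between the larger single effect and the sum,
   same sign as the sum;
5. *antagonistic*: the remainder (the double falls below the larger single —
   the mutations counteract).

**Additivity offset.** With the slope fixed at 1, the least-squares offset
of (ΔΔG_M1 + ΔΔG_M2) against ΔΔG_M1M2 is exactly the mean CE_therm; its 95%
CI uses the t distribution. A free-slope ordinary regression is reported as
a diagnostic only.

## Synthetic data

The generators define the test conditions for the whole chain.

**MSA.** N = 800 sequences × L = 120 columns by default, i.i.d. rows (star
phylogeny — no phylogenetic correlation; real families violate this, which
inflates apparent coupling, so passing tests here bound statistical
behavior under independence, not under realistic relatedness). Background
uniform over 20 amino acids by default (configurable). Each planted pair
fixes two compatible residue combinations; with probability ε a sequence
draws one combination (fair coin), otherwise both columns come from the
background — compensatory covariation with one tunable strength. Defaults:
four planted pairs at ε = 0.8. Optional near-duplicate clusters (within
identity 0.98) and terminal fragments (60% truncations) exercise curation.

**Titrations.** Twelve concentrations log-spaced over 238 nM – 1 mM, three
replicates, additive Gaussian noise with sd = 5% of the noiseless rate, at
the family's parameter scales (k_cat ≈ 0.004–0.5 s⁻¹, K_m ≈ 0.2 µM – 1 mM).

**Structures.** Ideal-geometry Cα traces. The helix uses rise 1.5 Å, twist
100°, radius 2.3 Å, giving the canonical 3.83 Å consecutive-Cα spacing and a
5.05 Å i→i+3 contact within a helical turn. Note that i→i+4 is ~6.2 Å for
any realistic helix (the 6 Å rise alone exceeds the contact cut), so
"within one turn" contacts are i+3, not i+4. The random coil is a
fixed-step (3.8 Å) random walk, not self-avoiding.

All generators are bit-reproducible under a fixed seed.

## Problem sizes and determinism

The default test and acceptance runs use the generator defaults above
(N = 800 × L = 120 SCA runs complete in well under a second; the
Michaelis–Menten simulation study uses 500 draws). Hypothesis runs
derandomized with 50 examples per property. The pipeline embeds a hash of
its config in every output and caches the SCA matrix keyed by that hash, so
a rerun with unchanged inputs is byte-identical and reuses the cache.

## Known limitations

- The SCA formulation here is one explicit member of the perturbation-SCA
  family; published analyses used code whose exact generation/normalization
  is not recoverable, so network membership counts are comparable only in
  spirit, not digit-for-digit.
- No phylogenetic correction: relatedness between sequences masquerades as
  co-evolution. The curation identity threshold is the only guard.
- Sector extraction assumes the thresholded matrix has block structure; on
  diffuse networks average linkage can return one dominant cluster plus
  singletons.
- The fragment filter is length-based only; internally deleted yet
  full-length sequences pass it.
- Divergence counts rely on the alignment being correct at the compared
  columns; misalignment shows up as spurious divergence.
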