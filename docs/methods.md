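# Methods

## Sequence design

Barrel peptides are generated from fixed heptad position rules: the
interface signature `g = S, a = L, d = I, e = A` specifies the oligomer
interface; `b = c = E` (acidic chains) or `K` (basic chains) provides the
complementary charge flanks; `f` positions are free and default to
`(Q, K, W)` on acidic and `(Q, K, Y)` on basic chains, N to C — one
chromophore per chain plus solubilising residues. These defaults are a
package choice (the residue *set* is fixed by the design scheme, the exact
per-variant order is configurable). Termini default to N-acetyl / C-amide,
as synthesized. The register (start letter) is the only design axis the
scan varies: register-permuted sequences are rotations of one another's
infinite repeat.

Unnatural reporter residues — 4-cyanophenylalanine (fluorophore) and
selenomethionine (quencher) — are carried as single-character extension
codes (`Δ`, `Ω`) that the validator accepts only at `b`, `c` or `g`
positions, the substitution sites used in the quenching experiments. They
carry no charge and are excluded from mass/extinction bookkeeping. The
free-amino-acid ε₂₁₄ side-chain table is a required argument of
`epsilon214` rather than a shipped constant; only the backbone value
(923 M⁻¹cm⁻¹ per amide bond) is built in.

## Synthetic assemblies

The generator builds straight-axis bundles: ideal α-helices (rise 1.5
Å/residue, 3.6 residues/turn, Cα radius 2.3 Å) placed at equal azimuthal
phases on a circle of the assembly radius (default 9.5 Å for a hexamer — a
plumbing default, config-exposed). Orientation −1 flips a helix by a 180°
rotation about its local x axis; axial offsets translate chains along z, so
an antiparallel barrel with A chains at +z/2 and B chains at −z/2 realises
an inter-helix Z-shift of z. The straight-bundle limit (infinite supercoil
pitch) is the default because the Z-shift definition requires only a common
axis; a supercoiled builder could sit behind the same parameter type but is
not needed for any quantity computed here. Models are Cα-only: every
downstream metric (Z-shift, TM-score, RMSD) is Cα-based.

Ensembles emulate multimer-prediction runs: `len(seeds) × n_variants`
models (five variants per seed by default; 100 seeds → 500 models), each
with Gaussian coordinate noise (default σ = 0.3 Å, roughly the scatter of
confident predictions of a small coiled coil), a planted
parallel/antiparallel ground-truth topology, and an ipTM drawn from a
two-component Beta mixture with topology-dependent means. When a
high-confidence count is planted, exactly that many models score above the
0.7 threshold, with the parallel minority ranked on top — reproducing the
situation where the highest-confidence predictions belong to the minority
topology. Everything is deterministic given the seed list and one RNG seed.

What the generator does *not* emulate: supercoiling and knobs-into-holes
packing detail, per-residue pLDDT profiles, correlated (non-i.i.d.) error
modes of real predictors, and length/compositional heterogeneity. Passing
tests therefore demonstrate correct *recovery of planted structure* under
idealized noise, not predictor behaviour on real sequences.

## Geometry

Helix axes are principal-direction fits, but on *turn-smoothed* traces:
moving centroids over a window spanning a whole number of helical turns
(18 residues = 5 exact turns at 3.6 residues/turn) lie exactly on the
helix axis, removing the tilt bias that a fractional final turn induces on
the raw Cα cloud (~1.4° for a 21-residue helix, enough to corrupt 0.1 Å
Z-shift recovery). Directions are sign-fixed N→C. The bundle axis is the
sign-aligned average of per-chain axes (each flipped onto the dominant
principal direction of the pooled cloud so antiparallel chains reinforce
rather than cancel), sign-fixed to the majority chain direction.

Z-shift: |difference of the two helix-centroid projections onto the bundle
axis|, per ring-adjacent pair; ring adjacency is azimuthal order about the
axis, not chain-ID order (file chain order is arbitrary). The per-model
aggregate is the **mean** over adjacent pairs; min and max are also
reported since a single per-model figure could be summarised either way.
Topology: the sign of each helix direction against the bundle axis — all
equal → parallel, strict alternation around the ring → antiparallel; a
helix with |cos| < 0.2 against the axis is flagged ambiguous rather than
silently classified. The orientation-preference rule is strict: parallel
iff the antiparallel-state Z-shift exceeds the 4 Å threshold (exactly 4 Å
counts as antiparallel).

Overhang is reported per end: the axial distance by which one helix's
projected Cα span protrudes beyond its neighbour's at each end of the
bundle (for equal spans both ends equal the pair's |Δz|).

## TM-score and clustering

The TM-score is the standard length-normalised superposition score,
normalised by the reference residue count with chains concatenated and
d₀ = 1.24(L−15)^⅓ − 1.8 clamped below at 0.5 Å. The superposition maximum
is searched by iterative inclusion: Kabsch-superpose on a seed fragment,
score all aligned residues, re-superpose on those within a distance
cutoff, iterate to convergence; seeds are sliding windows of lengths n,
n/2, n/4 and 4, over a cutoff ladder d₀ + {0, 1, 2.5, 4} Å. On ≤ 30-residue
toys this agrees with direct numerical maximisation over the six
rigid-body degrees of freedom (multi-start Nelder–Mead; an independent
code path kept in the test suite) to < 0.01.

Chain mapping for the C₃-pseudosymmetric A₃B₃ assembly: candidates are the
2n dihedral mappings (cyclic rotations × reflection of the azimuthal ring
order), filtered to type-preserving ones (A→A, B→B); each is ranked by a
single-superposition TM estimate and the best is scored with the full
search. Residue correspondence is index-wise N→C over the shorter chain.
"Fraction aligned" is the mapped-residue fraction **of the larger
structure**, so `normalized_tm = TM × fraction` strictly penalises
truncation; this definition is a package choice among the plausible
conventions.

Clustering is greedy leader clustering in descending confidence order
(ipTM, ties by mean pLDDT, then model index — the usual prediction-ranking
convention): a model joins the first cluster whose leader it matches at
normalized-TM ≥ threshold (default 0.95), else founds a new cluster. This
is deterministic, O(n·k), and makes each representative the
highest-confidence member by construction. Complete-linkage agglomeration
on the full pairwise matrix is available behind a flag for small ensembles.
"Binned into clusters" admits either reading; leader clustering is the
default for determinism and cost.

## Solution-phase models

Adopted conventions (standard forms consistent with the stated variable
definitions): MRE = θ·10⁶ / (c_μM · l_mm · n) with n the number of amide
bonds including the N-acetyl cap and C-amide; ε₂₁₄ = 923 · n_bonds + Σ
side-chain contributions; single-site binding y = B_max·x/(K_D + x) with x
the **assembly** concentration (peptide concentration ÷ oligomeric state,
default 6). Fits use least squares (`scipy.optimize.curve_fit`) with
data-derived initial values; R² on the fitted curve; 95% confidence
intervals by seeded case-resampling bootstrap (1000 resamples by default —
the CI method is a package choice). Non-convergence raises with
diagnostics, never silently.

The Job plot locates the signal maximum by a quadratic fit through the
empirical maximum and its two neighbours (a wider window biases the vertex
on tent-shaped continuous-variation curves); a maximum at a composition
boundary raises "no complex detected". The mole fraction x̂ maps to the
nearest coprime small-integer stoichiometry p:q with p+q minimising
|x̂ − p/(p+q)|, p, q ≤ 6.

Quench logic: a fluorophore/quencher pair is quenched iff adjacent —
same-terminus placements in a parallel assembly, opposite-terminus
placements in an antiparallel one. Orientation inference returns the unique
topology whose truth table matches all observations; because the two
tables differ in every cell, a single observation already decides, and
"ambiguous" is reachable only for an empty-constraint degenerate (kept for
contract completeness).

## Register scan and problem sizes

The default scan runs registers b, c, g with planted antiparallel Z-shifts
2.5, 3.5 and 5.6 Å (the measured ordering g > c > b; the c value sits
between the stated endpoints) and high-confidence compositions 1:301,
1:115 and 2:170 parallel:antiparallel out of 500 models each. Per
register: design → ensemble → ipTM filter → clustering → topology → mean
antiparallel Z-shift → threshold rule, plus optional quench observations
for the solution-phase cross-check. A register that fails produces an
error entry without stopping the others. Reports round-trip losslessly
through JSON; CSV has one row per register; markdown one table per
register.

Test-suite and acceptance problem sizes (chosen so a full run completes in
a few minutes on one core): clustering checks use the full 172-model
g-register ensemble and 302/116-model b/c ensembles; topology recovery
uses 300 models; TM-oracle comparisons use 30-residue toys (the oracle's
multi-start optimisation dominates its cost); binding noise studies use
100 replicates of 12-point titrations.

## Known limitations

- The geometry assumes near-straight helices; strongly supercoiled or bent
  assemblies would need a local-axis treatment the straight-bundle metrics
  do not provide.
- Antiparallel ring-alternation requires an even chain count; odd barrels
  classify as mixed by construction.
- The TM-score search is heuristic; its oracle agreement is verified on
  small instances, not proven globally.
- Chain-type inference from files uses charge composition (Glu vs Lys/Arg
  counts) and can be overridden; it would misassign neutral designs.
- The binding model assumes a single class of independent sites and free
  ligand ≈ total ligand; tight-binding regimes (K_D comparable to the
  ligand concentration) need a quadratic depletion model that is out of
  scope here.
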