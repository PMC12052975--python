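# Methods

## Scope and model reduction

The package studies substrate gating of full-size ABCG/PDR transporters
on a one-dimensional reaction coordinate: *z*, the position of the ligand
along the translocation pathway (nm), from the intracellular entry
(negative *z*) through the central binding pocket to the extracellular
gate (around 1.3–2.0 nm). All-atom detail is deliberately replaced by
analytic free-energy landscapes *F(z)*; everything downstream — the
enhanced-sampling machinery, the pull statistics, the classifier, the
conservation pipeline — operates exactly as it would on real simulation
output, which is the point: the statistical procedures can be validated
against known ground truth.

## Langevin engine

The coordinate evolves under underdamped Langevin dynamics discretized
with the BAOAB splitting, which has near-exact configurational sampling
at the time step used. Parameters, with units and defaults:

| parameter   | unit      | default  | role |
|-------------|-----------|----------|------|
| temperature | K         | 303.15   | sets kBT ≈ 2.52 kJ/mol; equilibrium distributions |
| timestep    | ps        | 0.002    | integration step |
| friction    | 1/ps      | 1.0      | timescales only |
| mass        | g/mol     | 50       | timescales only |

Friction and mass are coarse-grained conventions: they fix relaxation
times, not equilibrium averages, and no claim is made that they match the
effective ligand friction of a membrane transporter. Velocities are drawn
from Maxwell–Boltzmann at the run temperature using the run seed; each
walker of a multi-walker run uses an independent generator seeded
`seed + walker_index`, so every run is bit-reproducible. Positions
outside a landscape's domain are clamped (with a warning) rather than
rejected; the one-sided power walls (default κ = 1000 kJ/mol/nm²,
exponent 2, at −1.1 and 2.0 nm) make such excursions rare and confine the
ligand to the pathway. Tabulated landscapes interpolate linearly with a
right-sided derivative at the nodes.

## Well-tempered metadynamics

Hills of width σ = 0.05 nm are deposited every 500 steps (1 ps) at each
walker's position, with height `h0 · exp(−V/(kB(γ−1)T))`, h0 = 0.6
kJ/mol, γ = 10. The shared bias is kept in two synchronized forms:

* the exact ordered hill list (written as a PLUMED-style HILLS text
  table), used for hill-height scaling and for bias queries; and
* a projection onto the configured grid (391 nodes, 0.01 nm spacing over
  [−1.5, 2.4]): every deposited Gaussian is evaluated in full at every
  node (no truncation), and the propagator interpolates energy and
  gradient linearly between nodes.

Grid-backed bias is the standard engineering choice for this method; the
interpolation affects only the propagation force (error of order
Δz²·V″ ≈ 3·10⁻³ kJ/mol), while all recorded heights and all bias values
reported at probe points come from summation, so offline re-summation of
the HILLS file reproduces the online bias to floating-point round-off.
Walkers propagate in synchronous rounds and deposit in fixed index order;
a hill deposited earlier in a round damps the heights of later deposits
in the same round. The FES is recovered as −γ/(γ−1)·V on the grid,
shifted to minimum zero, with a sampled-region mask marking nodes within
3σ of at least one hill center. FES comparisons (`fes_rmse`) align both
surfaces to mean zero on the comparison region first, since a free energy
is defined up to a constant. Convergence statements are made on the
well-and-barrier region (|z| ≤ 1.1 nm for the 12 kJ/mol double well):
outside it the quartic limbs rise to the order of 100 kJ/mol and are
visited only transiently, so no hill-sum estimate converges there at any
practical run length.

## Steered pulls and contact statistics

The placement stage uses the staged moving restraint (hold at the initial
distance with κ = 1000 kJ/mol/nm², sweep the center to 0.2 nm by step
4.5·10⁶, release the spring by step 5·10⁶), with center and stiffness
interpolating linearly between stages and held beyond the last. The
pull-out is a constant-velocity restraint along +z with force constant
500 kJ/mol/nm² and velocity 0.0005 nm/ns by default; desk runs rescale
the velocity (the generators use 40 nm/ns and note the value in the run
metadata) because the production velocity would need microseconds of
integration.

Contact with a pathway residue is defined as |z − c| ≤ w for that
residue's zone (default half-width 0.1 nm) — a one-dimensional stand-in
for 3-D atom-pair contacts that preserves the downstream statistic's
structure. The correction factor of a frame sums positive and negative
restraint-force samples in a ±10 ps window (truncated at the trajectory
ends, no padding; 0 when every sample is zero) and normalizes their
difference, giving a value in [−1, 1] that is exactly antisymmetric under
force negation. The adjusted frequency of a zone is the frame average of
contact · correction factor; the combination rule is a package
convention (the raw frequency is always reported alongside), and an
alternative reading that counts positive samples instead of summing
their values reduces the statistic to a sign fraction — it is documented
here but not implemented as the default.

## Transport classifier

Adjusted frequencies from all (molecule, variant, replicate) simulations
form the design matrix (residue columns sorted by residue number, missing
residues filled with 0, per-column z-scoring by the population standard
deviation with constant columns left at zero). The classifier minimizes
mean cross-entropy + (λ/2)‖β‖² with unpenalized intercept, by damped
Newton iteration from a zero start (step halving enforces a non-increasing
objective; convergence at gradient norm < 1e-8). λ = 1 by default;
replicates enter as rows; one pooled model is fitted across molecules and
variants. The zero start makes the label-flip symmetry
(y → 1−y ⇒ β → −β) hold to round-off. Residues are classed promote/
counteract by coefficient sign with a 1e-10 dead zone. The electronic
binding-energy helper is the plain relation E_el = E_PL − (E_P + E_L)
with sign-based binder/non-binder classification; the quantum-chemical
machinery that produces the components is out of scope and they are
treated as inputs.

## Gate-conservation pipeline

The full-size screen keeps sequences of length 950–1800 (inclusive) that
contain all four PDR signature motifs, with X matching any single
residue and overlapping matches allowed. Reference mapping offers two
routes: through an existing multiple alignment (the k-th non-gap
reference character maps to its column, with an exact inverse), or
through pairwise global alignment to the reference (BLOSUM62, affine
gaps with open −10 and extend −0.5 under the "first gap costs
open + extend" convention, end gaps penalized). The gate positions
703/704/1374/1375 lie just outside the printed helix segments (which end
at 700 and 1371), so they resolve only through alignment to a full
reference sequence; the synthetic scaffold provides one. Occurrence
tables keep gaps as a 21st category; information content
R = log₂20 − H is computed over amino acids only, with the small-sample
correction (19/(2·ln2·n)) off by default. The consensus caller emits the
top residue at fraction ≥ 0.5, a two-residue token when the top two sum
to ≥ 0.5 with each ≥ 0.2, else "x".

## Synthetic data

Landscape archetypes: the substrate profile is a linear downhill trend
(slope −8 kJ/mol/nm) with two Gaussian bumps (4 and 5 kJ/mol at −0.1 and
0.7 nm, width 0.12 nm) — an overall downhill translocation with small
local barriers; the non-substrate profile adds an 8 kJ/mol Gaussian at
−0.75 nm (width 0.12), an elevated entry barrier in the −1…−0.5 nm
region. All parameters are recorded on the object so the analytic
surface is exactly known.

The transport phenotype table is fixed and complete over four molecules
× nine gate variants: IBA exported by every variant except A1357V; CLX
only by Wt and L704Y; IAA only by L704Y and L704S; indole only by L704Y.

Contact panels come in two modes. *Direct* mode samples each residue's
adjusted frequency from a clipped Gaussian baseline (0.2, sd 0.05) and
shifts planted residues: +0.3 for the seven promoting residues in
transported runs, ∓0.15 for the four counteracting residues
(−: transported, +: blocked). Baseline and effect size are package
conventions — contact magnitudes are published as color scales, not
numbers — chosen so that recovery is neither trivial nor impossible, and
both are exposed on `PanelSpec`. In direct mode the raw frequency is reported as
|adjusted|, its tightest admissible lower bound. *Mechanistic* mode runs
an actual steered pull per simulation on the matched landscape archetype:
a weak spring (κ = 1 kJ/mol/nm²) with a fast center sweep (40 nm/ns,
120 ps), so the pull finishes early and the time a run spends parked at
the extracellular gate reflects the entry-escape delay instead of being
erased by a stiff moving restraint. Promoting-residue zones tile the
gate-parking region (1.70–2.00 nm), counteracting zones the entry-waiting
region (−1.00…−0.76 nm); the zone map is a fixed convention of the
generator. Both modes agree directionally: gate-zone contact is higher
for transported systems, entry-zone contact for blocked ones.

Sequence panels build every record from the reference scaffold: the four
helix-segment blocks (with flanks covering the gate positions) are copied
exactly, gate residues are redrawn from round-number per-taxon
distributions (qualitative shapes only — the first gate position of each
half F/Y-dominated, the second more variable; no claim to reproduce the
published percentages), the PDR motifs are planted in scaffold order,
and the inter-block backgrounds are mutated (65% substitution),
length-adjusted copies of the scaffold's backgrounds, so records behave
like alignable family homologs. Decoy records, used to exercise the
screen, either omit one high-specificity motif (the 12-mer or the 7-mer,
whose chance occurrence in random background is ≤ 10⁻³ per panel) or
take lengths outside [950, 1800]; truth tables record every planted
fact. What the generators do **not** emulate: real indel/substitution
processes, phylogenetic correlation between records, database
contamination, 3-D contact geometry, and work-based free-energy
estimates — so passing tests validate the statistical machinery, not
claims about any particular real dataset.

## Problem sizes and numerical choices

Default test and acceptance runs use 2·10⁶ steps per walker (4 walkers)
for metadynamics recovery, 2·10⁷ steps for the Boltzmann check
(~1500 barrier crossings of the 6 kJ/mol well used there), 4·10⁵ steps
for the stiff-spring check, and 20 seeded 36-simulation panels for sign
recovery — sizes chosen so each stage's statistical error sits well
inside its tolerance. The equipartition check uses a stiff well near
critical damping (k = 50 kJ/mol/nm², friction 2/ps) so the position
autocorrelation time (~1 ps) leaves thousands of effective samples.
The aligner oracle enumerates all alignments exhaustively for all
sequence pairs up to length 3 over a four-letter alphabet and for a
seeded sample of length-4–6 pairs (full enumeration over all length-≤6
pairs would be ~30 million pairs at ~10⁴ alignments each, out of
proportion to what the check establishes).

## Known limitations

* One pooled logistic model is fitted; per-molecule models are possible
  with the same machinery but are not the default.
* The sampled-region mask marks any node within 3σ of a hill, including
  single-visit excursions; convergence claims therefore restrict to the
  well-and-barrier region explicitly.
* Mechanistic-mode contact contrasts are statistical (escape over the
  entry barrier is thermally activated, ~2.4 kBT); directional tests
  average over fixed-seed replicate sets.
* `restraint_state` on a schedule whose first stage center is "the
  initial distance" requires resolving the schedule with `z_init` first.
* Reweighting estimators, FES error bars, transition-tempered variants,
  2-D collective variables, Jarzynski/Crooks work estimates and graphical
  logo rendering are out of scope.
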