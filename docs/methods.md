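# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic-data generators do and do not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Ion-pair state classification

A frame of an Arg/Glu pair receives exactly one of five labels. Two
inclusive (≤) distance criteria at 4.0 Å each drive the partition: the
centroid criterion on the unweighted means of the charged-group atoms
(guanidinium {CZ, NE, NH1, NH2}; carboxylate {CD, OE1, OE2}) and the
pair criterion on side-chain nitrogen–oxygen distances ({NE, NH1, NH2} ×
{OE1, OE2}). Both criteria → salt bridge; pair only → N–O bridge; neither →
long range. "Carbonyl oxygen" is read as the side-chain carboxylate oxygens
(consistent with the charged-group framing); backbone O can be added through
`BridgeCriteria` if a broader reading is wanted.

Salt-bridge frames are sub-classified by an injective nitrogen→oxygen
assignment: geometry A requires NH1 and NH2 matched to *distinct* oxygens
within the cutoff, geometry B requires the same for NE and NH2, and A takes
precedence when both hold (it is the tighter bidentate arrangement and the
two populations are reported as disjoint). The "distinct oxygens" reading
of geometry B — each nitrogen paired with a different oxygen, found by
maximising the matching — is a deliberate interpretation of an ambiguous
phrase; the alternative (both nitrogens near one specific oxygen) is not
implemented. Boundary values count as "within" because the criterion is a
closed ball; the choice only matters on a measure-zero set for real
coordinates.

All classification decisions are invariant under rigid motion of the frame,
which the tests assert by construction (generator frames with and without a
random rigid motion share labels).

## Superposition and fluctuation statistics

Rigid fits use the Kabsch solution via quaternion alignment
(`scipy.spatial.transform.Rotation.align_vectors`), which returns a proper
rotation (det = +1); a near-collinear anchor set (second singular value
< 1e-8 of the first) is refused. Per-residue RMSD is the root mean square
over a residue's atoms against a common reference frame, computed on frames
superposed beforehand — the function deliberately does not re-fit.
Hydrogens are excluded by default (a flag includes them) since deposited
ensembles and stripped trajectories differ in proton content.

The frame-averaged RMSD protocol averages per-frame, per-residue RMSD over a
selected frame subset of each independent simulation, yielding one profile
per simulation. Selection is either by interaction state (using per-frame
labels) or a seeded uniform random subsample of a matched fraction; the
subsample seed enters the output metadata, and each simulation draws from an
independent child stream so results are order-independent. Group contrasts
use a two-tailed independent t-test per residue on the per-simulation
averages — Welch by default (group sizes of ~10 profiles give no reason to
assume equal variances; a pooled option exists for textbook comparisons).
Residues with zero variance and equal means in both groups get p = 1 by
convention. The default significance threshold is 2×10⁻⁵, with the
alternative convention 2×10⁻⁴ available as a parameter; no multiplicity
correction is applied beyond the fixed threshold, matching the practice the
package reproduces.

RMSF is the per-atom root-mean-square deviation about the time-mean
position, averaged within each residue. Alignment-residue selection keeps
residues with RMSF strictly below the 75th percentile (linear interpolation
between order statistics — the retained set depends on this convention, so
it is fixed and documented; the cutoff value is returned).

## Order parameters

S² estimates treat the N→H unit-vector series of each residue in a
molecule-fixed frame; ensembles must be superposed on a stable anchor set
first, and the vector-extraction helper skips prolines and chain termini.
When amide protons are absent, H is optionally reconstructed at 1.02 Å from
N along the direction opposing the bisector of the C(i−1)–N and CA–N bonds.

The double-sum estimator averages P₂(μ̂(t)·μ̂(t+τ)) over all frame pairs
with lag τ in a plateau window, default [T/2, T−1]: at long lags internal
motion has decorrelated, so the correlation plateaus at S². The exact pair
sum is computed in O(T) using prefix sums of the outer products μ̂μ̂ᵀ
(⟨μ̂μ̂ᵀ(t), μ̂μ̂ᵀ(s)⟩ = (μ̂ₜ·μ̂ₛ)²); a literal pair loop validates the
identity in the tests. The window is configurable because the lag-range
convention is a genuine free choice of the discrete estimator. The
independent second-moment form S² = 3/2 Σᵢⱼ⟨μᵢμⱼ⟩² − 1/2 is the plateau
value implied by the orientation distribution alone; agreement of the two
estimators (within 0.02 at T = 10⁵ on cone-model series) is the package's
core anti-bug property for this module, since they share no code path.

The wobble-in-a-cone reference model (uniform sampling per solid angle
inside semi-angle θ₀) has the closed form S² = [cosθ₀(1+cosθ₀)/2]²; note it
is non-monotone past 90°, so monotonicity checks stop at the hemisphere.

## ¹⁵N relaxation

The forward model maps the two-term isotropic Lipari–Szabo spectral density
J(ω) = (2/5)[S²τm/(1+(ωτm)²) + (1−S²)τ/(1+(ωτ)²)], 1/τ = 1/τm + 1/τe,
through the standard dipolar + CSA expressions for R₁, R₂ (plus additive
R_ex) and NOE. Constants: r_NH = 1.02 Å, Δσ(¹⁵N) = −160 ppm, standard
gyromagnetic ratios, 600 MHz proton frequency — all configurable through
`NmrConstants`. The signed γ(¹⁵N) keeps the NOE capable of going negative
for flexible residues.

`modelfree_fit` inverts one (R₁, R₂, NOE) triple at fixed τm (11.0 ns and
11.6 ns are the worked-case values for the wild-type and mutant protein)
over the ladder S² → S²+τe → S²+R_ex → S²+τe+R_ex, selected by
AIC = χ² + 2k on uncertainty-weighted residuals, ties favouring the simpler
model. AICc is undefined here (its correction divides by n−k−1 with n = 3
observables), so plain AIC is used. τe is optimised internally in
nanoseconds: in seconds (~1e-11) the trust-region finite differences stall
well short of the optimum, in nanoseconds the noiseless round trip is exact
to machine precision. Default uncertainties are 2 % of each observable when
none are stated; high-precision data should carry correspondingly small
uncertainties or the ladder will (correctly) refuse weakly-supported
parameters.

Identifiability, not optimisation, limits noisy recovery: linearised
propagation of 2 % observable noise gives 1-SD relative errors on τe of
~10–60 % depending on where the true parameters sit (worst where 1−S² is
small, since that factor scales the entire τe term). Recovery claims at
2 % noise are therefore phrased as the bias of replicate-averaged estimates,
median over a 27-point grid (S² ∈ {0.7, 0.85, 0.95}, τe ∈ {20, 50, 100} ps,
R_ex ∈ {0, 2, 5} s⁻¹, chosen once as a realistic folded-protein range);
single-point errors at the S² = 0.95 corners are unavoidably larger.

CPMG dispersion uses the constant-period transform ΔR_ex(τcp) = −ln(I/I₀)/T
with T = 80 ms and I₀ at the shortest τcp (so ΔR_ex is zero there by
construction), and the Luz–Meiboom fast-exchange profile
R_ex = Φ_ex τ_ex [1 − (2τ_ex/τcp) tanh(τcp/(2τ_ex))] with Φ_ex = p₁p₂Δω².
Since the printed equation forms were not machine-readable in the source
material, both are implemented from the symbol definitions and isolated so
alternate forms can be swapped; a numerical two-site Bloch–McConnell
propagator (matrix exponentials between ideal π pulses, conjugation for the
pulse) provides the independent check, agreeing within 5 % across the
1–20 ms τcp range in the fast-exchange regime. The nine-point τcp grid is
linear over 1–20 ms; the source states the range and count but not the
spacing. Dispersion fits report Φ_ex ≈ 0 with a `flat_profile` flag rather
than failing on exchange-free residues.

## Urea denaturation

CD curves follow the six-parameter two-state linear-extrapolation form
y = [(y_f + m_f u) + (y_u + m_u u)K]/(1+K), K = exp(−(ΔG_H₂O − m·u)/RT),
R = 1.987×10⁻³ kcal/(mol K), T = 298.15 K by default. Initialisation is
automatic: endpoint regressions for the baselines, the steepest-gradient
point for the midpoint, a generic cooperative m to start. A fit is rejected
(with the best iterate in the error) when the midpoint leaves the measured
range, m ≤ 0, or the baseline separation at the midpoint is below 20 % of
the signal span — the last guard catches transition-free curves that the
unconstrained six-parameter model would happily "fit". Replicate titrations
are averaged pointwise on the overlap grid with linear interpolation, with
optional min–max normalisation; both the raw-signal fit and the
fraction-unfolded transform f_u = (y − baseline_f)/(baseline_u − baseline_f)
are provided because either can be the fitted object depending on
normalisation conventions.

## Conservation filtering

Ungapped lengths are kept in [L, L+100] where L is the family HMM model
length — a parameter, not a constant, since family-model lengths drift
between database releases. De-duplication is a greedy scan in input order
(seedable shuffle available): a record is dropped when its identity to any
already-kept record *exceeds* the threshold (0.98), identity being matches
over columns where neither sequence is gapped; the alternative
shorter-sequence denominator is a flag. Conservation ranking scores each
column by the modal-residue frequency over non-gap rows, excludes
gap-majority columns, and breaks ties by column index so rankings are
deterministic.

## Synthetic data

The generators emulate the statistical structure of each input class, not
the physics:

* **Bridge ensembles** draw per-frame states from prescribed populations and
  instantiate hand-built planar guanidinium/carboxylate templates (ideal
  internal geometry: C–N 1.33 Å at 120°, C–O 1.25 Å at 126°) whose every
  classifier-visible distance clears its 4.0 Å cutoff by a margin, plus
  isotropic Gaussian jitter; a jitter σ with 2σ above any requested
  template's margin is refused. Margins are 0.17–2.4 Å, so the default
  σ = 0.05 Å misclassifies of order 10⁻⁴ of frames at worst (a >3 SD
  distance excursion); fraction-recovery tests use binomial error bands,
  and exact label agreement is asserted at σ = 0.02 where flips are >8 SD
  events. Cα atoms sit off the interaction plane at state-specific
  separations (12.3 Å for geometry A, shifted for looser states) purely to
  give the distance statistics structure. No force field, sterics or
  thermodynamics — passing tests show the classifier and summaries are
  correct, not that the geometries are energetically realistic.
* **Cone vectors** are uniform per solid angle inside θ₀ with the closed-form
  S² as ground truth.
* **Fluctuating chains** are helical Cα/Cβ toy traces (1.5 Å rise, 100°
  twist — chosen so any anchor block is non-collinear) with independent
  isotropic Gaussian per-residue displacements and a near-static anchor
  block; real backbones have correlated, anisotropic motions, so t-test
  calibration results transfer only the *statistical* behaviour.
* **Relaxation, dispersion and unfolding tables** come from the package's own
  forward models plus Gaussian noise. Round trips therefore test inversion
  and noise behaviour, not forward-model correctness — that is what the
  closed-form limits, the rigid-rotor reduction and the Bloch–McConnell
  cross-check are for.
* **Alignments** draw each column independently with a prescribed consensus
  frequency; no phylogenetic correlation between rows, which real familes
  always have.

Every generator is deterministic under (parameters, seed) and returns or
embeds its ground truth.

## Problem sizes

Default analysis scales, chosen to characterise each estimator well while
keeping any full run cheap on a single CPU: 5 000 frames for state-fraction
recovery (binomial SDs of ~0.3–0.7 %), T = 10⁵ vectors for S² estimators,
10 noisy replicates per model-free grid point, 500 replicates for the
unfolding bias study, 20 repetitions × 100 residues (two groups of 10
simulations × 30 frames) for t-test calibration.

## Limitations

* Binary trajectory formats are out of scope for the core; the frame-table
  dialect and multi-model PDB are the interchange formats, and an adapter
  (anything producing coordinates + atom metadata) can feed `FrameEnsemble`
  directly.
* The model-free machinery is single-field, isotropic, single-timescale;
  no global τm optimisation (τm is a fixed input), no anisotropic diffusion,
  no two-timescale extended model.
* The dispersion model is the fast-exchange limit; slow-to-intermediate
  exchange needs the full Bloch–McConnell treatment that is provided here
  only as a numerical check.
* Unfolding fits are strictly two-state chemical denaturation.
* Conservation ranking is unweighted; no phylogenetic down-weighting of
  redundant clades beyond the identity filter.
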