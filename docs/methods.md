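# Methods

This note records the models, the numerical choices, and the limits of what
the synthetic test bed can demonstrate.

## Scope and units

Coordinates are Å, times are ns, energies are kcal/mol
(k_B = 0.0019872041 kcal/(mol·K)), angles are degrees in (−180, 180] at
every public boundary and radians internally. Residue numbering is the
author numbering of the input PDB; no renumbering scheme (IMGT/Kabat) is
applied, so CDR and domain definitions are always explicit chain +
residue-range selections supplied by the caller. Trajectories live either
in multi-model PDB or in a frame-major binary container with a one-line
JSON header (atom count, frame count, frame interval, float32 payload);
mmCIF and compressed MD formats are out of scope.

## Dihedral features and the collective variable

ψ(i) is defined over N(i), CA(i), C(i), N(i+1) and φ(i) over C(i−1), N(i),
CA(i), C(i); a terminal residue without the needed flanking atom
contributes no angle, and flanking atoms are taken from the full chain even
when they fall outside the selection. The dihedral follows the IUPAC
convention (cis = 0°, right-handed positive). Each angle enters the feature
matrix as a (sin, cos) pair, which removes the ±180° discontinuity;
sin² + cos² = 1 holds to 1e−9 by construction and is asserted.

The metadynamics collective variable is s = Σ aᵢ sin ψᵢ + Σ bᵢ cos ψᵢ over
the ψ angles of both CDR3 loops. The coefficients of the production-scale
CV are not published; the default here is uniform weights aᵢ = bᵢ = 1,
overridable in config, and nothing downstream depends on that choice.

## Toy well-tempered metadynamics

The bias mathematics is exercised on overdamped Langevin dynamics directly
in a one-dimensional CV space (ds = −∇(V+V_bias)dt + √(2k_BT dt)η,
mobility 1, so D = k_BT): the all-atom engine is out of scope and the toy
engine isolates exactly the parts this package is responsible for — hill
deposition with geometric tempering, escape from deep minima, and the
estimator F(s) = −γ/(γ−1)·V_bias(s). Deposition stride (1,000 steps),
bias factor (γ = 10) and temperature (300 K) default to the
production-scale settings. The hill width σ is not published; the default
is 0.35 CV units, and the double-well experiments use σ = 0.25 with hill
height 0.5 kcal/mol — an appropriate fraction of the 6 kcal/mol test
barrier (the production height of 10 kcal/mol belongs to a much larger
system and CV scale). Periodic CVs are supported through minimum-image
distances in the Gaussian argument. Multi-dimensional hills and hill-width
adaptation are not implemented.

The test bed is the quartic double well V(s) = B((s/m)² − 1)² with exact
barrier B and minima at ±m. At B = 6 kcal/mol (≈10 k_BT) the unbiased
walker does not cross within 2·10⁵ steps while the biased walker crosses
hundreds of times, and 600,000 steps reconstruct the barrier to ~1 %. The
well-tempered damping law h = h₀exp(−V_bias/((γ−1)k_BT)) is verified
exactly by replaying the deposition history.

## Seed clustering and microstating

Pairwise RMSD uses optimal Kabsch superposition per pair on the backbone
atoms of the configured selections (the production atom mask is not
published; backbone is the common convention). Pre-aligning all frames to
frame 0 would not change pairwise-optimal RMSD, so the matrix is built
directly; the cost is O(n²) and desk-scale frame counts are assumed.
Average-linkage agglomeration and the flat cut at the distance cutoff are
delegated to scipy's hierarchical clustering; representatives are medoids
(minimal mean in-cluster distance, ties to the lower frame index). The
1.2 Å cutoff is the production default.

k-means is implemented directly (k-means++ seeding, Lloyd iterations to a
1e−8 center-shift tolerance) because two contracts are asserted on every
run: the within-cluster sum of squares is non-increasing at every
iteration, and an emptied cluster is re-seeded at the point farthest from
its assigned center. Fixed seeds make runs bit-reproducible; scikit-learn
serves as an independent cross-check in the tests, never as the
implementation.

## tICA

Instantaneous and lagged covariances are accumulated over all (t, t+τ)
pairs, never across trajectory boundaries, with the mean taken over the
pair-weighted data; C(τ) is symmetrized, which assumes reversible dynamics
and guarantees a real spectrum in (−1, 1]. The generalized eigenproblem is
solved with a ridge of 1e−6 on the diagonal of C(0) — sin/cos pairs of
low-variance angles are nearly collinear, and the ridge is what makes
duplicated features well-behaved. Two components are retained by default
(the landscapes of interest are two-dimensional); the lag defaults to
10 ns. Free-energy surfaces are −k_BT ln of the binned density, minimum
shifted to zero; empty bins carry NaN rather than a fabricated value.
Crystal-like single structures are featurized with the identical dihedral
definition and projected through the same mean-centred linear map, so a
structure of the wrong loop length fails loudly on the label match.

## Markov-state model

Transition counts use a sliding window. Estimation is restricted to the
largest strongly connected component of the count graph (ties broken by
total counts, then lower state index) — probabilities are only meaningful
on a fully connected network. The reversible maximum-likelihood transition
matrix comes from the classic self-consistent iteration on the edge
weights x_ij ← (c_ij+c_ji)/(c_i/x_i + c_j/x_j), iterated to a 1e−10
relative tolerance; row-stochasticity, stationarity, and detailed balance
are asserted on every constructed model (1e−10/1e−8/1e−8). Spectra are
computed through the π-symmetrized similarity transform, so eigenvalues are
real by construction. Implied timescales are −τ/ln λ; eigenvalues ≥ 1
report as infinity and ≤ 0 as NaN (an undefined marker, never a number).

PCCA+ memberships come from the inner-simplex (vertex) algorithm on the
leading n_macro eigenvectors, followed by a feasibility projection (clip
negative entries, renormalise rows). The iterative crispness optimisation
that some implementations add is omitted: on the metastable systems in
scope the vertex solution is already feasible to ~1e−10 and the refinement
has no testable effect at this scale. Crisp assignment is the argmax
membership with ties toward the lower macrostate id; n_macro is a config
input, guarded by an error when the spectrum has no structure at that rank.
Macrostate kinetics are reported as mean first-passage times (linear solve
over non-target states, stationary-weighted over the source); inverse-rate
readings of the same arrows are available through the implied timescales.

The Chapman-Kolmogorov test compares the π-weighted macro-set staying
probabilities of [T(τ)]^k against models re-estimated at lag kτ, for
k = 1…5. Uncertainty bands are 2.5/97.5 percentiles of 100 bootstrap
resamples over trajectories; with a single trajectory the bootstrap
resamples ten contiguous segments instead (a trajectory-level bootstrap
would be degenerate). Multiples that cannot be re-estimated are flagged in
the report, never dropped.

## Interdomain orientation and state-conditioned statistics

The relative Vα-Vβ orientation is the torsion over four centers of mass:
CDR loops of the α chain → Vα → Vβ → CDR loops of the β chain. COMs are
mass-weighted by default (an unweighted option exists because the
production convention is unknown), and the four selections must be
mutually disjoint. Which loops constitute "the CDR loops" is a user
decision via the selections — the operation takes all four regions
explicitly.

Angle summaries are circular (mean direction; variance reported as the
squared circular standard deviation, (−2 ln R)^{1/2}, in degrees²); a
linear mode exists for comparability, and the two agree away from ±180°,
where interface-angle distributions live. The two-sample KS test is
scipy's, asymptotic mode with the effective-n correction. Frames are
treated as independent although simulation frames are autocorrelated; an
optional stride thins samples before testing, and raw p-values are
reported with a Bonferroni column alongside. RMSF uses a two-pass
superposition (align to the first frame, average, re-align to the mean)
and reports the root-mean-square deviation of each residue's backbone
centroid. Note that superposition absorbs six rigid-body degrees of
freedom, so RMSF on selections with few atoms is biased low by
√(1 − 6/3N).

## Synthetic ground truth

`generate_hmm_trajectory` samples a hidden discrete-time Markov chain
(geometric dwell times — the MSM assumptions are exactly satisfiable,
which is the point) and realises each frame as a toy polyalanine-like
backbone: ψ from state-specific means plus Gaussian emission noise
(default σ = 15°, a realistic within-basin spread), φ near −60°, built by
NeRF-style chain extension with idealised geometry (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, standard angles, ω = 180°). Side chains, sterics and
energetics are absent; downstream features are dihedral-based, so this
suffices.

`generate_two_domain_trajectory` builds rigid pseudo-Vα/Vβ frameworks
(six-atom octahedra, so the framework COM is exact) plus pseudo-CDR3 loop
backbones, and places the four COMs directly so the interdomain torsion
equals the macrostate's target exactly: Vα COM at the origin, Vβ COM at
distance d on the z-axis, loop COMs offset by r at azimuths 0 and θ —
algebraically identical to rotating the β side about the Vα–Vβ axis.
Defaults d = 40 Å, r = 15 Å match variable-domain dimensions. Macrostate
labels are drawn i.i.d. from occupancies or from a label-level Markov
chain; torsion spread is controlled in degrees (`angle_sigma_deg` — the
quantity the distribution tests need to prescribe directly) and coordinate
noise in Å (`jitter_sigma`). Optional state-specific loop ψ means couple the loop
conformation to the label — with the coupling on, the pipeline must find
macrostates whose interface-angle distributions differ; with it off, the
shuffled-null behaviour must hold.

What passing on this test bed does **not** show: force-field accuracy,
convergence of real all-atom sampling, solvent or sterics effects, or that
real CDR3 dynamics is Markovian at any particular lag. It shows that every
estimator in the chain recovers known inputs under the model assumptions,
with the documented tolerances.

## Problem sizes

The recovery experiments use 3-state hidden chains at 50,000 frames × 5
seeds with 50 microstates; the ensemble analysis in `analysis/` uses
20,000 frames and 100 microstates; metadynamics runs 2·10⁵–6·10⁵ steps.
These sizes give estimator errors well inside the documented tolerances
(stationary probabilities to ~±0.02, slowest timescale to ~10 %, barrier
to ~1 %) while keeping every script in the minutes range on one CPU. The
150-microstate production default is exposed in config; at 50-state
density per basin the discretisation error is already negligible for the
synthetic systems.

## Known limitations

- PCCA+ without the crispness refinement can produce mildly non-crisp
  memberships on weakly metastable spectra; the spectral-structure guard
  raises before the decomposition becomes meaningless.
- The CK bootstrap underestimates uncertainty when segments are shorter
  than the slowest relaxation.
- The binary trajectory container stores float32 (≈1e−4 Å at protein
  scale); bit-exact round trips need the PDB path with pre-rounded
  coordinates.
- KS p-values at α = 0.05 inherit the discreteness of D: the realised test
  size oscillates with sample size around the nominal level.
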