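# Methods

This note documents the models, conventions and numerical choices behind
`glycopmf`, and what the synthetic surrogate does and does not emulate.

## Geometric monitors

A `Frame` is an ordered set of uniquely labelled atoms with coordinates in Å.
Labels are free strings matched exactly; no PDB-name normalization is
attempted, because the synthetic generators control their own labels and
real trajectories can map names explicitly at load time.

* **Reaction coordinates** (`RCSpec`) are signed linear combinations of
  interatomic distances, Σᵢ wᵢ·d(aᵢ, bᵢ). This covers the coordinates used
  to follow inverting glycosidase mechanisms: single distances (glycosidic
  C1–O4 cleavage, nucleophile O–C1 approach) and distance differences for
  proton transfers (donor–H minus acceptor–H, positive once the proton has
  crossed over). The cleavage coordinate is oriented so that larger values
  mean more dissociated (bond intact ≈ 1.5 Å, cleaved ≈ 3.2 Å).
* **Hydrogen bonds** use a geometric criterion: H···acceptor distance
  ≤ 2.5 Å and donor–H···acceptor angle ≥ 120°, both configurable. The
  distance cutoff is the common heavy-atom-independent convention and
  comfortably contains both ordinary H-bonds (H···A ≈ 1.8–2.0 Å) and
  shared-proton arrangements (≈ 1.0–1.3 Å) encountered along a
  proton-transfer pathway. The measured geometry is always returned so the
  caller can apply a different criterion post hoc.
* **Ring-plane axiality**: the angle between a bond vector and the ring
  mean plane, in [0°, 90°], with 90° = perpendicular (axial). The plane is
  the Cremer–Pople mean plane of the six ring atoms — deliberately the same
  construction the puckering module uses, not a least-squares fit — so a
  single plane convention holds across the package.
* **RMSD** is the least-squares superposition minimum (Kabsch). The optimal
  rotation comes from `scipy`'s `Rotation.align_vectors`; the residuals are
  then recomputed explicitly because the solver's reported
  root-sum-square distance is produced by cancellation of large norms and
  loses about seven digits near zero, which would mask the exact
  rigid-motion invariance the operation guarantees. Selections of fewer
  than 3 atoms, or collinear selections, are rejected (the rotation would
  be underdetermined).

## Cremer–Pople puckering

Atom ordering is fixed as O5, C1, C2, C3, C4, C5 (j = 1..6). After
translating to the geometric centre, the unique mean plane is defined by the
two trigonometrically weighted sum vectors R′ = Σ rⱼ sin(2π(j−1)/6),
R″ = Σ rⱼ cos(2π(j−1)/6), and the out-of-plane displacements zⱼ = rⱼ·n̂
(which sum to zero by construction) give

    q₂ cos φ =  √(1/3) Σ zⱼ cos(4π(j−1)/6)
    q₂ sin φ = −√(1/3) Σ zⱼ sin(4π(j−1)/6)
    q₃       =  √(1/6) Σ (−1)^(j−1) zⱼ

with Q = √(q₂² + q₃²) and cos θ = q₃/Q. Under this sign convention θ = 0 is
the ⁴C₁ chair of D-pyranoses — the choice that makes the standard
carbohydrate conformer names reproducible. The Stoddart projections are
q_x = q₂ sin φ, q_y = q₂ cos φ.

The inverse transform places atoms on a circle (traversed so the mean-plane
normal is +z) with zⱼ = √(1/3) q₂ cos(φ + 4π(j−1)/6) + √(1/6) q₃ (−1)^(j−1);
forward∘inverse is the identity on (Q, θ, φ) to 10⁻⁶ for Q ≥ 0.1 Å, which is
both a correctness check and the basis of the synthetic ring generator.

**Classification** is nearest-vertex by great-circle distance on the
(θ, φ) sphere against a fixed 38-vertex canonical table: chairs at the
poles; 6 boats and 6 skew-boats alternating every 30° in φ on the equator
(¹S₃ at φ = 210°, ²,⁵B at φ = 120° under the ordering above); 12 envelopes
at θ = 54.74°/125.26° and 12 half-chairs at θ = 50.84°/129.16° (the ideal
positions of those forms). No region polygons are drawn — published
Stoddart-diagram region boundaries are qualitative — so the label is always
the nearest ideal form, with the geodesic distance reported. Rings with
Q < 0.1 Å are labelled "planar" because θ and φ are numerically unstable
near zero amplitude. The absolute φ origin depends on the atom-ordering
convention; conformer names, not raw φ values, are the stable comparison
surface across implementations.

The **itinerary** summary assigns frames to named, non-overlapping RC2
intervals (defaults: reactant 1.5–1.8 Å, transition state 2.0–2.3 Å, product
2.4–3.2 Å), reporting per-region conformer fractions (summing to one in each
nonempty region) and mean/SD of (q_x, q_y). Frames outside all regions are
ignored; empty regions are reported with a count of zero.

## WHAM

The unbiased profile is obtained by iterating the standard self-consistency
equations in log space (log-sum-exp throughout), gauge-fixed to F₁ = 0,
until the largest per-window free-energy change is below tol·k_BT
(default tol = 10⁻⁷, max 10⁵ iterations; the default problem converges in a
few thousand iterations in a couple of seconds). Defaults: bin width 0.02 Å,
T = 300 K, k_B = 0.0019872041 kcal/mol/K.

* **Bias convention**: w(x) = f_b·k·(x − c)², with f_b = ½ by default and
  configurable, since both the ½kx² and kx² conventions circulate for
  quoted force constants. The Langevin generator shares the same `f_b`, so
  recovery tests are self-consistent by construction.
* **Binning** is aligned to integer multiples of the bin width, making
  histograms reproducible independent of sample order.
* **Connectivity**: if the pooled histogram has an interior empty gap, WHAM
  raises an error naming the gap instead of silently bridging it — an empty
  interior bin means the window ladder failed to overlap and any profile
  spanning it would be an extrapolation.
* The probability density is normalized (Σ P·Δξ = 1, exposed as
  `log_prob`) before G = −k_BT ln P is anchored to zero at its minimum.
* Only a 1-D profile is reconstructed. In the motivating application the
  accompanying coordinates (proton transfers, nucleophile approach) are
  incremented together with the cleavage distance along the pathway; that
  coupling lives in how the input samples were produced, not in the WHAM
  dimensionality.

`direct_histogram_pmf` — plain Boltzmann inversion of an unbiased
histogram — is kept as an independent oracle: on (effectively) unbiased
samples WHAM must agree with it bin by bin, and does to < 0.05 kcal/mol in
the test suite.

**Landmarks** are the argmin of G inside a reactant window and a product
window plus the argmax strictly between them, each refined by the vertex of
the parabola through the extremal bin and its two neighbours. The quadratic
refinement is skipped at the edge of the populated range, and an interior
"maximum" that is not a local maximum (a monotonic rise toward the product
window) is an error, not a landmark. At the surrogate's slope-discontinuous
curvature (the reactant node joins a harmonic wall on one side and a cubic
segment on the other) the three-point parabola has an intrinsic bias below
half a bin width, well inside the reported tolerances.

**Profile comparison** (`profile_sd`) is the RMS pointwise difference over
bins matched by centre within half a bin width, after re-anchoring both
profiles to zero at their reactant minimum (by default the global minimum;
an explicit anchor window can be supplied, since published profile-to-profile
spreads rarely state their anchoring convention).

## The synthetic surrogate

The surrogate exists because the physical data source — QM/MM sampling of a
solvated enzyme — is far beyond desk scale. It reproduces the *statistical
structure* the analysis consumes, with landmark values taken from the
published CelS profile, so that recovery of those landmarks validates the
machinery end-to-end.

* **Surface**: C¹ cubic-Hermite interpolation through (position, energy)
  nodes — defaults (1.5, 0), (2.17, 19), (3.2, 5), all flagged stationary
  (zero slope) — with harmonic walls (default 100 kcal/mol/Å²) beyond the
  outer nodes, matched in value and slope. Gradients are analytic; a
  finite-difference check is part of the suite. The reaction free energy
  node uses 5 kcal/mol, the value belonging to the same replicate as the
  19 kcal/mol barrier.
* **Dynamics**: overdamped Langevin motion on U(x) plus the window bias,
  integrated with a Heun predictor–corrector step at dt = 0.1, D = 10⁻³
  (nominal step ≙ 0.001 ps, so the default 10,000 + 10,000 steps mirror a
  10 ps + 10 ps window protocol). The Heun step is used rather than plain
  Euler–Maruyama because at these parameters the Euler stationary variance
  of a k = 500 kcal/mol/Å² window is inflated by ≈ 4%, a bias of the same
  order as the accuracy targets; the Heun bias is O(a²) ≈ 0.2%. A stability
  precondition dt·D·(k_bias″ + max|U″|)/k_BT < 0.5 is enforced with an
  explicit error. Only the stationary distribution matters for the PMF;
  time units are nominal.
* **Windows**: 42 evenly spaced centres over [1.3, 3.5] Å with
  k = 500 kcal/mol/Å² by default — the bond-breaking force constant of the
  reference protocol; the window count matches it, and the range is an
  assumption (the original spacing is not printed) chosen to bracket both
  minima with margin. Per-window sub-seeds are `seed + index`, so the
  dataset is reproducible window by window and independent of execution
  order.
* **Ring itinerary**: anchors on the puckering sphere as a function of RC2,
  great-circle interpolation between them, linear interpolation of Q, plus
  Gaussian noise (tangent-plane components of sd 8° and amplitude sd
  0.03 Å — magnitudes typical of thermal puckering fluctuations). The
  default path holds the ¹S₃ vertex through the reactant basin
  (anchors at 1.5 and 2.0 Å), switches sharply to ²,⁵B across 2.0–2.1 Å,
  holds it through the barrier region to 2.3 Å, and relaxes to the ⁴C₁ pole
  by 2.5 Å. The plateau-and-switch shape matters: the reported data show
  the projections changing abruptly near the transition state and
  oscillating around zero past 2.4 Å, and a single uniform drift between
  the three vertices would instead spend most of the reactant region near
  intermediate boat forms that are not part of the itinerary. The
  transition-state amplitude Q = 0.45 Å models the ring flattening of the
  oxocarbenium-like state (C1–O5 partial double bond); it is a modelling
  choice, not a measured value. Geometries are produced by the inverse
  puckering transform on a 1.45 Å ring — idealized rings, with no bond-length
  alternation, substituents or environment.

**What passing tests show — and do not.** Recovery of the construction
landmarks from the surrogate validates the umbrella/WHAM/landmark machinery
and the puckering/classification/itinerary machinery under realistic noise
and sample sizes. It does not validate anything about real enzymes: the
surrogate has no solvent, no coupled coordinates, a memoryless 1-D dynamics,
and its ring stream is generated from the very conformational path the
analysis is asked to find. The two-replicate profile spread measured here
(≈ 0.1 kcal/mol) is an order of magnitude smaller than published QM/MM
replicate spreads, because the surrogate sampling problem is far easier than
the physical one; the comparison against the published spread is therefore a
bound, not an equality.

## Degenerate inputs and tie-breaks

* Planar rings (Q = 0): valid puckering result with θ, φ undefined (NaN);
  classification below Q = 0.1 Å returns "planar".
* Collinear ring atoms: geometry error (no mean plane).
* Classification ties: broken by canonical-table order (chairs first, then
  half-chairs, envelopes, boats, skew-boats, north before south).
* Windows require k > 0 and at least one finite sample; an effectively
  unbiased window is expressed with a tiny k rather than k = 0.
* Quadratic landmark refinement falls back to the bin centre when the
  three-point parabola is degenerate or its vertex falls outside the
  neighbouring bins.

## Problem sizes

Default scientific runs use 42 windows × 10⁴ production samples (4.2 × 10⁵
samples per profile), 0.02 Å bins, and 2,000-frame ring trajectories; the
statistical property tests use 10⁵–6 × 10⁵ samples where a 5% or
0.05 kcal/mol tolerance demands it. These sizes put every statistical
tolerance several standard errors inside its band while keeping any single
analysis in seconds.
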