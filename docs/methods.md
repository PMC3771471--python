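# Methods

This note records the model assumptions, the discretization and its
exactness properties, the tunable parameters, and the design decisions
taken where the design was genuinely open.  Nothing here states an
empirical number that the test suite or `scripts/acceptance.py` does
not itself compute.

## Continuum model and scope

The package implements the idealized *continuum* measurement model of
EIT: currents and voltages are square-integrable functions on an open
boundary arc Σ of the unit circle, with zero integral mean.  Electrode
models (gap/shunt/complete), complex admittivities, 3-D domains and
half-space geometries are out of scope.  The domain is the unit disk;
other smooth domains can only enter through mesh import, and the
analytic oracles and closed-form dipole traces then no longer apply.

The data operator is the Neumann-to-Dirichlet (NtD) map Λ(σ), and the
reconstruction target is the region where σ differs from a reference
σ₀ — more precisely its *outer support* relative to Σ: parts of the
anomaly boundary data cannot distinguish (holes not connected to Σ
through the background) are filled in.  This is a property of the
problem, not of the implementation.

## Discretization and what is exact

* **Finite elements.** Piecewise-linear (P1) triangles on a structured
  disk mesh (concentric rings, 6·i vertices on ring i, Delaunay
  connectivity), boundary vertices snapped to the unit circle; default
  mesh size h = 0.03, uniform 1→4 refinement with midpoint re-snapping.
* **Grounding.** The pure-Neumann problem is grounded by one mean-value
  constraint over ∂Ω via a Lagrange multiplier, matching the zero-mean
  potential space; no vertex is pinned.
* **Conductivity sampling.** σ is evaluated once per triangle at the
  centroid.  Piecewise-constant phantoms are therefore represented
  exactly, and the energy identities below hold verbatim.
* **Boundary basis.** Trigonometric functions restricted to Σ in fixed
  order (cos θ, sin θ, cos 2θ, …), mean-subtracted and Gram–Schmidt
  orthonormalized in a composite Gauss–Legendre quadrature on the arc
  parameter (≥ 12 panels per basis order, 4 Gauss points each).  On the
  full circle this reproduces cos kθ/√π, sin kθ/√π exactly.
* **NtD assembly.** Boundary loads and trace projections use the *same*
  quadrature, so the discrete NtD matrix B'A⁺B is symmetric by
  construction and the energy identity g'Λg = ∫σ|∇u|² is exact to
  round-off.

Because both conductivities of a comparison are assembled on the same
mesh, basis and load vectors, the two-sided monotonicity bounds

    ∫(σ₀−σ₁)|∇u₀|²  ≤  g'(Λ₁−Λ₀)g  ≤  ∫(σ₀/σ₁)(σ₀−σ₁)|∇u₀|²

are *identities-plus-positive-terms* for the Galerkin pair and hold to
round-off (checked at 1e-10 relative slack), not merely up to
discretization error.  The same applies to the virtual-measurement
adjointness ⟨L_D F, g⟩ = ⟨F, L_D* g⟩ and to the Gram identity
g'M_E g = ∫_E|∇u₀|².  Discretization error only enters where the
discrete operator is compared with the *continuum* one: NtD eigenvalues
vs the separation-of-variables oracles (1/k homogeneous;
(1/k)(1−μρ^{2k})/(1+μρ^{2k}), μ=(a−1)/(a+1), concentric), observed at
≈0.5% for modes k ≤ 8 at h = 0.02 and decreasing under refinement.

## Dipole traces

The dipole source d·∇δ_z is read as an x-derivative; with that
convention the boundary trace on the homogeneous disk is
(1/π)·d·(x−z)/|x−z|² (image construction), and the global sign is fixed
once by agreement with the FEM construction.  Since the PDE determines
Φ_{z,d} only up to a constant, every trace is mean-subtracted on Σ
before projection.

For general σ₀ that is *constant near z* (the setting in which the
dipole exists), the trace is computed by a **mollified solve**: the
right-hand side is realized weakly as ∫ψ_ε(x−z) d·∇w dx with a radial
C¹ bump ψ_ε of width ε (default 2h), which keeps the zero-total-flux
compatibility exact and needs no special quadrature.  A
singularity-subtraction construction (free-space dipole scaled by
1/σ₀(z) plus a FEM correction) was considered and rejected: it moves
the singularity into the correction's right-hand side without improving
accuracy at the ε = 2h operating point, where the mollified trace
already agrees with the closed form to ≈0.5% in relative L².  Points
where σ₀ is discontinuous are rejected (the mollifier support must not
meet a σ₀ jump or ∂Ω).

## The discrete range test

* **Truncation.** Modes of |Λ(σ)−Λ(σ₀)| with |λ_k| ≥ ε_rel·|λ₁| are
  retained (default ε_rel = 1e-12, guarding round-off noise), with a
  hard cap of K−2 modes.  No rigorous discrete convergence criterion is
  known for this truncation; the defaults are a working regularization,
  not a theory.
* **Directions.** The criterion holds for every single unit direction
  d; the default uses {(1,0), (0,1)} combined by the harmonic mean of
  the per-direction indicators, which suppresses the orientation
  artifacts a single dipole direction produces.
* **Definiteness.** The sign of σ−σ₀ is auto-detected from the extreme
  eigenvalues of the NtD difference and logged; the spectral absolute
  value makes the criterion itself direction-agnostic.
* **Degenerate data.** If ‖Λ(σ)−Λ(σ₀)‖ is at round-off level the map is
  flagged degenerate and the mask left empty rather than thresholding
  noise.
* **Threshold.** The mask keeps points with finite indicator
  ≥ c·(max finite indicator).  The Picard series diverges as z
  approaches the anomaly boundary from inside, so the indicator decays
  continuously to the exterior level there; a half-max cut therefore
  keeps only the anomaly core.  The default is **c = 0.1**: on the
  reference disk phantom (radius 0.3 at (0.3,0), contrast +1, K = 16,
  h = 0.02) the Jaccard overlap with the true disk exceeds 0.5 for
  every c in [0.003, 0.2] and no exterior point enters the mask for
  c ≥ 0.05, so 0.1 sits centrally on the stable plateau.  The indicator
  spans several orders of magnitude; users comparing contrast levels
  should look at the values, not only the mask.

## Indefinite anomalies and the excluded region

With mixed-sign contrasts the method's definiteness assumption fails
globally.  Given an a-priori region E containing the minority-sign
part, the data operator is shifted by γ·α·M_E (σ ≤ σ₀ outside E) or the
comparison is flipped and shifted by γ·β·M_E (σ ≥ σ₀ outside E), with
α > ‖σ−σ₀‖_∞ and β > ‖(σ₀/σ)(σ₀−σ)‖_∞ supplied by the user.  The shift
factor γ defaults to 2: the two-sided energy bound that makes the
shifted operator's range equal that of L_{D∪E} is derived with the
factor 2, while the bare range statement is often quoted with factor 1;
since any positive multiple yields the same range, the factor is
exposed as a parameter and not adjudicated.  With E = ∅ the indefinite
routine delegates to the definite one, bit for bit.

One caveat on the *constants* of the shifted bound (the range equality
itself is unaffected): the upper constant 1 in

    g'(Λ(σ)−Λ(1)+2M_E)g ≤ ∫_{D−∪E}|∇u₀|²

cannot hold for arbitrary phantoms — adding 2∫_E to the exact chain
gives the upper envelope ∫_{D−} − ½∫_{D+} + 2∫_E, which with E = D+
exceeds ∫_{D−∪E} whenever the D+ energy is near its envelope.  The
bound is informative exactly when the D− gradient energy dominates the
difference-field energy (sufficient, to first order:
∫_{D+}|∇u₀|² ≤ ∫_{D−}|∇u₀|² per current).  The reference indefinite
phantom is chosen in that regime — a small positive disk (r = 0.15 at
(0.4, 0)) against a larger, deeper-reaching negative disk (r = 0.25 at
(−0.45, 0)), E = D+ — and the acceptance script reports the measured
min/max ratio.

## Synthetic scenarios: what they emulate and what not

The generator produces disk-shaped anomalies (1–3 per scenario, radii
0.10–0.25, centers at least 0.2 from ∂Ω, mutual clearance 0.1),
contrasts +0.5…+1.5 or −0.25…−0.75 on background 1 — moderate, well
separated conductivity jumps of the kind the method's assumptions
cover.  Indefinite scenarios place mixed signs and return an excluded
region E of slightly inflated disks covering the minority sign.  All
randomness flows from one integer seed; identical seeds reproduce
scenarios byte for byte.

These scenarios deliberately do **not** emulate: measurement noise
(a symmetric relative Gaussian NtD perturbation exists as an option,
default off, and no noise analysis is claimed), electrode discreteness,
contact impedance, anisotropy, contrasts without a jump (σ−σ₀ decaying
continuously to 0), or anomalies touching ∂Ω.  Passing tests therefore
demonstrate correctness of the operators and of the method's discrete
surrogate under the continuum model — not robustness on experimental
EIT data.

## Numerical choices and degenerate inputs

* Symmetry guards: matrices entering the spectral absolute value may be
  asymmetric up to 1e-8 relative (they are symmetrized); assembled NtD
  matrices must be symmetric to 1e-10.
* Eigenvalues are sorted by decreasing magnitude; ties keep LAPACK
  order (deterministic for identical inputs on one platform).
* Region masks resolve to whole triangles by the centroid rule; pixel
  masks use 4-connectivity, and a complement component is "connected to
  Σ" iff it contains a boundary pixel whose center angle lies in Σ.
  Corridors thinner than one pixel can be misclassified — the surrogate
  is resolution-dependent by construction (masks are checked to move
  < 5% in area under grid doubling on smooth shapes).
* The inner support is realized at a user level δ (|σ−σ₀| ≥ δ) and
  eroded by one pixel: a grid surrogate of the essential-infimum
  definition, documented as such.
* +∞ is a legal indicator value (test function orthogonal to all
  retained modes); it is excluded from masks and serialized as the
  literal `inf`.
* Sampling grids stay in the interior (default margin 0.1 from ∂Ω);
  the criterion is undefined on the anomaly boundary itself, and points
  near ∂D have no guaranteed behavior.

## Problem sizes

The verification and acceptance runs use K = 16 boundary modes with
h = 0.03 for the round-off-level identities (monotonicity chain,
adjointness, energy-ratio bounds; 16 trigonometric currents each) and
h = 0.02 (≈ 11k vertices) for the accuracy and reconstruction checks,
with 40×40 sampling grids (1020 interior points) and 96×96 ground-truth
pixel grids; 50 seeded scenarios exercise the mask semantics.  These
sizes make every check reproducible in seconds on a single CPU while
keeping the oracle comparisons well inside their tolerances.

## Known limitations

* No convergence theory for the truncated Picard criterion is claimed;
  the eigenvalue floor and threshold are practical defaults.
* Reconstruction quality degrades for anomalies close to ∂Ω or very
  small relative to 1/K; the basis order bounds the achievable angular
  resolution.
* Whether points inside holes of the anomaly satisfy the range
  criterion is open; the package *reports* hole indicators (they are
  observed at anomaly-like levels on the annulus phantom, consistent
  with outer-support recovery) but asserts nothing about them.
* Partial-arc data (Σ ≠ ∂Ω) is supported throughout, but the
  reconstruction examples and defaults are tuned for full-boundary
  data.
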