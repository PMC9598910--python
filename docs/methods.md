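# Methods

## Constitutive model

The intestinal wall is treated as an incompressible fiber-reinforced
membrane whose in-plane stiffness comes from four collagen fiber
families embedded in a soft isotropic matrix:

* `a01 = e1` — longitudinal muscular layer (lm),
* `a02 = e2` — circumferential muscular layer (cm),
* `a03, a04` — submucosal pair (sm) at ±α to the longitudinal axis
  (default α = 30°).

The strain energy uses the standard volumetric/isochoric split
`F = (J^{1/3} I) F̄`, with modified invariants `Ī1 = tr C̄` and
`Ī4,i = a0i · C̄ · a0i` (squared fiber stretch):

    ψ = κ0/2 (J−1)² + μ0/2 (Ī1 − 3)
        + Σ_mus  k1_mus/(2 k2_mus) [exp(k2_mus (Ī4−1)²) − 1]
        + Σ_sm   k1_sm /(2 k2_sm ) [exp(k2_sm  (Ī4−1)²) − 1]

Fiber terms are tension-only (`Ī4 ≥ 1`), the two muscular families share
one `(k1, k2)` pair and the submucosal ±α pair another; no fiber–fiber
interaction or dispersion is modeled.  The analytic Cauchy stress is the
push-forward of `2 ∂ψ/∂C`; its deviatoric fiber terms are
`(2/J) ψ′(Ī4) dev(F̄ A0i F̄ᵀ)`.  Correctness is guarded by a
finite-difference oracle: the analytic stress must match the central
difference of the total energy, pushed forward, to relative 1e−5 on
random deformations (it agrees to ~1e−9 in practice).

### Units and modes

MPa–mm–N throughout; stretches dimensionless.  Exact incompressibility
(`kappa0 = None`) is the default for all curve-level work — the
force-to-true-stress conversion `σ = P λ/(L T)` already assumes it — and
the plane-stress condition `σ_zz = 0` then supplies the pressure in
closed form.  The penalty mode `p = κ0 (J−1)` exists for the single
brick element; κ0 defaults to `1e4 × max(μ0, k1_mus, k1_sm)`, large
enough that the brick solution is within ~1e−4 mm of the incompressible
one.

## Damage

Only the collagenous layers damage; the matrix and volumetric parts do
not.  Each layer k ∈ {lm, cm, sm} carries a scalar `D_k ∈ [0, 1]`
multiplying its energy and stress by `(1 − D_k)` (the two submucosal
fibers pool into one energy and share one scalar; the two muscular
fibers are damaged independently).  The driving quantity is the
equivalent strain `τ = √(2 ψ̄_k)` of the *undamaged* layer energy, with
the closed-form evolution

    D(τ) = 1 − (τ0/τ) exp(A (1 − τ/τ0)),   A = (gf/τ0² − 1/2)^{-1},

a state function of the history maximum of τ.  This makes
irreversibility structural: unloading and elastic reloading freeze D,
every increment dissipates `Σ_k Ḋ_k ψ̄_k ≥ 0`, and the ramp
discretization affects only how the trajectory is sampled, never the
final state (halving the step count changes final stresses by ≪0.1%).
Well-posedness requires `gf > τ0²/2`; a lower τ0 means earlier onset, a
lower gf a steeper (more brittle) post-onset drop.  In stress evaluation
`(1 − D)` is floored at 1e−12 to avoid exactly singular tangents during
root-finding.

## Protocol solving

Biaxial paths use `F = diag(λL, λC, λz)`; shear is ignored on this path
(measured shear strains are orders of magnitude below the normal
strains), while the tensor engine still accepts full `F`.  In
incompressible mode `λz = 1/(λL λC)` and the in-plane stresses reduce to

    σLL = μ0 (λL² − λz²) + 2(1−D_lm) ψ′(λL²) λL²
          + 4(1−D_sm) ψ′(Ī4_sm) cos²α λL²

(and symmetrically for σCC), cross-checked against the tensor engine.
The brick simulation ramps `DX, DY` proportionally on a 1 mm cube (one
constitutive evaluation per increment — a single element deforms
homogeneously, so no mesh is needed), solving `σ_zz(λz) = 0` by Brent
root-finding with the bracket `[0.2, 1.2] ×` the incompressible guess,
expanded geometrically on failure; accepted steps satisfy
`|σ_zz| < 1e−9` MPa.  Under in-plane tension the deviatoric normal
stress is negative, so the penalty pressure is positive and `J ≥ 1`:
the penalty `DZ` approaches the incompressible value `1/(λx λy) − 1`
monotonically from above as κ0 grows.  A static plane-stress model can
therefore never produce `J < 1` at this loading; thickness contractions
beyond the incompressible value reported for dynamic FE runs with an
unstated bulk modulus are outside what this quasi-static model can
reproduce, by construction.

## Synthetic rig data

The generator emulates the equibiaxial protocol: 40 mm × 40 mm
specimens, thickness fixed at the cohort mean 1.188 mm or drawn
uniformly from the observed 0.68–2.15 mm range (the uniform law is a
stand-in; real thickness distributions are not uniform), crosshead speed
10 mm/min per axis (stretch increment 1/240 per frame at 1 Hz), ramp to
rupture.  Noise-free stresses come from the forward model; forces are
back-computed via `P = σ L T/λ`; measurement noise is multiplicative
Gaussian on the force channel (default 2% relative) plus an additive
0.01 N sensor floor — both placeholders, since no rig noise statistics
are available — and Green–Lagrange channels are `E = (λ²−1)/2`.

Rupture is emulated by truncating the record once **all three** layers'
damage exceeds 0.99 (configurable; `any_layer` mode is available).  The
complete-rupture rule was chosen because the rig stretches until the
specimen fails entirely, and because it ends the reference records at
λ ≈ 1.37–1.75 — bracketing the reported mean failure stretches — while
the any-layer rule would cut the S2/S4 records before their
circumferential layer ever activates, leaving those damage parameters
unidentifiable.  Preconditioning cycles are not generated: the model is
rate-independent and below-threshold cycles leave no state behind.
What passing tests show is therefore internal consistency (round-trip
parameter recovery, physics invariants), not fidelity to any effect the
generator omits: needle-tearing artifacts, strain-field heterogeneity,
viscoelasticity and inter-animal variability are all absent.

## Parameter identification

Both directions are fit simultaneously with equal weights (one parameter
set must explain both R²'s) over the ten free parameters
`{k1_mus, k2_mus, k1_sm, k2_sm, τ0 × 3, gf × 3}`; μ0 is pinned at its
1e−4 MPa floor (equibiaxial membrane data barely constrain it, and every
credible fit sits on the floor) unless explicitly released.  `k1`, `k2`
and τ0 are searched in log-space with bounds `k1 ∈ [1e−6, 1]` MPa,
`k2 ∈ [1e−3, 1e2]`; τ0 is bounded by `√(2W)` with W the measured
deformation work per unit volume (no layer can have seen a larger
equivalent strain than the total work allows); gf is reparameterized as
`gf = τ0²/2 (1 + e^u)` so feasibility holds at every trial point.

The landscape is multimodal, and random multi-start alone stalls in
local minima.  The solver therefore leads with a deterministic staged
basin search that exploits the equibiaxial protocol: both families see
the same invariant `λ²`, so the two stress directions form a pointwise
2×2 linear system in the family response functions
`f = k1 x e^{k2 x²}` (`x = λ²−1`), and log-linear regression of `ln f`
on `x²` over a damage-free toe segment yields both `(k1, k2)` pairs in
closed form.  Because the damage-free length is unknown, several
candidate segment lengths (10–85% of the record) compete; each candidate
is completed by a damage-only least-squares stage (threshold starts from
where each direction departs from the undamaged prediction, under every
plausible first-failing-layer assignment) and a joint trust-region
polish.  On noisy records the basin search runs on a Savitzky–Golay
smoothed copy (the pointwise decomposition divides by `x` and is
noise-dominated at the toe) and its winner is re-polished against the
raw data.  Sixteen seeded uniform multi-starts back this up, and the
overall best is refined at tight tolerance.  A `sequential` strategy
(hyperelastic frozen, damage-only refit) is available.

Quality control before fitting: each direction must rise monotonically
(lightly smoothed) to a global stress peak located beyond the first 30%
of the record — an early peak is the signature of grip tearing, not
tissue damage.  A separate predicate reports per-direction softening
(final-segment slope below the peak slope); requiring *concurrent*
softening in both directions is exposed in the config for cohort
selection, since curves without it carry no damage information, but is
off by default in `fit`.

Measured behavior under the default study conditions (computed by the
test suite, one CPU): noise-free records from all four reference rows
refit to machine precision (≪1% per parameter); with 2% force noise the
median relative error per parameter over 10 seeded replicates stays
below 15% (exponents compared on the log scale).

## Numerical choices

* Fiber exponents are capped at `exp(60)` so absurd trial points during
  optimization stay finite; the cap is far above any admissible state.
* `R² = 1 − SS_res/SS_tot` per direction, against the mean of the
  experimental stresses; undefined (error) for constant series.
* Damage trajectories are exported per frame
  (`lambda_L, lambda_C, tau_*, D_*`) so threshold crossings and failure
  ordering can be read off directly.
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; cohort generation spawns independent child seeds per curve
  and records them in the manifest, making outputs bitwise reproducible.

## Known limitations

* No fiber dispersion, no I5/I7/I8 coupling invariants, no active muscle
  tone, no viscoelasticity or preconditioning hysteresis.
* The damage model is local; softening materials in multi-element meshes
  would need nonlocal regularization, which a single material point does
  not exercise.
* The rupture criterion (damage cap on all layers) is a modeling stand-in
  for real specimen failure, which involves tearing localization the
  continuum model cannot represent.
* Identifiability of a layer's damage pair requires the record to cross
  that layer's threshold; records truncated earlier leave those
  parameters bounded only from below.
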