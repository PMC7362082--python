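# Methods

## Scope and assumptions

The model is one-dimensional along the fiber axis: every node of the
protofibril network carries a single scalar axial displacement, because
all forces in the element's free-body diagram are axial and only axial
force–extension is predicted. Loading is quasi-static — every node is in
force balance at each applied load, with no rate or time dependence — and
fully deterministic. Protofibrils are parallel and uninterrupted over the
whole fiber length; fragmentation into short (15–20 monomer) protofibrils
and stochastic interconnectivity are out of scope, as are entropic
(worm-like-chain) force contributions: the package's purpose is precisely
the nonlinear-spring alternative to WLC behavior.

## Units

Internal units are nm and pN everywhere (stiffness pN/nm, cubic stiffness
pN/nm³, energy pN·nm). Clot-scale inputs are entered in mm/μm and
converted where used: the eight-chain prefactor πD²vL/24 is evaluated with
D and L in μm and v in μm⁻³, making it a dimensionless effective fiber
count, and clot forces are reported in mN (1 mN = 10⁹ pN; the conversion
is recorded in the curve metadata). The choice of mN is cosmetic — no
reference values constrain it.

## Force laws

Four scalar laws (see `force_laws`): the monomer and binding laws are
linear + Heaviside-gated cubic; the knob–hole and γ–γ bonds are saturating
erf laws. Conventions chosen for reproducibility:

* H(0) = 1 at the cubic onset — immaterial since the cubic factor
  vanishes there, but fixed for bit-reproducibility.
* Compression (x < 0): laws applied as written — the linear term restores
  symmetrically, the cubic term stays off, and the erf laws are odd
  exactly. Tension-driven simulations never load springs in compression;
  the branch only stabilizes the solver.
* erf is evaluated by `scipy.special.erf` (abs error well below 1e-12).
* Each monomer half-spring uses constants (2k₁, 8k₂, d₂/2) so that two
  identical halves in series reproduce the whole-molecule law exactly.
* Every law has a closed-form antiderivative with energy(0) = 0; the
  equilibrium solver's residual is proven (by test) to equal the negative
  energy gradient, so energy minimization serves as an independent oracle.

The binding constants are coupled: k₆ = k₅/500 and d₅ = L_elem/4. When a
config overrides k₅ alone, k₆ follows the coupling (so k₅ = 0 switches the
binding force off entirely); an explicit k₆ that breaks the ratio is
accepted with a warning.

## Element topology

Per 46-nm element: strand B contributes one whole monomer
(D–E–D, two half-springs); strand A is half-staggered, with E-regions at
the element boundaries and two coincident D-nodes at the center joined by
the γ–γ spring; knob–hole springs connect each E to the opposite strand's
coincident D node(s) — two at the center, one at each boundary junction;
one binding spring spans the element end-to-end in parallel. Consecutive
elements share boundary nodes. The exact pairing of E to D via knob–hole
bonds is the one structural point the half-staggered geometry does not
fully pin down; it is isolated in `build_element_topology` so alternative
wirings are a one-function change.

The left strand ends are fixed. The load enters through two dummy nodes
rigidly tied to the right strand ends and to each other — a rigid yoke,
like the AFM probe attachment — each carrying the per-monomer force F, so
one protofibril (two strands) carries 2F, consistent with
F_fiber = (monomers per cross-section) × F. Rigid ties are exact
constraints (tied nodes share one degree of freedom), not stiff penalty
springs, which keeps the stiffness matrix well conditioned.

Derived counts round by ceiling: monomers per cross-section
= ⌈φ(D/2)²/r²⌉ (the π factors of the fiber and monomer cross-sections
cancel) and element count = ⌈L/L_elem⌉; values within 1e-9 of an integer
are taken as that integer first, so exactly-integral ratios are not
inflated by floating-point noise.

## Equilibrium solve and continuation

The total energy is strictly convex (every tangent stiffness is positive
and the graph is connected to a fixed node), so the equilibrium is unique
and equals both the root of the nodal force balance and the energy
minimum. The solver is a trust-region dogleg Newton iteration on the
residual with an analytic spring-assembly Jacobian — dense for small
systems, sparse LU for the full chain (the matrix is banded under the
axial node ordering). Convergence requires the residual 2-norm to fall
below the tolerance (default 1e-8 pN) or, when stiffnesses are scaled to
near-rigid values, below the machine-precision floor ~ eps·‖J‖·‖x‖ at
which smaller displacement updates are no longer representable.

Force continuation applies F on an even grid (default 500 steps, 0→200 pN
per monomer), warm-starting each solve from the previous step. A
non-converging step is retried once from the last good state with 10×
smaller sub-steps; if it still fails the step is recorded as the break
index and the curve is truncated — solver stall is the model's rupture
signature. No stretch cap is applied unless `break_extension_factor` is
set. With the default parameters the curve completes all 500 steps,
reaching λ ≈ 3.0.

Because all elements are identical and the rigid end yoke reproduces the
equal-displacement condition that mirror symmetry enforces at every
interior junction, the full-chain solution is an exact translation-stack
of the single-element solution. `fiber_curve` therefore solves one element
by default (seconds for 500 steps) and offers `full_chain=True`, which
solves all 261 elements explicitly and agrees with replication to solver
precision (~1e-11 relative; asserted at 1e-6 in the tests).

## Clot coupling

Model 2's curve is force-controlled; the eight-chain relation needs
stretch-controlled evaluation, so F_fiber(λ_f) is obtained by monotone
shape-preserving PCHIP interpolation of the sampled curve (passes through
every sample, no overshoot). Evaluation beyond the fiber curve's last
stretch is clot rupture: the clot curve truncates there rather than
extrapolating. The λ₁ grid (default 200 points to λ_max = 2.5) is an
output-resolution choice only.

## Sensitivity sweeps

Default grids: 9 radii evenly spaced over 25–225 nm at 12 μm length, and
10 lengths over 0.5–14 μm at 165 nm radius (the studied ranges; the grid
densities are package choices). Curves in a sweep share the force grid, so
long-format CSV output is rectangular. Trend checks compare force at fixed
stretch across radii, and extension (λ−1)·L at fixed force across lengths
— per-element stretch is length-invariant, so length sensitivity is an
extension-axis statement.

## What the defaults do and do not show

The default parameter set is a calibration against molecular-dynamics
pulling of fibrinogen and AFM bond-rupture measurements taken as given;
the package performs no fitting. Passing tests demonstrate internal
consistency (energy–residual identity, oracle equivalence, closed-form
limits, replication symmetry) and the qualitative geometry trends; they do
not validate against experimental fiber or clot curves, which users must
supply as two-column CSVs for RMS comparison (`--reference`).

## Known limitations

* Solver non-convergence is a numerical proxy for rupture; with the
  default parameters strand B can always carry the load, so the fiber
  never formally breaks within the 200 pN range — break behavior emerges
  only for parameter sets that exhaust the erf bonds' capacity.
* The knob–hole wiring ambiguity above; alternative pairings would change
  the partition of load between strands, though not the series-spring
  limits.
* One-dimensionality excludes bending, torsion and lateral fiber
  rearrangement; the eight-chain coupling inherits affine-deformation and
  incompressibility assumptions.
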