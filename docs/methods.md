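# Methods

## The model

`cdcpol` implements a mass-conserved bulk–surface reaction–diffusion model of
GTPase-driven cell polarisation.  The cell is the unit ball Ω with membrane
Γ = ∂Ω (the unit sphere).  Three forms of the GTPase Cdc42 are tracked: the
active, GTP-bound membrane form *u*, the inactive, GDP-bound membrane form
*v*, and the GDI-sequestered cytosolic form *V*.  Because the cytosolic form
diffuses orders of magnitude faster than the membrane-bound forms, the
cytosol is taken as well mixed (the fast-bulk-diffusion limit), and *V* enters
the membrane dynamics only through the mass-conservation functional

    V[u + v] = V0 − (1/|Ω|) ∫_Γ (u + v) ds,

so the total amount |Ω|·V + ∫_Γ (u + v) ds = |Ω|·V0 is an exact invariant.
The membrane dynamics are

    ∂u/∂τ = Δ_Γ u + γ f(u, v)
    ∂v/∂τ = d Δ_Γ v + γ (−f(u, v) + q(u, v, V[u+v]))

with

    f(u, v) = c2 v − u + u² v
    q(u, v, V) = c1 V (c_max − (u + v)) − c_minus1 v.

*f* collects GEF/GAP-mediated activation–inactivation plus a quadratic
positive feedback; *q* is the attachment flux of the cytosolic form onto the
membrane (saturating at the maximum membrane load c_max) minus dissociation.
All parameters are dimensionless; `nondimensionalise` maps a dimensional
rate-constant set onto them (concentrations scale with √(k₋₂/k₃), time with
R²/D_A).  γ is the reaction strength relative to membrane diffusion and is
proportional to the membrane area; d = D_I/D_A is the relative diffusivity of
the inactive form.

A note on signs: spatially averaging the *v* equation gives
dv̄/dτ = γ(−f + q0) — the sign pattern used throughout the package, because it
is the only one consistent with the surface equations and with mass
conservation (f converts between u and v without changing u + v; only q
exchanges mass with the cytosol).

## Homogeneous analysis

The well-mixed system replaces q by
q0(ū, v̄) = c1·a·(c_max − s)(m − s) − c_minus1·v̄ with s = ū + v̄,
a = |Γ|/|Ω| = 3 and m = V0/a.  Steady states satisfy f = q0 = 0; from f = 0
the inactive form is slaved, v = u/(c2 + u²), and substituting into q0 = 0
and clearing the (c2 + u²)² denominator yields a degree-6 polynomial in u.
Roots are taken from the companion matrix (a global method — a Newton
iteration alone can miss roots when up to six exist) and polished by Newton
steps on the unscaled residual.  Near-multiple roots (relative spacing below
1e−6) are flagged degenerate instead of being dropped or double-counted; for
simple roots the number of strictly positive steady states is even.

Physically valid states live in the trapping region
A = {u, v ≥ 0 : u + v ≤ min(c_max, m)}; homogeneous trajectories started in A
never leave it, which the test suite verifies over seeded ensembles of random
positive parameter sets.  A steady state can support diffusion-driven
instability only if √c2 < min(c_max, m) and u* ∈ (√c2, min(c_max, m)); the
simulation modules perturb the lowest-u* root in that bracket (the same rule
a local Newton solver with the bracket start guess would select).

## Turing classification

Perturbations split into the uniform (degree l = 0) mode, which feels the
mass-conservation coupling and is governed by the homogeneous Jacobian, and
inhomogeneous spherical-harmonic modes (l ≥ 1, k² = l(l+1)), which integrate
to zero over the sphere so the nonlocal term drops out; they are governed by
M(k²) = γ·J_loc − diag(k², d·k²), where J_loc linearises the reactions at
fixed V = V*.

The classification requires the uniform mode stable (trace < 0, det > 0 of the
homogeneous Jacobian) and distinguishes:

* **classic** — J_loc is stable but unequal diffusion opens an unstable band:
  det J_loc > 0 and d·a11 + a22 > 2√(d·det J_loc).  Impossible at d = 1.
* **non-classic** — J_loc is a saddle (det J_loc < 0): the instability comes
  from the bulk–surface mass coupling and exists for every d, including d = 1.

These algebraic conditions act on the continuous wavenumber.  This was a
deliberate design choice for the parameter-plane maps: the conditions are
γ-free, the non-classic region is then *exactly* independent of d, and the
classic regions are exactly nested in d (the band criterion is monotone in d
when a11 > 0 > a22, which holds throughout the classified regions).  The
dispersion relation over integer degrees is computed alongside and used where
γ matters: `dispersion` demotes a classification to `none` when no admissible
integer degree l ≥ 1 is actually unstable, and the simulator's early-time
growth rates are validated against it.  Points with |det J_loc| within 1e−9
(relative to the squared Jacobian scale) of the saddle/node boundary are
flagged indeterminate and excluded from region statistics with a logged count.

Default map ranges are c_minus1 ∈ (0, 0.1], c2 ∈ (0, 1] and c1 ∈ (0, 10]
(fixed c1 = 0.05 or c_minus1 = 0.05, V0 = 6, c_max = 3) at 200×200 resolution,
all overridable from the CLI.

## Surface simulation

The membrane is a subdivided icosahedron projected to the unit sphere
(trimesh provides the subdivision; level L has 10·4^L + 2 vertices).
Diffusion uses the cotangent Laplace–Beltrami stiffness matrix with
barycentric lumped mass; the discrete spectrum reproduces l(l+1) with
multiplicity 2l+1 to within 2% at level 4, which is the resolution used by
the tests and the acceptance script (level 5 is the production default).

Time stepping is IMEX backward Euler: diffusion implicit (sparse LU factors
cached per step size), reactions explicit, and V recomputed from the
functional after every step — making mass conservation exact in floating
point.  The step size grows by a factor 1.2 from dt = 1e−4 up to
dt_max = 5e−3 while the relative change per step stays below 1%, halves when
it exceeds 10%, and is additionally capped at 0.5/γ for the explicit
reactions.  dt_max = 5e−3 was chosen as the largest step at which the
polarised state is free of the spurious explicit-reaction oscillation visible
at dt = 1e−2 with γ = 25; halving it again changes the reported measures only
in the fourth digit.

Initial conditions perturb the selected steady state multiplicatively,
uᵢ = u*(1 + σξᵢ) with ξ i.i.d. uniform on (−1, 1), σ = 0.05 by default.  The
noise amplitude is the package's own choice of a small but resolvable
perturbation; only its seed-to-seed variability, not its magnitude, shows in
the final measures, since the unstable modes grow from any generic
perturbation.  Note that the perturbed field may exceed the trapping bound at
a few vertices — the trapping property binds the homogeneous system, not the
PDE pointwise — so this is reported as a warning, never an error.

A run terminates when the pole count and relative pole area are unchanged
and the field moves less than 1e−4 (relative max-norm) across a τ-window of
0.2, or at τ_max = 40.  Runs ending at τ_max with poles present are labelled
`max_tau` (multi-pole configurations can keep competing on slow timescales);
without poles, `no_pattern`.

## Pole recognition

Vertices with u ≥ u_min + θ(u_max − u_min), θ = 0.5, form the candidate set;
connected components under mesh adjacency are poles; components below 1% of
the surface area are discarded.  Midrange thresholding is the simplest rule
that is invariant under affine rescaling of the field and marks a single
circular spot as one pole; the 1% floor removes single-vertex speckle in
near-uniform fields.  Pole size is reported as a fraction (or percentage) of
the total membrane area.  Sweeps over d or γ run a fixed number of seeded
replicates per value (20 by default, fewer in the test suite) with per-run
seeds derived deterministically from a base seed, and report 5/50/95%
quantiles of pole size, polarisation time, pole count and the extreme
concentrations.

## What the defaults reproduce

With the classic kinetics (c1, c_minus1, c2) = (0.05, 0.04, 0.45), V0 = 6,
c_max = 3, d = 10, γ = 25 on a level-4 mesh, runs form a single pole with
final u_max ≈ 3.66 and relative pole area ≈ 26%; the non-classic set
(0.05, 0.03, 0.15) gives a single pole with u_max ≈ 4.18.  Sweeping γ over
{10, 20, 40, 80, 160} the median pole count first exceeds one at γ = 40 and
reaches five poles at γ = 160.  `scripts/acceptance.py` recomputes these
numbers from scratch.

## Numerical choices and limitations

* Integration of the homogeneous ODE system uses LSODA at rtol 1e−9;
  trapping checks tolerate 1e−6 excursions.
* Steady-state residuals are polished to ~1e−12; polynomial-root and Newton
  paths agree to 1e−8 wherever both converge.
* The well-mixed-cytosol reduction replaces the full bulk model with finite
  cytosolic diffusion.  Quantities tied to the bulk gradient (e.g. the exact
  polarisation times) are approximated; final pattern amplitudes and pole
  counts are insensitive to the reduction at large relative bulk diffusion.
* The mesh is a fixed sphere: membrane deformation, non-spherical geometries
  and pole drift/merging statistics over time are out of scope.
* Simulations at level 4 (2562 vertices) resolve unstable degrees l ≲ 25
  comfortably; the γ = 160 multi-pole regime is near the coarse end of that
  resolution, and pole counts there should be read as ±1.
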