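# Methods

`polycalib` is a desk-scale toolkit for molecular-crystal force-field
calibration: it evaluates lattice energies and cell geometries of rigid
molecular crystals under a point-charge + Lennard-Jones (LJ) model, and
recalibrates the LJ parameters against per-polymorph experimental targets
with multiobjective Bayesian optimization under a polymorph
stability-ordering constraint.  This note records the model, its
assumptions, the numerical choices, and what the synthetic test problems
do and do not demonstrate.

## Energy model

Nonbonded interactions only: pairwise LJ
`4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]` with geometric or Lorentz–Berthelot
combining rules, plus Coulomb interactions between fixed partial charges.
Units are global: Å, kJ mol⁻¹, elementary charges, degrees; the Coulomb
prefactor is e²/4πε₀ = 1389.35458 kJ mol⁻¹ Å e⁻².

**Electrostatics.** Classical Ewald summation (not mesh-based): the
supercells handled here are at most a few thousand sites, where O(N^1.5)
Ewald is fast and, unlike an interpolating mesh, exactly testable against
lattice-sum constants.  The real-space part sums `erfc`-screened
interactions over explicit lattice images, so the cell may be *smaller*
than the cutoff — important for the few-molecule crystals used in
calibration; no "cutoff too large for the cell" restriction applies.
Tinfoil (conducting) boundary conditions are assumed: no surface-dipole
term, so polar cells with a net dipole moment have a well-defined energy.
The splitting parameter α and the reciprocal cutoff are derived from a
requested relative accuracy (default 10⁻⁶) by the standard error
heuristics, and the total is invariant to the split within that accuracy
(verified over a factor-of-two range of α).  Non-neutral cells are
rejected outright; no uniform-background correction is implemented
because every system of interest is neutral.

**Dispersion tail.** Beyond the LJ cutoff (default 9 Å) a
uniform-density analytic tail is added per type pair,
`(8π N_a N_b ε σ³ / 3V)[(σ/r_c)⁹/3 − (σ/r_c)³]`.  On a crystal the
uniform-density assumption is approximate; the truncated+tail energy
converges to the fully summed energy as the cutoff grows, which is the
property the tests assert.

**Exclusions and the vacuum reference.** The default exclusion policy is
*rigid-molecule*: all intramolecular nonbonded pairs are excluded and
molecules are rigid bodies.  The per-molecule lattice energy is
`E_latt = E_total/N − E_single`, and under this policy `E_single = 0` by
construction (the vacuum molecule has no remaining interactions), so
`E_latt = E_total/N`.  A *bonded-graph* policy (1-2/1-3 excluded, 1-4
scaled, defaults 0.5/0.5, configurable) is provided for flexible-molecule
experiments; it requires an explicit bond list and a caller-supplied
`E_single`.

**Alchemical pair potentials.** For solution-thermodynamics bookkeeping
the package exposes the linear Coulomb decoupling `(1−λ)·C q_i q_j/r` and
the Beutler soft-core LJ form with α = 0.5, which is finite at particle
overlap for λ > 0.  One analytic subtlety: the soft-core energy is *not*
monotone in λ at fixed separation anywhere in σ ≤ r < 2^{1/6}σ (it dips
before rising to zero); monotonicity holds from the LJ minimum outward,
and the tests are written accordingly.

## Structure relaxation

Relaxed crystals are produced by a deterministic three-stage procedure:
(1) rigid-body position minimization at fixed cell, (2) relaxation of the
free cell lengths under the symmetry constraint, (3) a final position
minimization at the fixed optimal cell.  The intermediate stage that a
simulation workflow would perform with barostatted dynamics is replaced
here by nested 0 K minimization: the outer loop line-searches each free
lattice-vector length (bounded parabolic search, fractional molecular
centers held fixed, intramolecular geometry rigid) and then re-relaxes
positions, until the energy gain per cycle falls below `cell_tol`.  A
consequence worth flagging: the final cell is the line-search optimum
rather than a finite-temperature ensemble average, so finite-temperature
cell fluctuations and thermal expansion are outside the model.

Position minimization is adaptive-step steepest descent on molecular
translations (and optional axis-angle rotations, off by default for the
high-symmetry fixtures), converged when the largest force component on
any rigid body is below 0.01 kJ mol⁻¹ Å⁻¹ (= 0.1 kJ mol⁻¹ nm⁻¹).  Forces
are analytic for every energy term, including the Ewald reciprocal and
exclusion-compensation parts.

Symmetry families are expressed as pinned angles (monoclinic α = γ = 90°;
trigonal α = β = 90°, γ = 120°; all three lengths free in every preset).
Because the relaxation only rescales lattice vectors, pinned angles are
preserved to machine precision.  Cell collapse (volume below 25% of the
start) raises an instability error, which the objective layer converts to
a sentinel value.

**Box canonicalization.** Reported cell parameters are derived from a
canonical lattice basis: the cell matrix is rotated to lower-triangular
row-vector form (a along x) via the Cholesky factor of its Gram matrix,
then reduced by integer row operations until every off-diagonal element
is at most half the corresponding diagonal.  This undoes any skew
representation of the same lattice, is idempotent, preserves volume
exactly, and keeps molecules whole (positions transform by a pure
rotation; no per-site rewrapping).

## Calibration objectives

For each polymorph p the targets are an experimental lattice energy and
the six cell parameters y = (a, b, c, α, β, γ).  The objective vector has
six components: per-polymorph absolute fractional error in E_latt, and
per-polymorph RMS fractional error over the six cell parameters (d = 6,
with pinned angles kept in the average even though they contribute zero —
fidelity to the printed definition).  All objectives are scale-free.  A
feasibility flag records the stability-ordering constraint
E_γ ≤ E_α ≤ E_β (ties allowed within 10⁻⁹ kJ mol⁻¹).  A failed relaxation
yields a sentinel objective of 10³ with `feasible=False` rather than an
exception, so optimization survives unstable parameter regions.

## Bayesian optimization

Each objective is modeled by an independent Gaussian process over the
unit-cube-normalized parameter space: constant mean, isotropic RBF kernel
(single length scale, no ARD), outputs standardized.  Hyperparameters
(μ, l, signal and noise variances) maximize the log marginal likelihood
over a multi-start grid of 24 log-spaced length scales × 4 noise ratios;
μ and the signal variance have closed forms at fixed (l, η).  An
all-constant target degenerates gracefully to a prior-like model.

The loop starts from 15 scrambled-Sobol points and runs up to a
configurable number of iterations (the recovery benchmark uses 45, i.e.
60 evaluations total).  Candidates are scored by Monte-Carlo expected
hypervolume improvement (EHVI): a shared set of uniform volume points
turns the hypervolume improvement of each posterior sample into a
dominated-point count.  Two design choices matter in practice:

* the volume-point box is localized to `[0, min(ref, 2×front-nadir)]`, so
  Monte-Carlo resolution keeps pace as the front tightens toward zero;
* the Sobol candidate pool (default 128) is augmented with jittered
  copies of the best evaluated points and with two rounds of local
  coordinate refinement of the top-scoring candidates, giving the
  acquisition a late-stage exploitation path.

The stability constraint biases acquisition through the posterior
probability of the correct energy ordering, estimated from three
additional GPs fit to the raw per-polymorph lattice energies and the same
Monte-Carlo machinery; EHVI is multiplied by this weight.  If every
candidate scores zero, the maximum-posterior-variance candidate is taken
instead (logged exploration fallback).

The hypervolume reference point is the componentwise maximum over
observed feasible objectives × 1.1, ratcheted monotonically.  Hypervolume
itself is exact (recursive sweep) up to three objectives and seeded Monte
Carlo with reported standard error above that.  Pareto bookkeeping is by
direct dominance comparison; infeasible points never enter the front
while any feasible point exists.  The final reported parameter set is, by
default, the feasible evaluated point minimizing the worst-case
objective; the full front and audit trail (every x, f, feasibility,
incumbent hypervolume) are retained and JSON-serializable for resumption.

All randomness flows from a single top-level seed expanded into child
seeds; identical seeds reproduce the evaluation sequence bitwise.

## Synthetic study problems

The test suite and acceptance script run entirely on generated fixtures:

* **Rock-salt lattice** — ±q charges on the conventional cubic cell; the
  Ewald kernel must reproduce the Madelung constant 1.747565 from the
  energy per ion pair.  This is the electrostatics oracle.
* **FCC Lennard-Jones crystal** — relaxation and tail-correction checks
  against line-scan and direct-sum oracles.  One caveat discovered here:
  a truncated LJ lattice energy is discontinuous where a neighbor shell
  crosses the cutoff, so grid-scan oracles must scan the smooth branch.
* **Dipolar molecular crystal** — two rigid two-site dipoles per cubic
  cell (antiparallel by default); exercises exclusions, Ewald with
  molecular charges, and the relaxation variational bound
  (full relaxation ≤ positions-only, checked on 20 randomized fixtures).
* **Calibration triple** — three crystals of a four-site rigid polar
  molecule (net-neutral, charges ±0.38/±0.22 e) in three symmetry
  families (orthorhombic, monoclinic β = 103°, trigonal), one molecule
  per cell, each with a different fixed in-plane orientation.  Four atom
  types carry LJ parameters (σ 2.95–3.60 Å, ε 0.40–0.70 kJ mol⁻¹); the
  zero-parameter hydrogen-like type is frozen out, giving a 6-dimensional
  calibration vector with ±25% σ and ±50% ε bounds.  The "experimental"
  targets are the model's own relaxed outputs at the ground-truth
  parameters, with polymorph labels assigned so the γ ≤ α ≤ β ordering
  holds by construction.  The recovery benchmark asks the optimizer to
  drive all six objectives below 0.02 within 60 evaluations.
* **Brownian ensemble** — 500 independent 3-D random walks of 10⁴ steps
  (1 ps spacing) with known diffusion constant; the Einstein estimator
  (origin-averaged MSD, log-log slope window [0.9, 1.1], least-squares
  slope / 6) must recover it within 5%.

What these fixtures do *not* emulate: real molecular flexibility and
intramolecular energetics, finite-temperature sampling and thermal
expansion, solvent environments, polarization or many-body dispersion,
and the size and conditioning of a real 10-dimensional calibration.
Passing tests demonstrate the machinery is correct and the optimization
loop efficient on a smooth, self-consistent problem — not that any
particular real force field will calibrate equally fast.

## Other numerical conventions

* Diffusion units: positions in Å and times in ps give D in
  10⁻⁹ m² s⁻¹ via a factor of 10 on the MSD slope / 6.
* Block averaging: block-size doubling; the reported standard error is
  the first plateau (change < 10% across two successive doublings), else
  the maximum across block sizes — a documented stand-in for more
  elaborate automated procedures.
* The Gibbs–Helmholtz solvation enthalpy is the exact two-temperature
  finite difference, exact for ΔG(T) affine in T.
* The sublimation route to the reference lattice energy uses the
  temperature of the sublimation *measurement* (e.g. 455 K for the
  glycine datum), not ambient temperature — the 2RT term makes this a
  ~2.6 kJ mol⁻¹ distinction.
* Saturation mole fractions interpret solubility as grams per liter of
  water (55.508 mol), the only reading consistent with the cited
  solubility/mole-fraction pair.
* Problem sizes in the shipped benchmarks (one molecule per cell in the
  calibration triple, 60-evaluation optimization budgets, 10⁴-step
  Brownian ensembles) are the package's chosen study conditions: small
  enough to be exactly oracle-checkable, large enough that every
  estimator operates in its intended regime.

## Known limitations

No forces on cell parameters (no stress tensor) — cell relaxation is
line-search only, so heavily coupled length/angle relaxations (fully
triclinic with free angles) are out of scope.  The acquisition optimizer
is a pool search with local refinement, not a gradient-based inner
optimizer; for dimensions well beyond ~10 it would need more samples.
Hypervolume above three objectives is Monte-Carlo with reported error,
not exact.  The bonded-graph policy carries no bonded energy terms — it
only controls exclusions and 1-4 scaling of nonbonded terms.
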