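# Methods

## Model and scope

`ibicg` implements structure-based coarse-graining by Iterative
Boltzmann Inversion for systems described by three interaction
classes — non-bonded pair, bond length, and bending angle — whose
probability structure is assumed to factorize,

    P(r, l, θ) = P_nonbond(r) · P_bond(l) · P_angle(θ).

Each factor is Boltzmann-inverted independently (U = −k_B T ln P, no
4πr² or sin θ Jacobian corrections; the table headers record this
convention so files are self-describing). Only the non-bonded term is
refined iteratively; bonded terms are extracted once from the
reference ensemble and held fixed. The motivating application is a
periodically infinite (5,5) carbon nanotube (24 beads of 10 carbons)
with a single capped amino acid (three beads: acetyl cap, residue,
amine cap), in implicit solvent — all solvent effects live inside the
inverted potentials.

Assumptions worth stating explicitly:

* the reference and iterated RDFs are measured with the *identical*
  estimator (binning, normalization, exclusions, box); the IBI fixed
  point is defined relative to that estimator, so it is frozen as
  part of the file contract;
* orthorhombic boxes and minimum-image distances only;
* no CG electrostatics (beads are uncharged) and no pressure
  coupling — the ensemble is NVT, matching the protocol the potentials
  are meant for.

## Units

GROMACS-consistent MD units throughout: nm, ps, amu, kJ/mol, K, with
k_B = 0.0083144621 kJ/(mol·K). In this system F/m with F in
kJ/(mol·nm) and m in amu is directly an acceleration in nm/ps², so
the integrator contains no conversion factors; this is asserted by the
unit-audit test.

## Key parameters

| parameter | default | meaning / why |
|---|---|---|
| T | 330 K | sampling temperature of the protocol; slightly above ambient to speed adsorption/desorption statistics |
| r_cut | 1.0 nm | non-bonded truncation; tables are shifted so U(r_cut)=0 |
| dt | 0.001 ps | leapfrog step; stable for all bead masses and table stiffnesses used here (larger steps integrate stably on smooth tables but 1 fs is the default) |
| steps/iteration | ≥ 10⁵ (paper scale); 5·10⁴ in the closure tests | RDF sampling length per iteration |
| thermostat | CSVR ("v-rescale"), τ_T = 0.1 ps | canonical kinetic-energy distribution, not just the mean; its stochastic term is what makes runs seed-dependent |
| α | −0.001·k_B T | amplitude of the linear tail correction ΔU(r) = α(1 − r/r_cut) applied every update |
| f_tol | 1e-4 | stop threshold on f_target = ∫e^{−r}(g−g_T)² dr (r in nm; the weight makes the functional dimensionless-ish in nm quadrature, declared explicitly since the RDF is dimensionless) |
| damping | 0.2 | factor on the k_B T ln(g_n/g_T) increment; changes the path, not the fixed point. Closure tests use 0.5 — a single well-sampled pair RDF tolerates, and benefits from, larger steps |
| g_floor | 1e-6 | below this a bin counts as unsampled |
| unsampled cap | ±2 k_B T | per-iteration increment bound where only one distribution is sampled, preventing runaway walls |
| RDF bins | dx = 0.01 nm, left-edge bins, midpoint values | declared default (not inferred from any source) |

## Numerical choices

* **Inversion of unsampled regions.** The inner core (g ≤ g_floor)
  is filled with a linear repulsive wall continuing the innermost
  sampled slope; if that slope is not repulsive, a steep fallback wall
  (1000 kJ/mol per unit coordinate) is used so dU/dr < 0 at r_core
  always holds. Interior gaps are bridged linearly; the outer end
  continues its last slope.
* **Force columns.** F = −dU/dx by central differences (one-sided at
  the edges), zeroed at and beyond r_cut. Energies and forces are
  linearly interpolated; distances below the table clamp to the wall
  force. Derivatives are taken of the *accumulated* potential U_n, not
  of ln g_n — for n ≥ 1 the two differ, and only the former conserves
  energy for the potential actually simulated.
* **Update smoothing.** A quadratic Savitzky–Golay filter (window 5)
  is applied to the update *increment*, not to the updated potential:
  a zero increment then reproduces U_n exactly, making the fixed point
  exact rather than approximate.
* **Integrator.** Leapfrog with positions wrapped each step;
  mobile-bead COM momentum is removed every step so velocity rescaling
  cannot feed a drifting box ("flying ice cube"). Kinetic energy is
  measured at half-steps, which biases the reported temperature by
  O((ωdt)²) — well under the 2% acceptance band at dt = 1 fs.
* **CSVR propagator.** The kinetic energy is advanced with the exact
  stochastic propagator (one Gaussian and one χ²_{N_f−1} draw per
  step) and velocities scaled by a common factor; N_f = 3N−3 after COM
  removal. "V-scale" is read as this canonical scheme; a Berendsen
  thermostat is provided for parity but not used in production.
* **Degenerate inputs.** Zero-length angle arms are skipped and
  counted; identically zero distributions refuse inversion; bonded
  pairs and angle end pairs are auto-excluded from the non-bonded sum;
  a type pair occurring without an assignment (table or explicit
  "none") is a configuration error, not a silent zero.
* **Tie-breaks.** Histogram values exactly on a bin edge fall into
  the right-hand bin (numpy convention); the best iteration is the
  first minimum of f_target.

## Performance paths

The numpy implementation is the reference. When numba is importable,
three kernels replace the hot loops: the tabulated pair-force loop, a
fused NVT step loop (single-table, bond-free, all-mobile systems) with
a Verlet neighbor list (0.2 nm skin, rebuilt every 20 steps — beads
close mutually by ≪0.01 nm between rebuilds at thermal speeds), and
RDF distance counting. The fast path draws its thermostat randoms in
vectorized order, so the two paths agree statistically but not
bit-for-bit; any given path is bit-reproducible for a fixed seed,
which is the determinism contract the archive replay relies on.

## The synthetic reference generator

Real reference data for this workflow are hundreds of nanoseconds of
solvated all-atom trajectories; they are replaced by two generators.

*Structures.* The (5,5) armchair tube is built by the rolled-graphene
construction (radius 3·n·a_CC/2π, period √3·a_CC, two rings of 10
atoms per period) and axially strained — 0.9% for the 2.93 nm box — to
close across the periodic boundary. Capped residues are schematic
three-cluster structures whose group masses are composition-exact
(e.g. Gly residue unit 57.05 amu); their geometry is deliberately
coarse.

*Closure fixtures.* The target distributions are produced by the CG
engine itself under a known ground-truth potential (truncated-shifted
12-6, ε = 1.5 kJ/mol, σ = 0.47 nm by default). The workhorse closure
system is a single-component fluid of 300 Gly-mass beads in a 4.3 nm
box (ρσ³ ≈ 0.39, a moderate liquid): its ~45,000 equivalent pairs give
the RDF statistics the 1e-4 convergence scale demands. The sizes were
fixed by a power analysis of the noise floor of f_target between
independent same-potential runs: a 300,000-step target run (sampled
every 10 steps) and 50,000-step iteration runs (sampled every 5)
leave a floor near 3e-5, a three-fold margin under f_tol. A
nanotube-plus-peptide variant (27 beads, harmonic-table bonded chain
with bonds closing across the z boundary) carries the thermostat and
protocol checks at the study geometry.

What passing closure tests show — and what they do not: they verify
the estimator/inversion/update/engine loop is self-consistent and
recovers a known pair potential (to k_B T/2 over the attractive well,
up to the truncation constant) from its own ensemble. They cannot
certify force fields derived from *external* reference data, where
mapping noise, anisotropy around the tube, and finite reference
sampling enter; the noisy-target generator probes robustness to the
last of these only.

## Design choices where the design was open

* CNT beads are axially consecutive rings (10 atoms each), keeping
  beads evenly spaced and matching a bonded CNT–CNT chain; the tube
  beads are mobile with bonded terms by default, with a `frozen` flag
  for a rigid-tube variant.
* Groups are made whole across the periodic boundary (minimum image
  to the group's first atom) before COM mapping; a raw COM of a
  boundary-straddling ring would be meaningless.
* The amino-acid bead excludes cap atoms (caps have their own beads);
  the alternative — folding caps into the residue COM — would change
  bead masses by ~30% and the bonded equilibrium lengths, but not the
  method.
* Solvent atoms are excluded from mapping entirely (implicit-solvent
  CG model).
* RDF normalization uses the homogeneous ideal-gas convention even
  for the anisotropic tube–peptide pair: the fixed point only requires
  target and iterate to share an estimator, and the conventional
  estimator keeps files interoperable.
* ΔU is applied every iteration (a config switch disables it for
  fixed-point tests); only the amino-acid–tube table is iterated,
  cap–tube tables stay at their PMF values.
* The iteration archive stores every iteration (table, RDF, seed,
  f_target) and reports the best-f iteration, since f fluctuates at
  the noise floor after convergence.

## Known limitations

* Orthorhombic boxes; no cell-list scaling beyond the Verlet list
  (systems here are ≤ a few hundred beads).
* No pressure-corrected IBI: ΔU improves the tail but the virial
  pressure of the CG model is not matched.
* Potentials are state-point specific (330 K); no transferability
  corrections.
* The angle-force test tolerance reflects piecewise-linear tables:
  force and energy columns are mutually consistent only to O(dθ²)
  between nodes, so oracle comparisons use fine bonded grids.
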