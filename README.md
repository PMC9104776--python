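# ibicg — Iterative Boltzmann Inversion coarse-graining toolkit

`ibicg` derives coarse-grained (CG) pair potentials from reference
structural data by Iterative Boltzmann Inversion (IBI), the
structure-matching scheme used to coarse-grain systems such as a
carbon nanotube interacting with capped amino acids. It is aimed at
molecular-simulation practitioners who want a small, fully
reproducible pipeline: center-of-mass bead mapping, distribution
extraction, Boltzmann inversion into tabulated potentials, an NVT CG
molecular-dynamics engine for tabulated tables, and the IBI refinement
loop — all in GROMACS-consistent units (nm, ps, amu, kJ/mol, K).

## The method

Given a target radial distribution function g_T(r) between two bead
types (in the motivating application: an amino-acid bead and the
beads of a (5,5) carbon nanotube), the potential of mean force

    U⁰(r) = −k_B T ln g_T(r)

is only the zeroth-order CG potential: it contains solvent and
multi-body averaging and does not reproduce g_T(r) when simulated.
IBI refines it by simulating the CG model with the current table,
measuring g_n(r), and updating

    U^{n+1}(r) = U^n(r) + k_B T ln( g_n(r) / g_T(r) ) + ΔU(r),
    ΔU(r) = α (1 − r/r_cut),   α = −0.001 k_B T,

where ΔU is a small linear tail correction. By Henderson's uniqueness
theorem the pair potential consistent with a given g(r) at a state
point is unique up to a constant, so the iteration has a well-defined
fixed point. Convergence is scored by the weighted functional

    f_target = ∫ e^{−r} ( g(r) − g_T(r) )² dr ,

and the best-scoring iteration is reported. Bond-length and
bending-angle potentials are Boltzmann-inverted once
(U = −k_B T ln P) and not iterated. The CG engine integrates leapfrog
dynamics with tabulated forces under periodic boundaries, holding
temperature with the canonical stochastic velocity-rescaling (CSVR)
thermostat at 330 K by default.

Because reference all-atom ensembles are too large to ship, the
package generates *closure fixtures*: it simulates a known
ground-truth potential with its own engine, records the resulting
distributions as the target, and verifies that inversion plus
iteration recovers the potential it started from.

## Worked example

Generate a closure target with the engine, invert it, and refine:

```python
from ibicg import (IBIConfig, SimulationConfig, make_closure_fixture,
                   pmf_from_rdf, run_ibi)

fixture = make_closure_fixture(kind="fluid", n_mobile=64, box=2.6,
                               steps=20_000, seed=11)
g_target = fixture.target_dists.rdf
U0 = pmf_from_rdf(g_target, T=330.0, r_cut=1.0)
config = IBIConfig(max_iters=8, f_tol=2e-4, damping=0.5,
                   sim=SimulationConfig(n_steps=10_000, seed=42,
                                        sample_interval=10))
state, records = run_ibi(U0, g_target, fixture.system, config)
```

Output for this 64-bead desk-size fluid:

```
target RDF: 100 bins, first peak g = 1.755 at r = 0.505 nm
PMF well depth: -1.496 kJ/mol
iteration 0: f_target = 2.229e-03
iteration 1: f_target = 8.009e-04
iteration 4: f_target = 4.413e-04
best iteration: 4 (f = 4.413e-04)
```

Iteration 0 scores the PMF itself: f ≈ 2.2e-3 says the plain PMF
misses the target structure. The update drives f down by a factor of
five in four iterations, after which this *small* example sits at its
sampling-noise floor (~4e-4 for 10,000-step runs of 64 beads). The
production-size closure exercised by the test suite (300 beads,
50,000-step iterations) reaches f_target ≤ 1e-4, the accuracy scale of
a converged IBI fit, and recovers the ground-truth well to within
k_B T/2.

The same stages are available from the shell:

```
ibicg fixtures --preset closure-fluid --seed 7 --out fx/
ibicg pmf --rdf fx/target_rdf.dat --temp 330 --r-cut 1.0 --out u0.dat
ibicg ibi --target fx/target_rdf.dat --seed 7 --out run1/
ibicg map / dists / simulate ...      # mapping, distributions, plain MD
```

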