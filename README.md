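# pathwork

Path-based nonequilibrium binding free energies: reference-path geometry,
path collective variables, steered/adiabatic-bias/metadynamics sampling on
toy systems, and the Crooks/Bennett–Jarzynski free-energy layer with
standard-state assembly.

## The problem

Absolute binding free energies of ligand–receptor complexes can be
obtained from *nonequilibrium* pulling simulations: a reference path of
molecular configurations connects the bound and unbound states, path
collective variables (PCVs) map any configuration onto a progression
coordinate S ∈ [0, 1] and an orthogonal deviation Z, and a moving harmonic
restraint drags the system back and forth along S while the Jarzynski work

    W_J = ∫ dt · Ŝ̇ · ∂H/∂Ŝ

is accumulated.  From equal numbers of forward and backward pulls, the
Crooks fluctuation theorem in its maximum-likelihood (Bennett) form,

    ⟨[1 + e^{β(W_f − ΔF)}]⁻¹⟩_f = ⟨[1 + e^{−β(W_b − ΔF)}]⁻¹⟩_b,

is solved per path segment and chained into the free energy profile F(S).
Splitting F(S) at a discriminating configuration gives the binding free
energy ΔF_b = −RT·ln(Q_site/Q_bulk), and the standard-state correction
ΔF_v = −RT·ln(V_bulk/V°) with V° = 1661 Å³ converts it to standard
concentration: ΔF_b° = ΔF_b + ΔF_v (+ literature correction terms).

`pathwork` implements this entire workflow as a tested library + CLI.
All-atom engines are out of scope; a Langevin toy engine with the same
bias types (constant-velocity SMD with a Z wall, ABMD ratchet,
well-tempered metadynamics, Debye–Hückel CV) makes every estimator
testable end to end against analytic references.  See `docs/methods.md`
for the models, conventions and numerical choices.

## Modules

| module | contents |
| --- | --- |
| `pathwork.path_model` | superposition (Kabsch), MSD metric, λ calibration, equidistant-waypoint resampling, RMSF-based atom selection, endpoint padding |
| `pathwork.pcv` | S(x)/Z(x) evaluation with log-sum-exp stabilization |
| `pathwork.toy_dynamics` | BAOAB Langevin engine, SMD/ABMD/WT-MetaD biases, Jarzynski work accumulation, Debye–Hückel CV |
| `pathwork.neq_estimators` | work segmentation, piecewise Crooks/Bennett solver, Jarzynski estimate, Crooks-consistent generator, bootstrap errors |
| `pathwork.binding_energy` | discriminating frame, partition-ratio integration, union-of-spheres volume proxy, standard-state assembly |
| `pathwork.io` / `pipeline` / `cli` | COLVAR/hills/FES tables, multi-model PDB and XYZ, YAML-configured pipeline, `pathwork` CLI |
| `pathwork.benchmarks` | the frozen double-well toy study used for validation |

## Worked example

A tilted double well (barrier 2.5 kcal/mol, basins at ±1.5 Å, tilt
−1 kcal/mol, 300 K) stands in for a ligand moving between a bound (S = 0)
and unbound (S = 1) basin:

```python
import numpy as np
from pathwork import benchmarks
from pathwork.neq_estimators import build_segment_work_set, cft_profile
from pathwork.binding_energy import (
    select_discriminating_index, integrate_partition_ratio)

study = benchmarks.make_double_well_study()     # path, λ, thermostat
fwd, bwd = benchmarks.run_smd_batch(study, seed=11)   # 30+30 pulls, 40 ps
segments = build_segment_work_set(fwd, bwd, study.path)
fes = cft_profile(segments, study.thermo, n_boot=200, seed=12)

print(f"terminal dF = {fes.F[-1]:.3f} ± {fes.stderr[-1]:.3f} kcal/mol")
print(f"analytic    = {benchmarks.landau_profile(study)[-1]:.3f} kcal/mol")
split = select_discriminating_index(fes)
ratio, dF_b = integrate_partition_ratio(fes, split, study.thermo)
print(f"dF_b (split node {split}) = {dF_b:.3f} kcal/mol")
```

prints (seed 11)

```
terminal dF = -1.976 ± 0.035 kcal/mol
analytic    = -2.000 kcal/mol
dF_b (split node 9) = 1.601 kcal/mol
```

i.e. the pulled, piecewise-Bennett estimate recovers the exact basin
free-energy difference within its bootstrap error.  The partition-ratio
ΔF_b is positive here because the "site" basin (S < barrier node 9) is the
shallower of the two wells — direct Boltzmann quadrature over the toy
coordinate gives 1.615 kcal/mol for the same split.

The same workflow is available from the shell:

```bash
pathwork run --config run.yaml --out results/     # full pipeline
pathwork path lambda --in path.xyz                # λ calibration
pathwork fep cft --forward 'f*.tsv' --backward 'b*.tsv' --nodes 21 --temp 300
pathwork synth works --dF 3.0 --sigma 1.2 --n 30 --seed 1
```

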