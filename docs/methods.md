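# Methods

`pathwork` implements a path-based nonequilibrium strategy for absolute
binding free energies, exercised end to end on analytic toy systems.  This
note records the models, the numerical choices, and what the toy validation
does and does not demonstrate.

## Path collective variables

A reference path is an ordered set of p configurations x₁…x_p connecting a
bound and an unbound state.  Progression and orthogonal deviation are

    S(x) = Σᵢ i·e^(−λ‖x−xᵢ‖²) / Σⱼ e^(−λ‖x−xⱼ‖²),
    Z(x) = −λ⁻¹ ln Σᵢ e^(−λ‖x−xᵢ‖²),

with ‖x−xᵢ‖² the optimal-alignment mean-square deviation (Å²) over the
path-atom selection after superposing x onto each waypoint on the alignment
selection.  Both are computed with log-sum-exp stabilization; a
direct-summation oracle in extended precision confirms agreement to 1e-10
on short paths.

λ (Å⁻²) is calibrated so that λ·⟨gap⟩ ≈ 2.3.  Two conventions are
implemented: `printed`, λ = 2.3·p/Σᵢ MSD(xᵢ, xᵢ₊₁) (the default), and
`mean-gap`, λ = 2.3/⟨MSD⟩, which differ by the factor p/(p−1).  The choice
is logged per run; for p ≳ 20 the difference is ~5% of λ and does not move
any toy result outside its error bars.

S is reported raw (1…p) and normalized to [0, 1] over the *physical*
waypoints: with n_h padded head frames, s = (S − 1 − n_h)/(n_phys − 1).
This affine map is the unique one placing the physical endpoints at 0 and
1.  The normalized value is clamped to [0, 1] only on output; the raw value
is always retained.

### Waypoint processing

* **Equidistant reparametrization.** Waypoints are resampled on the
  piecewise-linear interpolant of the (sequentially aligned) input in the
  flattened coordinate space of the path selection, with RMS distance
  (√MSD) as the arc-length metric.  Chord positions are iterated (cumulative
  chord-length redistribution) until the coefficient of variation of
  consecutive MSDs falls below the tolerance (default 1%); endpoints are
  pinned exactly.  On a straight 1D path this reproduces the closed-form
  equal-arc resampling.
* **Endpoint padding.** Fictitious frames are added by linear extrapolation
  of the terminal segment (scaled by `step_scale`), counted separately and
  excluded from S-normalization.  Padding removes the softmax saturation at
  the path termini: without it, ds/dx → 0 at the endpoints, the Landau
  profile acquires an integrable log singularity there, and the first/last
  segment free energies are distorted.  Three padded frames per end are
  enough for the toy study.
* **RMSF selection.** Candidate alignment atoms are groups whose RMSF
  (RMS deviation from the mean structure over frames, after iterative
  superposition onto the evolving mean) falls below a threshold — 1.8 Å is
  the conventional cutoff for flexible receptors.  The atom subset per
  group is configurable; without an alignment selection (1-atom toy
  frames) superposition is skipped.

## Toy sampling engine

A single particle (mass m, friction γ_f) moves on an analytic potential
under BAOAB-discretized Langevin dynamics at temperature T
(k_B = 0.0019872041 kcal/(mol·K); 1 kcal/mol = 418.4 amu·Å²/ps²).  Runs are
bit-reproducible given a seed.  Toy reference paths are single-atom
conformations in the particle's coordinate space, so the production PCV
arithmetic is exercised with closed-form gradients.

* **SMD.** A restraint R(x,t) = ½k(S(x) − Ŝ(t))² moves at constant velocity
  between two S values.  Work is accumulated discretely as
  ΔW = k(Ŝ(t+Δt/2) − S(x_t))·ΔŜ — the thermodynamic force conjugate to the
  schedule coordinate times the schedule displacement.  The midpoint
  schedule value makes the frozen-particle limit integrate exactly to ½kΔ²
  and the rule is additive over time intervals by construction.  A
  flat-bottom wall ½k_w(Z − Z₀)² (Z₀ = 0.05 nm² = 5 Å²,
  k_w = 4×10⁷ kJ mol⁻¹ nm⁻⁴ ≈ 956 kcal mol⁻¹ Å⁻⁴) acts only above the Z
  threshold.
* **ABMD.** The ratchet reference ρ is the best CV value achieved toward
  the target; the one-sided restraint ½k(CV − ρ)² acts only when the CV
  regresses past ρ, and switches off once ρ reaches the target, so progress
  is driven by thermal fluctuations alone.  ABMD force constants are taken
  in kcal/mol per squared CV unit; the (kJ/mol)⁻³ units sometimes quoted
  for ABMD constants in the literature are not dimensionally interpretable
  here and are not used.
* **Well-tempered metadynamics.** Gaussians on (S, Z) are deposited every
  `stride_steps` (default 250) with heights h₀·exp(−V_bias/((γ−1)RT)).
  Convergence is declared when the mean height of the last 50 hills falls
  below 10% of h₀ (alongside diffusive S sampling).  The FES is
  reconstructed by final-bias reweighting: each visited (S, Z) sample gets
  weight e^{+βV_bias,final}, and F(s) = −RT·ln of the weighted histogram.
  The −(γ/(γ−1))·V_bias view is available as a diagnostic.  Errors come
  from a 10-block, 400-iteration block bootstrap of the weighted histogram.
* **Debye–Hückel CV.** E = C·Σ q_iq_j·e^(−κr)/(ε_r·r) with
  C = 332.0637 kcal·Å/(mol·e²); κ = 0 reduces to Coulomb.  Used as an
  unbinding CV for charged systems (target 0 = dissociation).

## Free-energy layer

Work traces are cut at the instants the *schedule* Ŝ crosses each path
node (the restraint defines the switching protocol; the instantaneous S
does not), with the accumulated work interpolated linearly in time.
Backward (binding-direction) increments are stored as the negative of the
reverse-process increment — the forward sign convention.  Under it,
w_f = w_b = w implies ΔF = w, and the Gaussian pair below satisfies the
Crooks relation identically.  This convention is the single source of truth
across the package.

Per segment, ΔF solves the maximum-likelihood form of the Crooks theorem
for equal replica counts,

    ⟨[1 + e^{β(W_f − ΔF)}]⁻¹⟩_f = ⟨[1 + e^{−β(W_b − ΔF)}]⁻¹⟩_b,

a strictly monotone scalar root-finding problem solved by Brent's method
(bracket [min−10RT, max+10RT] of all works, auto-expanded; xtol 1e-12).
Unequal replica counts are rejected rather than silently generalized to
full BAR with sample-size terms.  Chaining segments gives F(s) anchored at
F(0) = 0; per-node errors come from a paired-replica bootstrap (one replica
resample shared across segments, errors cumulative along the profile).
The unidirectional Jarzynski estimate −β⁻¹ln⟨e^{−βW}⟩ (log-sum-exp) and
the dissipated work ⟨W⟩ − ΔF̂ are provided as diagnostics; on dissipative
synthetic data the paired estimator has the smaller bias.

The synthetic generator draws w_f ~ N(ΔF + βσ²/2, σ²) and
w_b ~ N(ΔF − βσ²/2, σ²) (forward convention), the unique Gaussian pair
with symmetric dissipation satisfying the Crooks relation exactly.

## Binding free energy

The profile is split at a discriminating configuration: by default the
highest interior FES point flanked by lower values on both sides (bound
minimum on one side, terminal plateau on the other); a manual override
always wins, since in practice the choice involves visual inspection.
Then

    ΔF_b = −RT·ln(∫_site e^{−F/RT} dS / ∫_bulk e^{−F/RT} dS)

by trapezoidal quadrature on the node grid (optionally on a cubic-spline
refinement), with the bulk region the full tail beyond the split.
The standard-state correction is ΔF_v = −RT·ln(V_bulk/V°), V° = 1661 Å³
(one molecule per 1/N_A liters).  V_bulk is proxied by the voxelized union
of probe-inflated atomic spheres over the unbound configurations — an
overestimate of the solvent-excluded-surface volume, since the re-entrant
surface is omitted; an external SES engine can be slotted in where
available.  ΔF_b° = ΔF_b + ΔF_v + Σ(labelled literature corrections), with
term errors combined in quadrature.  Correction terms (e.g. a
conformational-flip contribution of a receptor motif) are opaque inputs,
never computed here.

## Toy validation study

The reference system is a tilted quartic double well
V(x) = h((x/b)² − 1)² + c·x/b with h = 2.5 kcal/mol, b = 1.5 Å,
c = −1.0 kcal/mol at 300 K (m = 12 amu, γ_f = 5 ps⁻¹): a ~3.5 kcal/mol
barrier from the deeper basin and an exact basin free energy difference
near −2 kcal/mol — comparable, in units of RT, to small-molecule
unbinding barriers.  The path runs between the two minima (21 waypoints,
3 padded frames per end).  Waypoints are deliberately *not* placed high on
the potential walls: there the slope (≳20 kcal/mol/Å) overwhelms the
S-restraint and the sampled profile becomes the restrained ensemble's
rather than the Landau profile's — verified against direct quadrature of
the restrained partition function.

SMD uses k = 2000 kcal/mol per unit S², 40 ps per replica (dt = 2 fs),
30 replicas per direction, with a 20 ps set for the speed-ordering check.
The restraint width √(RT/k) Gaussian-smooths the sampled profile; at
k = 2000 that width (0.017 in S) is far below the barrier width and the
restrained profile tracks the Landau profile to < 0.05 kcal/mol, verified
against direct quadrature.  Metadynamics uses h₀ = 0.5 kcal/mol,
σ_s = 0.025, σ_z = 1 Å², γ = 5, 3000 ps (dt = 4 fs); the hill width is
likewise kept below the profile's feature scale because its smoothing is
not fully removed by reweighting.  Hill height, width and bias factor are
sized to the toy FES range — the larger production-scale values would
either wash out a 3 kcal/mol profile or defer convergence indefinitely.
These problem sizes keep the dissipated work per pull at ~0.1 kcal/mol,
i.e. near-quasistatic, which is the regime the piecewise estimator is
designed for.

Because the toy is one-dimensional, the exact Landau profile
F(s) = V(x(s)) + RT·ln|ds/dx| + const and the exact basin populations are
available by quadrature, so the pipeline is validated at three levels:
profile RMS (< 0.5 RT), terminal ΔF (within bootstrap error), and the
partition-ratio ΔF_b against direct Boltzmann integration.

**What this does not show.**  The toy has no orthogonal slow degrees of
freedom, no path-definition ambiguity, no alignment noise, and its
dissipation is orders of magnitude below that of solvated complexes.
Passing the toy study validates the estimator chain and the geometry/PCV
algebra — not force fields, path quality for real receptors, or
convergence at production dissipation levels.  Literature correction terms
are taken as given, and the union-of-spheres volume is an upper bound on
the SES volume.

## Degenerate inputs and tie-breaking

Duplicate waypoints (zero consecutive MSD) are rejected at λ calibration;
fewer than 3 non-collinear alignment atoms raise a degenerate-alignment
error; exactly equidistant waypoints are handled continuously by the
softmax, with the nearest-index diagnostic taking the lower index; a flat
or monotone FES has no discriminating frame and requires an explicit
override; empty work samples, unequal forward/backward counts and
non-spanning schedules are all rejected with labelled errors.

## Reproducibility

Every stochastic operation takes an explicit seed.  The pipeline derives
per-replica seeds from the master seed through named `SeedSequence`
substreams, so any replica can be reproduced in isolation; rerunning a
configuration is byte-identical, and every artifact records the
configuration hash, seeds, λ convention and sign convention.
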