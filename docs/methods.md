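# Methods

This note documents the models implemented in `fabstab`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the package's own design decisions where the procedure was
genuinely open.

## Units and constants

Lengths in nm, energies in kJ/mol, times in ps, temperatures in K.
k_B = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹; default temperature 310 K
(kT ≈ 2.577 kJ/mol). PDB files are Ångström at the boundary and converted
on read/write (factor 0.1).

## Synthetic umbrella sampling

### Toy landscapes

`ToyPotential` provides four analytic forms on a CV domain [lo, hi], in kT
units: `flat`, `harmonic`, `morse_well`
U(r) = D[(1−e^(−a(r−r₀)))²−1] (well depth exactly D, dissociated plateau
at 0 — a closed-form target for the depth estimator) and `double_well`
U(r) = D[(w(r−r₀))²−1]² (minima at r₀±1/w, barrier D). Quadrature
references (`boltzmann_pmf`, `boltzmann_density`) integrate
exp(−U−bias) on dense grids and serve as the exact answers the estimators
must converge to.

### Sampler

Umbrella windows are sampled by **Metropolis-adjusted overdamped
Langevin** dynamics: the Euler–Maruyama proposal
y = x + F(x)Δt/γ + √(2kTΔt/γ)ξ is accepted with the Metropolis–Hastings
ratio for the Gaussian proposal density. This makes the stationary law of
each window *exactly* the Boltzmann distribution of U + ½κ(x−c)² truncated
to the CV domain (out-of-domain proposals are rejected), at any stable
step size — a plain unadjusted integrator carries an O(Δt),
curvature-dependent histogram bias that is large enough to shift MBAR free
energies by a few tenths of kT at practical step sizes. Defaults:
Δt = 0.002 ps, γ = 50 kJ mol⁻¹ ps nm⁻² (relaxation time ≈ 25 steps under
the default spring), per-step drift clamped at 0.1 nm as a stability guard
against steep repulsive walls (the clamp is part of the proposal, so it
does not bias the law). Each window has its own RNG stream spawned from
the root seed (`SeedSequence.spawn`), so single windows are bit-reproducible
independently of the ladder; every `stride`-th step is recorded and the
first 10% of the recorded series is flagged as equilibration (mirroring
the convention of discarding the first tenth of each window).

Samples recorded at stride s retain residual autocorrelation
(lag-1 ≈ e^(−sΔt·κ/γ)); the test suite and acceptance configurations use
strides of 10–60 depending on how much independence the statistic needs.

### Bead-model Fab and trajectories

`build_toy_fab` places four 20-bead domains (VH, CH1 on chain H; VL, CL on
chain L) as Gaussian blobs around configurable centroids, with designated
native-contact beads placed opposite each other across each interface
midplane at 0.30 nm separation (inside the hydrogen-bond criterion).
Contact beads sit on every other residue so each donor's chain neighbour
lies back in the domain blob and the donor-alignment surrogate can pass.
The default interface chemistry cycles through donor/acceptor pairs in all
three moiety flavours, both salt-bridge charge orders and a hydrophobic
pair, so every contact type occurs. Native pairs supplied explicitly must
be inter-chain and are validated as realizable after building.

`generate_dissociation_trajectory` translates the L chain along the
inter-chain COM axis with a linear (rigid) or staged (`fv_first` /
`ch1cl_first`) schedule plus optional coordinate noise (frame 0 stays the
exact bound structure). Because all toy native pairs break over a narrow
CV range, the structural trajectory cannot place the bound→encounter
transition precisely; descriptor-level traces for the state model are
therefore produced by `generate_dissociation_trace`, which emits sigmoidal
descriptor decays versus CV with a *designed* transition point: q decays
in two stages (a partial loss of contacts at the transition CV, the
remainder 0.6 nm later where SASA also plateaus), d₁/d₂ rise sigmoidally
at the transition, and frames are ordered by increasing CV (the
concatenation convention for umbrella runs). The two-stage q keeps the
encounter complex partially bound, so the bound→encounter transition
always precedes encounter→unbound.

### Cohorts

`generate_cohort` draws morse-well depths (default uniform on 2–10 kT)
and melting temperatures Tm = α + βD + ε, ε ~ N(0, σ), defaults
α = 340 K, β = 2 K/kT, σ = 3.5 K. With Var(D) = 64/12 these defaults give
a population depth–Tm correlation of ≈ 0.80, the regime the cohort
recovery study targets; Tm values (340–360 K) sit in the range typical of
Fab thermal stability.

## Descriptors

* **q** — fraction of native inter-chain contacts (reference cutoff
  0.45 nm between bead centers, evaluated at 1.2× the cutoff), inter-chain
  only by default since the inter-chain interface is the dissociation
  coordinate. The reference set comes from frame 0 of the trajectory.
* **d₁ / d₂** — mass-weighted COM distances VH–VL and CH1–CL; unit masses
  unless the structure provides them.
* **SASA** — Shrake–Rupley with a single bead radius 0.3 nm, water probe
  0.14 nm and 960 golden-spiral sphere points (240 in bulk trace
  computation for speed). Coordinates are first rotated into a canonical
  principal-axis pose, which makes the point-sampled estimate invariant
  under rigid motion of the frame to rounding precision; the estimate is
  still quantized at one test point (≈ 4π(r+p)²/n_points per bead), which
  bounds how strictly monotone SASA can be along a smooth trajectory.
* **Contacts** — typed on bead chemistry labels. Hydrogen bond:
  donor–acceptor distance ≤ 0.35 nm and an alignment surrogate (angle
  between donor→acceptor and donor→bonded-neighbour ≥ 110°) replacing the
  explicit-hydrogen angle test, split into bb/bb, sc/bb, sc/sc by moiety;
  salt bridge: opposite formal charges ≤ 0.40 nm; hydrophobic: two
  hydrophobic beads ≤ 0.45 nm. No generic van-der-Waals category, and no
  π-system types (bead models carry no aromatic geometry). All thresholds
  are configurable (`ContactCriteria`).

## MBAR reweighting

`solve_mbar` minimizes the convex maximum-likelihood objective
κ(f) = Σ_n ln Σ_k N_k e^(f_k−u_kn) − Σ_k N_k f_k with damped Newton steps
(analytic gradient and Hessian, line-searched), falling back to the
log-sum-exp-stabilized self-consistent update when a Newton step fails to
decrease the objective; convergence is declared when a self-consistent
update moves f by less than 10⁻⁸ (max norm), and the gauge is f₀ = 0.
Typical ladders converge in 8–12 iterations. The independent cross-check
in the tests is a plain fixed-point iteration started elsewhere, plus
closed-form Gaussian partition-function ratios on a flat landscape.

PMF: default bin width 0.05 nm (matching the fine window spacing); empty
bins are masked, never interpolated; the minimum occupied bin is shifted
to 0. Uncertainties use a window-level block bootstrap (default 10 blocks
per window, ≥ 20 replicates, warm-started MBAR re-solves), which covers
the binning step as well as the estimator. The convergence diagnostic
re-runs the pipeline on the first and second half of every window and
reports the maximum per-bin deviation.

`reweighted_occurrence` computes Σw·present/Σw over a frame mask. When
every pooled frame carries the same bias energy the weights are uniform
and the estimate reduces exactly to the plain average; identical bias
*rows* with varying energies still (correctly) reweight toward the
unbiased ensemble.

## State model

Flank fits build a 60-bin histogram over the sampled range, normalize the
peak to 1, locate the mode (ties broken toward the bound side: high q, low
distance; a mode at the histogram edge is rejected as non-unimodal), and
least-squares fit a logistic to the bins on the stated side of the mode
(mode inclusive). The fit runs in standardized flank coordinates, which
makes it exactly equivariant under rescaling of descriptor units. Sign
conventions are enforced: s_q > 0, s_d1 < 0, s_d2 < 0.

Detection thresholds: θ_b = 0.01 with a 10-frame dwell for bound→encounter
(the state function approaches 0 smoothly, so a small threshold plus dwell
avoids transient dips), θ_u = 0.01 for encounter→unbound. Time-domain fits
for the unbound model use a four-parameter logistic (baseline, amplitude,
slope, midpoint) on frame index as abscissa; each fitted curve is min–max
normalized over the trace span and the SASA curve is inverted so both
factors equal 1 at the bound end. Constant descriptor series are rejected
(no transition to fit). A region counts as dissociated when its COM
distance rises ≥ 0.5 nm above its starting value; systems whose CH1–CL
interface never opens inside the sampled CV range are flagged and excluded
from cohort correlation by default.

## Stability metric

depth = F_ref − F_min over occupied bins at or below the transition CV,
with F_ref the mean of the last 3 occupied bins of that range (the
encounter-side plateau). The reference convention is this package's
explicit choice — the method statement only fixes "the depth of the global
minimum up to the transition" — and both the convention and m = 3 are
configurable and logged. Uncertainty combines the minimum-bin sigma and
the standard error of the reference bins in quadrature. With 0.025 nm
bins the bin-averaging systematic on a morse well of depth 10 kT is under
0.1 kT. Absent transitions raise an error that instructs the caller to
pass the profile's upper edge explicitly for a full-range fallback —
depths are never silently computed over an unintended range.

Cohort correlation: sample Pearson r over systems with Tm, percentile
bootstrap CI (default 1000 resamples, seeded).

## Interface analysis

Group aggregation is a logical OR over member residue-pair contacts per
frame, with unordered (sorted) group-pair labels; unlabeled residues are
rejected. State-window occurrence uses `reweighted_occurrence` over
[0, span) for the bound state and [transition frame, +span) for the
bound→encounter window (span defaults to the 2 ns convention converted
through the manifest time step; windows reaching past the trajectory end
are truncated with a warning). The display filter keeps occurrences
strictly greater than the threshold (default 0.3) and is idempotent.

Domain frames are principal axes of the bead-cloud covariance, ordered by
variance, sign-fixed toward designated reference beads and closed to a
right-handed triad; collinear clouds are rejected. The five orientation
angles are: four bends (each domain's first two axes against the
inter-origin axis, oriented away from the respective domain) and one
torsion (signed angle between the projections of the two primary axes onto
the plane normal to the inter-origin axis, falling back to the secondary
axes in the parallel-degenerate case). These simplified frames replace
consensus-structure reference planes, so *absolute* angle values are not
comparable with the antibody-community conventions — only shifts and
standard deviations along a trajectory are meaningful. Note that any
rotation-invariant torsion of this kind is invariant (not negated) under
swapping the two domains, because both the projection axis and the cross
product flip. Orientation shifts are |mean over the last window − mean
over the first window| with the analysed span ending at the
encounter→unbound frame (series end if absent); the torsion uses circular
mean/SD to avoid ±180° wrap artifacts.

## Problem sizes and reproducibility

The test and acceptance configurations run the full 29-window ladder with
roughly 5000 post-discard samples per window for PMF accuracy and
convergence checks, 0.025 nm bins and ~5000 samples per window for depth
recovery over D ∈ {2,4,6,8,10} kT, and 16-system cohorts at ~450 samples
per window for the correlation recovery study (100 seeded repetitions in
the test suite, one cohort in the acceptance script). These sizes were
chosen so each statistic's sampling error is several times smaller than
the property bound it is checked against. All generators and estimators
take explicit seeds; per-window and per-system streams are spawned from
the root seed, so identical configurations reproduce bitwise-identical
artifacts.

## What the synthetic data does not emulate

The Langevin sampler works directly on the 1-D CV with an analytic
landscape: there is no molecular force field, no solvent, no pulling-rate
kinetics, and no coupling between the sampled CV and the bead structures.
Descriptor traces are generated with designed sigmoidal shapes rather than
measured from simulated structures, so passing tests demonstrate that the
*estimators and detectors* recover known ground truth — not that real Fab
dissociation follows these shapes. Bead models carry one bead per residue
with label-based chemistry; contact geometry (explicit hydrogens, aromatic
systems) and secondary-structure assignment are out of scope, and group
annotations are inputs. Real umbrella-sampling data in the same CSV/JSON
window schema can be fed directly into the reweighting and downstream
modules.

## Known limitations

* MBAR assumes uncorrelated samples when interpreting N_k; correlated
  strides inflate the effective uncertainty (the block bootstrap absorbs
  this for error bars, but point estimates from short, strongly correlated
  windows can wander by a few tenths of kT).
* The SASA estimate is quantized at one sphere point; strict monotonicity
  along smooth trajectories holds only up to that granularity.
* Principal-axis domain frames lose sign stability for nearly symmetric
  bead clouds; reference-bead sign fixing assumes a generic geometry.
* The depth reference (last occupied bins before the transition) is a
  convention; profiles whose encounter-side region is not plateau-like
  will mix barrier shape into the metric.
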