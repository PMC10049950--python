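# fabstab

Quantifying antibody Fab interface stability from umbrella-sampling
dissociation simulations.

The antigen-binding fragment (Fab) of an antibody is held together by two
inter-chain interfaces: the variable VH–VL pairing and the first constant
CH1–CL pairing. When the heavy and light chains are pulled apart along the
distance between their centers of mass (the collective variable, CV), the
bound structure first relaxes into a loosely associated *encounter complex*
and only later separates completely. The free-energy cost of leaving the
bound state — the depth of the bound well in the potential of mean force
(PMF) truncated at the bound→encounter transition — is a computational
stability metric that correlates with experimentally measured melting
temperatures (Tm) across a panel of Fabs.

`fabstab` implements that analysis pipeline as a reusable, fully testable
library. Cluster-scale molecular dynamics is replaced by a synthetic-data
module (a Metropolis-adjusted Langevin sampler on analytic 1-D landscapes
plus annotated bead-model Fab structures), so every stage runs and is
validated at desk scale.

## The method

**Umbrella sampling → MBAR → PMF.** Harmonic biases
½κ(x−c<sub>k</sub>)² (κ = 1000 kJ mol⁻¹ nm⁻², T = 310 K) are applied on a
ladder of 29 window centers from 1.7 to 4.0 nm (0.1 nm spacing, refined to
0.05 nm between 2.0 and 2.5 nm where dissociation happens). The first 10%
of each window is discarded as equilibration. The multistate Bennett
acceptance ratio (MBAR) equations

f<sub>i</sub> = −ln Σ<sub>n</sub> exp(−u<sub>in</sub>) / Σ<sub>k</sub> N<sub>k</sub> exp(f<sub>k</sub> − u<sub>kn</sub>)

are solved for the per-window free energies, giving unbiased per-frame
weights w<sub>n</sub> and the binned PMF F<sub>b</sub> = −k<sub>B</sub>T ln Σ<sub>n∈b</sub> w<sub>n</sub>,
with window-level block-bootstrap uncertainties and a trajectory-splitting
convergence diagnostic.

**State functions.** The bound state is described by three descriptors —
the fraction of native inter-chain contacts *q*, the VH–VL distance *d₁*
and the CH1–CL distance *d₂*. A logistic 1/(1+e^(−s(x−x₀))) is fitted to
one flank of each bound-ensemble histogram (increasing on the left flank of
*q*, decreasing on the right flanks of *d₁*, *d₂*); the product of the
three projected logistics is the bound-state function S ∈ [0, 1]. The
bound→encounter transition is the first sustained drop of S below a small
threshold. The encounter→unbound transition uses time-domain sigmoid fits
of *q* and SASA, normalized, oriented to 1 at the bound end, and
multiplied.

**Stability metric.** depth = F(encounter-side plateau) − F(global
minimum) of the PMF truncated at the bound→encounter CV; across a cohort
the depths are correlated with Tm (Pearson r with a bootstrap CI).

**Interface analysis.** Geometric contact typing on bead chemistry labels
(hydrogen bonds in backbone/side-chain flavours, salt bridges,
hydrophobic), grouped by loop/β-strand labels, MBAR-reweighted occurrence
inside bound and transition snapshot windows, a strict >0.3 display
filter, and simplified principal-axis interdomain orientation angles (four
bends + one torsion + a distance per interface).

## Worked example

```python
import numpy as np
from fabstab.constants import kt
from fabstab.reweighting import make_window_ladder, pmf_from_weights, solve_windows
from fabstab.stability import energy_depth
from fabstab.synthetic import ToyPotential, simulate_umbrella_ladder

pot = ToyPotential("morse_well", depth=5.0, width=6.0, r0=2.0, domain=(1.6, 4.2))
windows = simulate_umbrella_ladder(pot, make_window_ladder(),
                                   n_steps=20_000, stride=10, seed=1)
result, x = solve_windows(windows)
pmf = pmf_from_weights(x, result, np.arange(1.7, 4.05, 0.05))
depth, _ = energy_depth(pmf, transition_cv=3.0)
print(f"windows: {len(windows)}, MBAR iterations: {result.iterations}")
print(f"estimated well depth: {depth / kt():.2f} kT (true 5.00)")
```

prints

```
windows: 29, MBAR iterations: 8
estimated well depth: 5.12 kT (true 5.00)
```

i.e. 29 umbrella windows were combined by MBAR (converged in 8 Newton
iterations) and the recovered bound-well depth is within ~2% of the
analytic depth of the generating landscape.

A full single-system run — bound-ensemble state-model fit, transition
detection, umbrella sampling, PMF and depth, with all artifacts written to
disk — is one call:

```python
from fabstab.stability import SystemConfig, run_system
stab, report, pmf = run_system(SystemConfig(potential=pot, tm=350.0,
                                            seed=3, outdir="scratch/demo"))
```

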