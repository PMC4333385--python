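# recqcycle

Kinetic analysis of the *E. coli* RecQ helicase ATPase cycle: a tested,
reusable implementation of the transient-kinetic experiments, models and
simulations that establish how this helicase couples ATP hydrolysis to
single-stranded-DNA translocation.

RecQ-family helicases maintain genome integrity in organisms from bacteria
to humans. Their DNA-restructuring activity rests on an ATPase cycle that
is strongly activated by ssDNA binding. This package is for enzyme
kineticists and modelers who want to simulate, fit and interrogate that
cycle: it reproduces the stopped-flow, quenched-flow, phosphate-reporter
and ¹⁸O-exchange measurements that pin down the elementary rate constants,
and runs the mechanoenzymatic model that attributes translocation run
terminations to specific nucleotide states.

## The model

The ATPase cycle is a four-state scheme

```
        k1·[ATP]        k2            k3             k4
   E  <==========>  T  <====>  DPi  ------->  D  <==========>  E
        k-1             k-2         (+ Pi,          k-4·[ADP]
                                     k-3·[Pi] back)
```

with E the apo enzyme, T = enzyme·ATP, DPi = enzyme·ADP·Pi and D =
enzyme·ADP. Concentrations are μM, time is seconds, and the second-order
constants k₁, k₋₃, k₋₄ are in μM⁻¹s⁻¹. Two default parameter sets (DNA-free
and ssDNA-bound) encode the measured constants; DNA binding enters only as
this choice of parameter set. The headline mechanistic facts the defaults
encode:

* ATP cleavage (k₂) is rate-limiting in both conditions and is the step
  DNA accelerates (~100-fold);
* hydrolysis is productive because Pi release (k₃) outruns resynthesis
  (k₋₂): the ¹⁸O-exchange ratio (k₃+k₋₂)/k₋₂ is 17 (DNA-free) and 11
  (DNA-bound), measured from double- vs single-labeled phosphate via
  L₂/L₁ = f·k₋₂/(k₃+k₋₂);
* ADP release is fast enough that the ADP-bound state is a minority
  (~15%) during translocation — yet its comparatively rapid detachment
  from ssDNA makes it responsible for ~76% of run terminations, so the
  DNA affinity of RecQ·ADP controls processivity.

Modules: `scheme` (stationary, ODE and Gillespie solvers of the cycle),
`transients` (md-nucleotide binding/chase, quenched flow, Pi release,
exponential/line/Hill/burst fits), `globalfit` (constrained multi-start
global fitting with bootstrap intervals), `exchange` (¹⁸O isotopologue
Markov model and its inversion), `translocation` (run-termination
simulation and 2-fold sensitivity analysis), `synth` (seeded synthetic
fixtures for every experiment type), plus a `recq` command-line interface.

## Worked example

```python
import numpy as np
from recqcycle import (cycle_flux, default_rates, ratio_from_measurement,
                       solve_default_off_rates, simulate_runs, TranslocationConfig)

rates = default_rates("dna_bound")
print(f"k_cat (DNA-bound, 1 mM ATP): {cycle_flux(rates, 1000.0):.1f} 1/s")
print(f"k_cat (DNA-free,  1 mM ATP): {cycle_flux(default_rates('dna_free'), 1000.0):.3f} 1/s")
print(f"(k3+k-2)/k-2 from L1=35%, L2=0.8%, f=0.40: {ratio_from_measurement(35, 0.8, 0.40):.1f}")

off = solve_default_off_rates(rates, atp=100.0)
cfg = TranslocationConfig(rates=rates, off=off, atp=100.0, n_runs=10_000, seed=1)
summary, _ = simulate_runs(cfg, return_records=False)
print(f"occupancy T: {100*summary.occupancy['T']:.0f}%  D: {100*summary.occupancy['D']:.0f}%")
print(f"terminations in D: {100*summary.termination_fraction['D']:.0f}%")
print(f"mean cycles/run: {summary.mean_cycles:.1f}  mean nt/run: {summary.mean_nt:.0f}")
```

prints

```
k_cat (DNA-bound, 1 mM ATP): 30.9 1/s
k_cat (DNA-free,  1 mM ATP): 0.137 1/s
(k3+k-2)/k-2 from L1=35%, L2=0.8%, f=0.40: 17.5
occupancy T: 76%  D: 14%
terminations in D: 76%
mean cycles/run: 23.5  mean nt/run: 21
```

The two turnover numbers are the stationary cycle flux of the default
parameter sets and match the measured steady-state k_cat values (30 ± 3
and 0.13 ± 0.01 s⁻¹). The exchange inversion turns the measured
isotopologue percentages into the reversibility ratio of the hydrolysis
step. The translocation ensemble shows the ATP-bound state dominating the
bound population while the ADP-bound state dominates terminations; with a
coupling stoichiometry of 1.1 ATP per nucleotide, ~23 cycles per run
correspond to ~21 nt of translocation on a 54-mer oligo-dT-like track.

The same operations are scriptable from the shell, e.g.

```sh
recq translocate --n-runs 10000 --seed 1 --out out/summary.json
recq exchange --L1 35 --L2 0.8 --f 0.4
recq fit-global --condition dna_bound --seed 1 --out out
recq sensitivity --out out/sens.json
```

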