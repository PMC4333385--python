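# Methods

This note documents the models implemented in `recqcycle`, the provenance
and meaning of the default parameters, the synthetic-data conditions, the
numerical choices, and the limitations a user should know about.

## The four-state ATPase cycle

The enzyme cycles through apo (E), ATP-bound (T), post-hydrolytic
ADP·Pi-bound (DPi) and ADP-bound (D) states. ATP binding (step 1),
cleavage (step 2) and ADP release (step 4) are reversible; Pi release
(step 3) is treated as irreversible at zero added phosphate (k₋₃ = 0 by
default) because the effective phosphate dissociation constant
K_Pi,eff = K₃K₂/(K₂+1) exceeds 20 mM — steady-state turnover is barely
affected by 20 mM Pi. A finite second-order k₋₃ (μM⁻¹s⁻¹) is accepted for
phosphate-inhibition studies. Units: μM, seconds; second-order constants
(k₁, k₋₃, k₋₄) in μM⁻¹s⁻¹.

Three solvers share one rate-matrix definition and are cross-checked
against each other in the test suite:

* **Stationary solve** — null space of the pseudo-first-order generator;
  the cycle flux is k₃·π(DPi) − k₋₃[Pi]·π(D), identical through every step
  at stationarity.
* **Deterministic ODE** — full mass action with explicit ligand depletion
  (LSODA, rtol 1e-8, atol 1e-9 μM); enzyme and nucleotide moieties are
  conserved to better than 1e-6 relative. Pseudo-first-order conditions
  are available by clamping ligands. A sequestration flag models the
  fluorescent phosphate-binding reporter as instantaneous irreversible
  capture.
* **Gillespie sampler** — exact event-driven simulation of one enzyme at
  fixed ligand concentrations; an integer seed is mandatory everywhere, so
  no unseeded stochastic path exists in the package.

### Default parameter sets

Rate constants that were measured directly take their best-fit values.
Constants reported only as bounds are resolved once, as follows, and are
not treated as tunable:

| constant | DNA-bound | DNA-free | provenance |
|---|---|---|---|
| k₁ (μM⁻¹s⁻¹) | 8.4 | 8.0 | binding-line slope |
| k₋₁ (s⁻¹) | 36 | 117.85 | intercept (k₋₁+k₂) minus fitted k₂ |
| k₂ (s⁻¹) | 42 | 0.15 | constrained global fit |
| k₋₂ (s⁻¹) | 110 | 0.625 | k₃/k₋₂ fixed by the ¹⁸O-exchange ratio |
| k₃ (s⁻¹) | 1100 | 10 | at (DNA-bound) or above (DNA-free) its bound |
| k₋₃ | 0 | 0 | quasi-irreversible release (see above) |
| k₄ (s⁻¹) | 200 | 100 | quenched-flow bound / mdADP intercept |
| k₋₄ (μM⁻¹s⁻¹) | 4.4 | 4.5 | mdADP binding-line slope |

The exchange measurement fixes (k₃+k₋₂)/k₋₂ = 11 (bound) and 17 (free);
taking k₃ at 1100 gives k₋₂ = 110 for the bound set, and k₃ = 10 for the
free set places Pi release far above the rate-limiting cleavage so that no
burst is generated, as observed. A separate `md_analog` set, differing
only in k₄ = 100 s⁻¹, is used for fluorescent-nucleotide simulations: the
methylanthraniloyl label slightly strengthens the enzyme–ADP interaction,
and the mdADP experiments report the smaller release rate.

## Binding and chasing transients

`simulate_md_binding` generates, by default, the two-state relaxation that
stopped-flow analysis assumes: a single exponential with
k_obs = k₁C + k₋₁ + k₂ (mdATP; hydrolysis terminates the observed
pre-hydrolytic complex) or k₋₄C + k₄ (mdADP). Fitting these traces and
regressing k_obs on concentration therefore returns the association rate
constant and breakdown-pathway sum exactly, which is how the binding
parameters in the default sets are defined.

This is a deliberate modeling choice, not an approximation of convenience:
the full four-state simulation with every md-bound state contributing
equally to the fluorescence does **not** relax at k₁C + k₋₁ + k₂ in the
DNA-bound condition — post-hydrolysis states remain fluorescent, so the
fitted intercept of such traces falls near k₋₁ rather than k₋₁ + k₂. A
`model="full"` option exposes that simulation; in the DNA-free condition,
where turnover is slow, the two routes agree (k_obs ≈ 198 s⁻¹ at 10 μM
mdATP) and the tests use the full route as an independent cross-check. The
divergence in the DNA-bound case reflects a real ambiguity in what the
FRET signal reports state-by-state, which single-exponential data cannot
resolve; the relaxation model is the standard interpretation.

Chasing is simulated with the full competitive scheme (pre-equilibrated
enzyme·mdADP mixed with excess unlabeled ATP; only md-bound enzyme
fluoresces): the decay approaches k₄ as the chase suppresses rebinding,
within 2% at the 25-fold excess used experimentally.

## Quenched flow, Pi release and steady state

Fraction cleaved counts every cleaved γ-phosphate — enzyme-bound ADP·Pi
plus released Pi — divided by total ATP (an acid quench liberates bound
products). Pi-release progress curves use the sequestration flag; the
reporter concentration only triggers a saturation warning. Steady-state
curves take the linear-phase slope of captured Pi, excluding the first
5/k₂(effective) seconds and capping substrate depletion at ~2% over the
slope window; Hill fits of scheme-generated curves return n within
[0.95, 1.05] because a single-site cycle cannot generate cooperativity.
Burst amplitudes back-extrapolate the trailing linear phase to t = 0 and
require slope consistency between the two halves of the window (within
15%) before reporting; the default sets produce no burst (< 0.1/enzyme),
and an artificial fast-hydrolysis set reproduces the closed-form
(k₂/(k₂+k₄))² burst.

Note the scheme's own Briggs–Haldane K_M at the default constants is
~7 μM, below the measured K_ATP of 16 μM; a two-step ATP-binding
isomerization could reconcile the two, but single-exponential binding data
cannot constrain it, so no K_ATP claim is made or tested beyond the Hill
machinery itself.

## Constrained global fitting

The fit reproduces the published constraint structure: k₁ and k₋₄ fixed at
their stopped-flow values, k₃/k₋₂ pinned at the exchange ratio minus one
(10 DNA-bound, 16 DNA-free), and k₂, k₋₁, k₋₂ (carrying k₃) and k₄
floated. k₋₃ is fixed at zero by default — quenched-flow mixtures contain
no added Pi, so it is structurally unidentifiable there — with an option
to float it within [0, 0.01 μM⁻¹s⁻¹] (exercised in tests; k₂ recovery is
unaffected). Optimization is damped least squares (trust-region
reflective) on log-transformed rates, multi-start with log-uniform seeded
restarts (default 8); residuals are weighted by per-trace noise SD, and a
failed candidate simulation returns a large penalty rather than aborting.
Uncertainties come from a residual-resampling bootstrap (≥100 replicates)
refit from the point estimate.

Recovery calibration on the synthetic bundles (below): DNA-bound k₂ is
recovered with ~12% single-round scatter and <10% median error over 20
seeds. DNA-free recovery is intrinsically weaker: at the same noise level
the global optimum of some noisy replicates sits on a k₂/k₋₁ likelihood
ridge (weaker apparent ATP binding traded against faster cleavage) at 2–3
times the generating k₂. This is a property of the experimental design,
not of the optimizer — the fitted optimum scores better than the
generating truth on those replicates — and it mirrors the tension in the
published table between the stopped-flow 1/K₁ (15 μM) and the
quenched-flow global-fit 1/K₁ (120 μM), and the ~33% relative uncertainty
on the DNA-free k₂. Tests therefore hold DNA-bound recovery to 10% and
DNA-free recovery to the published precision.

Where a single headline k₂ is reported (acceptance script), six
independently seeded rounds are fitted and the mean is taken, emulating
the several-round replication behind the published means ± SEM.

## ¹⁸O exchange

Each cleavage incorporates one water oxygen (¹⁸O with probability f, the
water label fraction, treated as an infinite reservoir); with probability
p_rev = k₋₂/(k₃+k₋₂) the hydrolysis reverses before release, expelling one
oxygen and re-incorporating a fresh water oxygen on re-cleavage. The
expelled oxygen is chosen uniformly among the three oxygens *other than
the most recently incorporated water oxygen*. This convention reproduces
the first-order relation L₂/L₁ = f·p_rev exactly as p_rev → 0 (within
3.3% at p_rev = 1/11); complete positional randomization over all four
oxygens would instead give (3/4)·f·p_rev, inconsistent with the relation
used to interpret the measurements. Which oxygen microscopically returns
to water on resynthesis (bridging-position bookkeeping, partial
rotational freedom of bound Pi) is not resolvable from the isotopologue
ratios; the convention is documented, not adjudicated.

The released-Pi label distribution is computed by an exact linear
absorption solve over (label count, newest-oxygen label) states — no
series truncation — and is validated against a direct Monte-Carlo
simulation of the same process. Predicted triple labeling stays below
0.05% for both conditions, consistent with it being undetectable. The
mass-spectrometry report draws multinomial ion counts over the m/z 97,
99, 101, 103 classes, optionally admixing a labeled background fraction
emulating the contamination seen in enzyme-free controls.

## Translocation and run terminations

During a processive run the DNA-bound enzyme executes the cycle at fixed
ATP (products assumed dilute: no ADP/Pi rebinding) while each state can
detach with its own off rate; detachment is absorbing. Runs start in E at
the moment the preformed enzyme·ssDNA complex is mixed with excess ATP.
Each Pi-release event is one mechanochemical cycle; nucleotides traveled
are cycles divided by the coupling stoichiometry C = 1.1 ATP/nt. The
two-step (weak/strong) DNA-binding isomerization is collapsed into
single-step detachment: the weakly bound form carries only ~1% occupancy,
and full-model simulations were reported indistinguishable.

Per-state off rates are not individually published; they are **solved**
from two macroscopic outputs of the model — the fraction of terminations
occurring in the ADP-bound state (0.76) and the mean number of cycles per
run (23) — using the detachment-free stationary occupancies: k_off,net =
flux/⟨cycles⟩, off_D = 0.76·k_off,net/π_D, with the residual termination
flux assigned entirely to T, and zero detachment from DPi (the clamped,
strongly bound post-hydrolytic state) and from the negligibly populated
apo state. At 100 μM ATP (saturating; the simulation ATP is
config-overridable) this gives off_D ≈ 6.6 s⁻¹ and off_T ≈ 0.40 s⁻¹.
Because the inputs are the printed outputs, reproducing 76%/23 cycles is a
consistency check, not validation; the genuinely testable content is the
set of independent identities the simulation must satisfy: termination
fractions equal the occupancy-weighted off-rate decomposition, mean cycles
equal flux/k_off,net (renewal identity), run lengths are near-geometric,
and the ensemble agrees with closed-form absorbing-chain expectations
(expected cycles and durations are computed exactly by first-step
analysis, which also powers the 2-fold sensitivity table
deterministically). The sensitivity analysis scales one state's off rate
by 2 or 0.5 and reports run-length ratios; the ADP state dominates, the
mechanistic conclusion of the translocation model.

## Synthetic data

The generator emulates the experimental set: binding series at 5, 10, 20,
50, 100 μM for both md-nucleotides (50 log-spaced points, 1 ms–2 s,
truncated to the relaxation window); one 20 μM mdADP chase; single- and
multiple-turnover quenched flow at the experimental concentrations
(DNA-bound: 2 μM enzyme with 1.5 or 25 μM ATP, 15 log-spaced points
2 ms–5 s; DNA-free: 4 μM enzyme with 3 or 50 μM ATP, 2–60 s); Pi-release
progress curves at six ATP concentrations (0.25 μM enzyme); and one
multinomial isotopologue count table (2×10⁴ ions). Noise defaults —
fluorescence 2% of amplitude, fraction cleaved ±0.02 absolute, Pi traces
1% of final amplitude — are chosen so fitted standard errors land in the
same range as the published uncertainties; they are study conditions, not
dials. All randomness flows from one integer seed through SeedSequence
spawning, so a manifest plus its seed regenerates every file
bit-identically.

What the fixtures do not emulate: instrument dead time, mixing artifacts,
photobleaching, reporter kinetics (capture is instantaneous), detector
nonlinearity, and day-to-day enzyme-activity variation. Passing tests
therefore demonstrate internal consistency of the models and estimators at
realistic noise, not robustness to real-instrument systematics.

## Numerical choices and degenerate inputs

Stationary solves reject all-zero or reducible generators; the ODE
integrator reports solver failures with diagnostics; exponential fits
require ≥8 points and reject constant traces; line fits require ≥3
concentrations; Hill fits require ≥5 nonzero concentrations; burst
extraction rejects windows without a consistent linear phase; the
translocation simulator refuses all-zero off rates (infinite runs);
bootstrap intervals require ≥100 requested and ≥50 converged replicates.
Problem sizes used by the test suite and acceptance script (10⁴ runs,
10⁵–2×10⁵ Monte-Carlo molecules, 20-seed recovery calibrations, 6-round
fit replication) were chosen to make stochastic checks decisive at 3-SEM
tolerances while keeping a full run in the minutes range.

## Known limitations

* Single-step ATP binding: the measured K_ATP (16 μM) exceeds the
  scheme's Briggs–Haldane K_M (~7 μM); a binding isomerization is neither
  included nor excluded.
* The md-fluorescence observable is modeled at the level the data
  constrain (two-state relaxation); state-resolved fluorescence yields are
  unknown.
* k₄ differs between unlabeled (200 s⁻¹) and md-analog (100 s⁻¹) sets;
  both are carried, neither reconciled.
* The split of non-D termination flux among E, T and DPi is a declared
  convention (all to T), not a measurement.
* DNA-free k₂ is weakly identified by quenched-flow data alone (likelihood
  ridge described above).
* Translocation is not spatially resolved; step-size microstructure,
  duplex unwinding and branched substrates are out of scope.
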