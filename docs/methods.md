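# Methods

## The model

`thalamodyn` implements a deterministic four-population neural-mass model
of the thalamocortical loop: cortical pyramidal (PY) and interneuron (IN)
populations, the thalamocortical relay (TC) and the reticular thalamic
nucleus (RE), in the lineage of the lumped bistable thalamocortical
network of Suffczynski, Kalitzin & Lopes da Silva (2004, Neuroscience
126:467-484). Each population carries one mean membrane potential,

    C_m dV_i/dt = - Σ_syn g_syn (V_i - V_syn) - g_leak (V_i - V_leak),

with synapse classes AMPA (excitatory), GABA_A (fast inhibition) and
GABA_B (slow inhibition). A synaptic conductance is the convolution of a
bi-exponential kernel h(t) = A [exp(-a1 t) - exp(-a2 t)] (a2 > a1) with
the presynaptic firing density. Tonic firing density is a sigmoid of the
membrane potential, F(V) = G_F / (1 + exp(ν_F (V - θ_F))). The GABA_B
current carries an extra sigmoidal recruitment factor B(F) of the
presynaptic rate, so slow inhibition engages only under strong
(burst-mode) presynaptic firing. Thalamic populations add a
low-threshold burst mode

    F_B(V) = G_B · m_inf(V) · [h_n * n_inf(V)](t),

where m_inf opens with depolarisation, n_inf de-inactivates with
hyperpolarisation, and h_n is a unit-area bi-exponential lag kernel;
thalamic output firing density is the sum of the tonic and burst modes,
cortical populations fire tonically only. Thirteen directed pathways
(contact counts c1-c13) wire the populations and route the three external
drives (sensory → TC, cortical → PY, reticular GABA_A bias → RE); the
model output is V_PY. Drives are biased sinusoids φ_b + φ_a sin(2πft)
with no clipping: a drive may swing negative when φ_a > φ_b, standing in
for fluctuations about the mean of the pulse-density input.

### Finite-dimensional realisation

Every kernel convolution is realised exactly as a second-order linear
filter (g'' + (a1+a2) g' + a1 a2 g = A(a2−a1) u), verified against the
closed-form convolution in the test suite. The full state is 26
dimensional: 4 potentials, 9 conductance filters × 2, and 2 burst-lag
filters × 2. The two inter-module transport delays (cortex→thalamus on
the PY firing density, thalamus→cortex on the TC density) are supported
by a method-of-steps integrator with interpolated history; the shipped
default parameter file sets both to zero, absorbing conduction latency
into the synaptic rise times. The delay machinery is validated against
the piecewise closed-form solution of dx/dt = −x(t−1).

### Parameter provenance and calibration

The shipped default file (`data/thalamocortical_default.yaml`) documents
every entry with units. Wiring, equation structure, and kinetic time
constants (AMPA/GABA_A/GABA_B rise and decay, burst gating thresholds
and lag) follow the published description of the model family and
standard literature kinetics. Synaptic amplitudes and contact counts are
this package's own calibration, fixed once so the network reproduces the
documented operating regime of the original network: a stable
low-activity equilibrium coexisting with a large-amplitude ~10 Hz
paroxysmal limit cycle around the nominal operating biases (cortical
13.5 pps, sensory 11 pps, reticular 12 pps), and an abrupt resonant
transition onto the paroxysmal branch when the cortical drive frequency
approaches the paroxysmal rhythm. No property test depends on these
numbers; the analysis pipeline accepts any file with the same schema.

Known deviations of the calibrated network from the original model's
published phenomenology, stated plainly: the paroxysmal cycle is
self-sustaining at zero cortical bias (so the static cortical-bias scan
shows bistable and limit-cycle-only regions but no flanking fixed-point-
only regions), the sensory bias can open a bistable sub-window, and the
additional chaotic window under a 2 pps cortical drive sits at
~7.7-8.7 Hz rather than below the main resonance near 5.5-7.5 Hz.

## Numerics

Integration uses SciPy's adaptive embedded Runge-Kutta 4(5) pair.
Defaults: rtol 1e-8 / atol 1e-10 for fixture work; model scans use
rtol 1e-6 / atol 1e-8 (a convergence utility,
`tolerance_refinement_drift`, quantifies the terminal drift under
halved tolerances). Output is sampled on a fixed 1 ms grid independent
of the internal steps, so extrema and stroboscopic operators always see
uniform sampling; trajectories carry their exact terminal state for
final-state continuation between scan points. Stimulus-schedule switch
times are integrator breakpoints: a step restarts exactly at each
switch so the discontinuity in df/dt is never smeared. Frequency
switches are phase-continuous (the sine argument accumulates the phase
integral), so the drive itself never jumps.

Scans start their first grid point from the solved fixed point of the
constant inputs (`settled_equilibrium`, a 4-potential reduced root
problem with filters at their DC gains). Starting from the raw leak
state instead transiently charges the synaptic filters, which is a
large perturbation that knocks a bistable operating point onto the
oscillatory attractor and makes the quiet branch unreachable.

## Analysis operators

* Transient discard: scans simulate max(duration, 30 drive periods) per
  point and discard the first two thirds; regimes near bifurcations
  settle slowly, so the discard is generous.
* Extrema and sections: interior three-point local extrema; stroboscopic
  (V_c, dV_c/dt) samples once per drive period via cubic interpolation;
  single-linkage clustering with a 0.05 mV tolerance. A section is
  period-k when k clusters are visited cyclically.
* Maximal Lyapunov exponent: Benettin two-trajectory renormalisation
  (defaults d0 = 1e-6, renorm every 0.5 s, 200 s horizon after a 50 s
  transient for standalone estimates; scans use shorter, stated
  horizons). The perturbation direction is seeded; the estimator is
  validated within 10% of a long-horizon multi-seed fixed-step RK4
  oracle on the Lorenz attractor and is non-positive on stable and
  periodically forced linear fixtures. Implemented for undelayed systems
  (the shipped model has zero delays); delayed systems raise a clear
  error rather than silently linearising the history.
* Regime labels: FIXED_POINT when the output range is below 0.01 mV;
  CHAOTIC when the exponent clears a +0.005 s⁻¹ guard band (absorbing
  estimator noise); otherwise PERIODIC(k) from the section; conflicting
  evidence (positive exponent but a single tight section cluster) is
  labelled UNRESOLVED with the evidence attached.
* Jumps and hysteresis: a jump is an adjacent-grid-point amplitude ratio
  above 2 (reported at the step midpoint); hysteresis intervals are
  maximal runs where forward and backward sweep amplitudes differ by
  more than 10% of the larger.
* Bistability probes: each grid point is re-integrated from a small
  initial-condition library — the solved quiet equilibrium, the raw
  leak state, a uniformly depolarised state, and a thalamic rebound
  kick (TC/RE hyperpolarised with burst availability loaded, the
  release-from-inhibition trigger of the paroxysmal volley).  Terminal
  attractors are inventoried by kind (fixed point vs oscillation),
  amplitude and mean level; the regime map combines scan-direction
  evidence with probe evidence.  A finite probe library can only
  undercount attractors.

## Benchmark systems

The fixture module provides a forced linear resonator (closed-form
response), forced Duffing oscillators, the Lorenz system, and a 1-D
double-well gradient flow. Oracles are deliberately plain fixed-step
RK4 routines, independent of the adaptive pipeline they check. The
softening preset (δ=0.16, α=1, β=−1/6, γ=0.22) has a dense-IC-oracle
multistable window ω ∈ [0.79, 0.83]: continuation sweeps on a 0.02 grid
jump up at the upper edge (forward) and down at the lower edge
(backward). Probe initial conditions stay inside radius 1.5 because the
softening well escapes beyond |x| = √6 — which is also why softening
hysteresis demands care: at stronger forcing the upper branch ends by
escape rather than a fold. The twin-well preset (δ=0.3, α=−1, β=1,
γ=0.5) crosses a reverse period-doubling cascade along the frequency
axis: chaotic for ω ≤ 1.3, period-2 near 1.4-1.5, period-1 from 1.6.

These fixtures are mathematical test articles. Passing tests on them
shows that the analysis operators (integration, continuation, extrema,
sections, exponents, sweeps, probes) behave correctly on systems with
known answers; it does not by itself validate the thalamocortical
parameter values, which is why the parameter file's provenance and its
known deviations are documented above.

## Reproduction experiments and problem sizes

The shipped named configs run: bidirectional bias scans (0.1 pps
steps), the driven cortical-frequency bifurcation scan with per-point
exponents (5-15 Hz, 0.1 Hz steps, drive amplitude 1 pps),
frequency-switch transition protocols, and directional sensory sweeps
at the quiet operating point (cortical bias 12 pps). The acceptance
script (`scripts/acceptance.py`) uses 16 s per scan point with the
first two thirds discarded and an 18 s Benettin horizon per point;
the test suite uses restricted grids (e.g. 8-10 Hz around the jump,
0.25 Hz steps for the chaos-window scan). These problem sizes are the
package's defaults for desk-scale reproduction; all are configurable.

## Known limitations

* The default parameter set is a calibrated reconstruction, not a
  transcription of the original network's unpublished table; figure-level
  quantitative agreement is limited to the phenomena listed above.
* No stochastic input mode; drives are deterministic biased sinusoids.
* Single cortical + single thalamic module; no spatial extension.
* No Lyapunov spectrum, embedding-based analysis, or continuation of
  unstable branches.
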