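# Methods

`synaptor` simulates plasticity induction at a single hippocampal CA3→CA1
synapse as a piecewise-deterministic Markov process (PDMP): low-copy-number
molecular populations (vesicles, receptors, calcium channels, the plasticity
processes) jump stochastically, while everything downstream of them
(membrane potentials, spine calcium, the enzyme network, the readout
activations) flows deterministically between jumps. This note documents the
model, the numerical scheme, the calibration constants, and the known
limitations.

## Model

### Presynaptic terminal

Vesicles occupy a docked pool `D` (capacity 25) and a reserve pool `R`
(capacity 30) coupled by birth–death transitions whose rates vanish at the
pool bounds (refill `(D0−D)·R/τ_D`, mixing `(R0−R)·D/τ_R`, replenishment
`(R0−R)/τ_Rref` with τ = 5, 45, 40 s). A phenomenological calcium resource
`Ca_pre` jumps by `Ca_jump` at each spike and decays with τ = 20 ms;
`Ca_jump` recovers to 1 with τ = 20 s and is depressed in proportion to
`Ca_pre` (δ = 4·10⁻⁴), producing short-term depression of release. A spike
releases one vesicle with probability
`p_rel = Ca_pre² / (Ca_pre² + h([Ca²⁺]o)²)` if `D > 0`, where the threshold
`h` is a decreasing logistic in extracellular calcium. Released glutamate is
a 1 ms cleft pulse of gamma-distributed amplitude (mean 1000 µM, shape
1/0.52, scale 0.52); the same decision and amplitude are copied to the
co-released GABA signal (a single shared release process). Uncaging
experiments are modelled by forcing every release to succeed
(`forced_release`).

The printed gamma parameterisation `Γ(1/0.52, 0.52)` has mean 1 but
CV ≈ 0.72 rather than the quoted CV 0.52; the printed parameterisation is
used as-is (`glu_cv` in the parameter table controls it).

### Electrical compartments

Spine, dendrite and soma are single isopotential compartments (leak reversal
−70 mV). The soma fires Hodgkin–Huxley-style Na⁺/K⁺ action potentials
(γ_Na = 800 nS, γ_K = 40 nS) triggered by rectangular current injections at
the protocol's postsynaptic times (`I_amp` = 2.5 nA for `δ_inj` = 2 ms,
chosen so a lone injection elicits a soma spike overshooting 0 mV). The BaP
reaches the dendrite through the axial conductance
`g = λ · g_diff · φ_dist(d_soma)`, where `φ_dist` is a decreasing logistic
in the spine's distance from the soma and `λ ∈ (0,1]` is a use-dependent
resource: each somatic injection consumes a step of λ (amplified as the
auxiliary resource `λ_aux` depletes), and λ recovers with τ = 2 s. A third
resource `λ_age` scales the somatic spike currents with an age-dependent
step (young animals attenuate more). In field-stimulation mode an
EPSP-summation proxy (increment 1 per presynaptic spike, decay 40 ms) feeds
the release sigmoid; 25 afferent synapses are tested per spike and a
postsynaptic AP is evoked with 15 ms latency when more than 80% succeed.
Evoked-AP decisions, like release decisions, are drawn before the main
simulation from a dedicated random stream.

The published resource-step constants are coupled to the injected current
through a unit convention that does not survive in print (with currents in
pA the published steps would produce no attenuation at all). The product
(step × injection drive) is the physically meaningful per-spike use, so the
injection drive is a single calibrated dimensionless constant
(`bap_use_scale = 10⁶` during injection pulses, preserving the printed
δ_decay : δ_aux : δ_age ratios). It was calibrated once against the same
published observation the original step constants were adjusted to: the
dendritic BaP amplitude declines to ≈85% of the first pulse by the 30th
pulse of a 5 Hz train.

### Receptors and channels

* **AMPAr** — 120 receptors on a 16-state chain (closed C0–C4 with
  statistical binding multiplicities, open O2–O4 with subconductances
  15.5/26/36.5 pS, desensitised D0–D4, deep-desensitised D22–D24).
  Temperature scales glutamate binding (forward factor) and unbinding
  (backward factor) only; gating and desensitisation keep their
  room-temperature rates.
* **NMDAr** — 15 receptors split between GluN2A and GluN2B by an
  age-dependent logistic ratio with per-sample noise (N(0, 0.05), ~one
  receptor flipping subtype between samples); independent rounding of the
  two shares. Each subtype is a 7-state linear chain (two binding steps,
  three conformational steps, two conducting states); GluN2B uses the GluN2A
  rates × 0.25 (forward) and × 0.23 (backward), making it ~5× slower. The
  conductance is a declining logistic in extracellular calcium (91 pS at
  1.8 mM), gated by the voltage-dependent magnesium block
  `1/(1 + [Mg]o/3.57 · e^(−0.062 V))`. 10% of the NMDAr current is calcium,
  computed through the GHK flux rather than the ohmic term.
* **GABA(A)r** — 34 receptors on the 5-state ligand-gated chain (C0–C2,
  O1–O2); temperature scales only the closing rates. The chloride reversal
  potential follows the developmental KCC2 logistic, so GABA is
  depolarising in immature tissue and hyperpolarising (−92.6 mV asymptote)
  in adults.
* **VGCC** — three channels each of T-, R- and L-type. T and R factor into
  independent two-state activation (m) and inactivation (h) gates per
  channel (conducting iff m open and h available); L has one closed and two
  open states with distinct closing rates. A shared temperature factor pair
  scales all α (forward) and β (backward) rates. T-type channels open
  tonically near rest, producing a fluctuating calcium baseline.
* **SK** — deterministic calcium-activated potassium conductance (Hill
  sigmoid in calcium, exponent 6, half-activation 0.333 µM, τ = 6.3 ms
  scaled by its temperature pair), hyperpolarising the spine above −90 mV —
  the negative feedback from calcium to voltage.

### Spine calcium

`dCa/dt` sums (i) relaxation to the 50 nM baseline with τ = 10 ms, (ii)
channel influx `(Ca_NMDA + I_T + I_R + I_L) / (2 F Vol_spine)`, (iii)
diffusion to the dendrite with τ ≈ 0.5 ms, where the dendrite is assumed to
sit at one-third of spine calcium floored at baseline
(`max(Ca∞, Ca/3)` source), (iv) a generic endogenous buffer (62 µM,
Kd 2.12 µM), (v) calcium sequestration by the explicitly modelled CaM pool
(two ions per lumped step), and (vi) in dye mode a Fluo-5F species (200 µM,
Kd 1.58 µM) plus the published experimental adjustments (+10 °C effective
temperature for laser heating, damped BaP injection).

Calcium currents are `g_Ca × Φ(V)` with `Φ` the normalised GHK flux (zero
exactly at the calcium Nernst potential, series expansion across V = 0).
The single-channel calcium conductances are printed with garbled exponents
in the source tables; the 12 : 17 : 27 subtype ratios are kept at pS
magnitudes and the absolute GHK scale (`ghk_scale = 0.85`) is the model's
one free calcium parameter, calibrated once so a single successful vesicle
release yields ≈3 µM peak spine calcium at the default conditions (the same
anchoring the original permeability constant used). SK's conductance is
likewise taken at the physiological 10 pS.

### Enzyme network

A deterministic mass-action network of 17 concentrations: CaM in four
lumped loading states (calcium binds/unbinds in pairs at the C and N lobes,
with calcium-dependent effective rates `a·b/(c + d·Ca)` and forward fluxes
`k_f · X · Ca²`), CaMKII monomer units binding CaM at any loading state,
phosphorylation of CaM-bound kinase proportional to the already-active
fraction, autonomous states P and P2 after CaM release, and CaN binding
fully loaded CaM4 only. Totals of 30 µM CaM, 70 µM kinase and 20 µM CaN are
conserved exactly. Temperature scales the CaMKII dissociation steps k2, k3,
k5 (backward factor) and both CaN binding directions (its own factor pair,
shared in form with the VGCC pair). "Active CaMKII" is
KCaM + PCaM + P + P2; "active CaN" is the CaN·CaM4 complex. Because apo-CaM
binds the kinase slowly even at resting calcium, the relaxed resting state
carries ≈5 µM tonic active CaMKII; all runs start from the resting
equilibrium (100 s relaxation at baseline calcium).

### Geometric readout

The joint (CaN, CaMKII) trajectory is classified against two fixed polygons
fitted once to a corpus of experiments: the LTP rectangle
CaN ∈ [6.35, 10] µM × CaMKII ∈ [1.4, 29.5] µM, and an adjoining LTD polygon
whose published vertex list is canonicalised by angular sort about its
centroid (it abuts the LTP region's left edge at CaN = 6.35; boundary
points count as inside). Time inside a region charges a leaky activation
(rise 200 a.u./s for LTP, 100 for LTD; decay 0.1 s⁻¹ and 0.02 s⁻¹ outside),
and the activations drive sigmoidal transition rates (half-occupation
1.3·10⁴ and 8·10⁴ a.u.; ceilings 1/13 s⁻¹ and 1/18 s⁻¹) of 100 processes on
the chain LTD ⇄ NC ⇄ LTP — every toward-LTP transition uses the LTP rate
and every toward-LTD transition the LTD rate. The predicted weight change
(%) is `LTP − LTD`. The readout consumes the enzyme trajectories on a 10 ms
grid and its activations start fresh for every sample.

## Numerics

The engine advances all samples of a batch together on an event-segmented
grid. Within a segment the transmitter amplitude and the somatic injection
are constant, so:

* AMPAr/NMDAr/GABAr rate matrices are constant (they are
  voltage-independent), and per-channel one-step transition probabilities
  are computed *exactly* as `expm(Q dt)`; populations are resampled with one
  batched multinomial per chain per step. There is no small-rate
  approximation for receptors at any step size.
* T/R-type VGCC gates use the exact two-state transition probability with
  rates frozen over the step; the L-type uses exponential escape
  probabilities per state.
* Voltages, spike gates, SK, calcium and buffers advance with
  per-variable exponential-Euler updates (unconditionally stable; the spine
  compartment is effectively quasi-static at its sub-µs time constant).
  Calcium/buffer substeps are 50 µs during transients and collapse to one
  update near rest.
* The enzyme network advances with midpoint RK2 on a ≈0.25 ms sub-grid
  whose substeps shrink with calcium (lumped rates grow ~Ca²); RK2
  preserves the linear conservation laws to rounding (< 10⁻⁶ µM over
  a full run).

Steps are tiered by activity: 25 µs for 30 ms after each spike event,
0.25 ms while receptor tails remain active (400 ms), 0.5 ms in quiescence.
After the last transient (+1 s), only the enzyme network is integrated
(LSODA) at each sample's post-stimulus baseline calcium out to the readout
horizon (default protocol end + 400 s, covering the slow LTD activation
decay), and the readout then consumes the recorded trajectories; the
plasticity chain is resampled on ~0.1 s chunks using the chunk-integrated
rates (transition probabilities ≤ 10⁻² per chunk).

Exact-jump machinery (Gillespie for constant-rate chains, integrated-hazard
sampling for time-varying rates) backs the presynaptic pool simulation and
the statistical oracles in the test suite. Randomness derives from the run
seed through named child streams (release, evoked APs, subunit assignment,
channel gating, plasticity chain), so switching one source to its
mean-field mode (`deterministic_sources`) leaves the other draws untouched.
Mean-field mode propagates expected occupancies under the same transition
matrices.

## Parameters that matter most

| symbol | meaning | default | unit |
|---|---|---|---|
| `ca_o`, `mg_o` | aCSF composition | 2.5, 1.3 | mM |
| `temperature` | bath temperature | 35 | °C |
| `age` | animal age | 50 | days |
| `d_soma` | spine distance from soma | 200 | µm |
| `ghk_scale` | GHK flux scale (calibrated) | 0.85 | — |
| `bap_use_scale` | BaP resource drive (calibrated) | 10⁶ | — |
| `I_amp`, `delta_inj` | somatic injection | 2500 pA, 2 ms | |
| `N_AMPA/N_NMDA/N_GABA/N_VGCC` | copy numbers | 120/15/34/3×3 | |

The full constant table lives in `synaptor.params.DEFAULT_PARAMS` with the
internal unit system documented there; YAML configs can override any symbol
for sensitivity studies.

## Validation scope and known limitations

* The test suite validates structural invariants (conservation laws, exact
  dwell-time statistics, mass-action equivalence against an independently
  generated oracle, CTMC matrix-exponential checks of the plasticity chain)
  and quantitative reproductions of published observables (release
  probability, BaP attenuation, receptor deactivation constants, enzyme
  decay constants, the single-EPSP calcium amplitude). Passing these shows
  the machinery is self-consistent and anchored at a handful of published
  operating points; it does not by itself demonstrate predictive accuracy
  for arbitrary protocols or for real biological variability beyond what
  the model's stochastic sources represent.
* With the published rate constants and temperature-factor curves taken
  exactly as printed, several kinetic decay constants at 35 °C come out
  1.3–4× faster than the timescales quoted alongside them in the source
  (the same implementation at 25 °C reproduces the corresponding 25 °C
  values closely). The discrepancy is documented per observable in the
  acceptance outputs rather than hidden by re-tuning printed constants.
* The plasticity-region polygons are published constants fitted to the
  original model's enzyme orbits. With this implementation's calcium and
  enzyme amplitudes, strong burst-pairing protocols drive peak CaN activity
  past the LTP region's right edge (e.g. ≈14.8 µM sample-mean peak for a
  300-pairing burst-STDP protocol), so the orbit transits the region instead
  of dwelling in it and protocol-level outcomes differ from the experiments
  the regions were fitted to. The regions were deliberately not refitted
  (that one-time fitting procedure is outside this package's scope).
* Spatial structure is absent: one average spine, a single-compartment
  dendrite, no calcium microdomains, one generic endogenous buffer.
* Plasticity expression/maintenance is out of scope — the readout predicts
  induction outcomes only.
* The weakly-attenuating BaP neuron class is not modelled (the attenuation
  model follows the strongly-attenuating class).
* The spine BaP depolarisation is ≈79 mV with the printed passive/active
  constants (the source quotes "up to ~60 mV"); amplitude is not separately
  tunable without departing from printed conductances, so it is left as the
  constants produce it.
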