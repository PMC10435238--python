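# synaptor

A stochastic, multi-timescale model of plasticity **induction** at a single
hippocampal CA3→CA1 synapse, for computational neuroscientists who want to
ask *why the same synapse potentiates, depresses, or does nothing depending
on the experimental conditions* — animal age, bath temperature, aCSF
Ca²⁺/Mg²⁺ composition, distance of the spine from the soma — and on the
stimulation protocol (spike-timing pairings, frequency trains, theta bursts,
jittered or Poisson in-vivo-like activity).

## The model in one paragraph

The synapse is simulated as a piecewise-deterministic Markov process. A
stochastic presynaptic terminal (docked/reserve vesicle pools, release
probability `p_rel = Ca_pre²/(Ca_pre² + h([Ca²⁺]o)²)`) emits glutamate/GABA
pulses onto stochastic receptor populations — a 16-state AMPAr chain, GluN2A
and GluN2B NMDAr chains split by an age-dependent ratio, a 5-state GABA(A)r
whose chloride reversal matures with age, and T/R/L-type voltage-gated
calcium channels — embedded in a three-compartment electrical model whose
soma fires back-propagating action potentials with use-, distance- and
age-dependent attenuation. Calcium enters the spine through the
Goldman–Hodgkin–Katz flux (NMDAr fraction f_Ca = 0.1 plus VGCCs), is shaped
by extrusion, neck diffusion, a generic buffer and an SK-channel feedback
loop, and drives a deterministic coarse-grained CaM→CaMKII/CaN network. The
**geometric readout** classifies the joint (CaN, CaMKII) activity orbit
against fixed LTP/LTD polygons in the activity plane; time spent inside a
region charges leaky activations `d act/dt = a·1_region − b·(1−1_region)·act`
whose sigmoids drive a 100-process Markov chain LTD ⇄ NC ⇄ LTP. The
predicted weight change is `LTP − LTD` (%), distributed over repeated
samples exactly as experiments are distributed over slices.

## Worked example

Predict the outcome of a classic burst-STDP LTP protocol (one presynaptic
spike paired with a postsynaptic doublet 10 ms later, 300 pairings at 5 Hz)
at its native experimental conditions:

```python
from synaptor.engine import batch_run
from synaptor.protocols import build_protocol, preset_conditions

res = batch_run(build_protocol("1Pre2Post10, 300 at 5 Hz"),
                preset_conditions("tigaret2016"), n_samples=10, seed=7)
print(res.outcome.as_dict())
```

which prints

```
{'mean': -5.6, 'median': 2.0, 'q25': 1.0, 'q75': 3.0, 'n': 10}
```

together with per-sample weights `[4, 2, 6, 3, 1, -20, 2, 3, -58, 1]` (%).
Reading the result: the sample-mean CaN activity peaks at ≈14.8 µM and
CaMKII at ≈29.9 µM, so the joint orbit crosses the LTP region
(CaN ∈ [6.35, 10] µM) twice — on the way up and on the way down — rather
than dwelling inside it; most samples end near no-change and a minority,
whose orbits linger near the LTD region on the way back, depress. In this
re-implementation the burst-pairing orbit overshoots the published region
geometry (see the limitations section of `docs/methods.md`), so
protocol-level outcomes should be read as what this model computes, not as a
reproduction of the corresponding slice experiments. The distributional
output itself — one weight per sample, quartiles across samples — is the
object the model is designed to produce.

The same interface is available from a shell:

```bash
synaptor run --protocol "1Pre2Post10, 300 at 5 Hz" --preset tigaret2016 \
             --samples 10 --seed 7 --out run1.h5
synaptor readout --traj traj.csv --out dwell.csv   # reuse the readout alone
synaptor fit-decay --traj trace.csv --col can      # exponential decay fits
```

Conditions can also come from YAML (`--conditions file.yaml`) with an
optional `parameters:` block overriding any model constant for sensitivity
studies; see `synaptor/config.py` for the schema and
`synaptor.protocols.PRESETS` for the named experimental presets.

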