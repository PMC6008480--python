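# Methods

## Model

### Synapse

Each synapse carries a dimensionless weight `ω ∈ [ω_min, ω_max]`, read as the
normalized conductance of a memristive element. The weight changes only when
the pre-synaptic neuron spikes; the update is a modified logistic law signed
by the post-synaptic membrane potential relative to a set point:

    dω/dt = β · ω · (1 − ω/ω_max) − κ·ω     at pre-spike times
    dω/dt = −κ·ω                            otherwise

    β = k · ω · (V_post − V_critical)

`ω = 0` and `ω = ω_max` are exact fixed points of the drive term, so weights
saturate softly; plasticity is maximal at `ω = 2/3·ω_max` (mid-range
weights). The lower clamp `ω_min = 0.05` keeps silent connections
recoverable. `V_post` enters as its numeric value in volts (implicitly
normalized by 1 V) so that `β` carries the per-ms units of `k`; with the
calibrated table this gives per-event changes of order 10⁻² at `ω = 0.5`,
i.e. tens of percent over 25–60 protocol repetitions.

One spike event is integrated as a single forward-Euler step of duration
`tau_event` (default 1 ms). The inter-event leak is integrated exactly
(`ω ← ω·e^(−κ·dt)`), which is unconditionally stable and makes retention
independent of the simulation step.

### Neuron

Membranes follow the quadratic integrate-and-fire equation

    C du/dt = g̃_L (u − u_rest)(u − u_critical) + I(t)

with a stable rest at `u_rest`, an unstable critical point at `u_critical`,
threshold-and-reset spiking at `θ_thres`, and an absolute refractory period
`t_ref` during which `u` is held at `u_rest`. The printed form of this
equation in the source literature carries an inverted leading sign that
would make the resting potential unstable and raise the rheobase by ×38; we
use the standard sign, under which the closed-form rheobase
`g̃_L((u_critical−u_rest)/2)² = 0.1 mA` and the fixed-point structure hold.

State is SI internally (V, A, F, s); interface clocks are milliseconds.
Integration is classical RK4 with `dt = 0.05 ms` by default; threshold
crossings are detected at step end (spike time error ≤ dt per spike, far
below all protocol timescales).

### Parameters

| symbol | meaning | default |
|---|---|---|
| θ_thres | spiking threshold | 61.75 mV |
| u_critical | critical potential | 9.00 mV |
| u_rest | resting potential | −11.0 mV |
| C | membrane capacitance | 1 mF |
| g̃_L | leak coefficient | 1 (Ω V)⁻¹ |
| t_ref | refractory period | 2 ms (free parameter) |
| V_critical | plasticity set point | 0 V |
| k | learning-rate constant | 1.21 ms⁻¹ |
| κ | forgetting rate | 4.17·10⁻³ s⁻¹ = 4.17·10⁻⁶ ms⁻¹ |
| ω_min, ω_max | weight clamps | 0.05, 1.00 |
| tau_event | event duration | 1 ms |

**The κ unit.** The source table prints κ in ms⁻¹, but the network text
states a leak of 0.42 % *per second* — the same digits per second — and a
continuous leak of 4.17·10⁻³ per ms (time constant 240 ms) would erase more
weight between 60 Hz pairings than the largest possible event gain, making
potentiation impossible at any pairing frequency. We therefore default to
the per-second reading; κ is configurable per experiment, and the per-ms
value is still meaningful for the *event-local* leak term in single-update
arithmetic.

## Pairing protocols

Pre-synaptic spikes are imposed events; the post neuron is a full QIF
model. The post spike of each pairing is produced by a constant-current
ramp of duration `drive_window_ms` (default 16 ms) that ends at the nominal
pairing time; the amplitude is solved by bisection so the rest-to-threshold
flight equals the window. Under this drive the membrane crosses the set
point ~13 ms before each spike, so:

- pre-before-post (+10 ms) reads a depolarized membrane → potentiation;
- post-before-pre (−10 ms) reads the freshly reset membrane at
  `u_rest < 0` → depression — until, at high pairing rates, the *next*
  pairing's ramp slides under the pre spike. The sign therefore flips near
  `f ≈ 1000/(|Δt| + T_ramp − t₀)` (t₀ = rest-to-zero-crossing time of the
  ramp), ≈ 43 Hz with the defaults.
- with the continuous leak on, one pre-post event gains
  `k·V·ω²(1−ω)·τ ≈ 1.7·10⁻³` while a period loses `ωκ/f`; the balance
  breaks between 1 and 2 Hz, so 1 Hz pairings lose weight and ≥ 2 Hz
  pairings gain.

A 16 ms window is the longest that still fits inside a 60 Hz pairing
period together with the refractory gap; above ~55 Hz the window is
truncated to `period − t_ref` and the amplitude re-solved, which lowers
the sampled voltage and bends the pre-post curve down at the top of the
grid. A 1 ms suprathreshold pulse cannot realize these experiments: it
leaves the membrane at rest 10 ms before the spike, which would invert
the potentiating branch.

The voltage-clamp driver needs no neuron at all: the clamped updates
commute, and with the leak off the pulse rate is immaterial. Results carry
both the model-frame axis [−11, 61.75] mV and the −29 mV presentation
shift.

## Network

All-to-all, bidirectional, no self-projections. When neuron *i* spikes,
every outgoing weight `ω_ij` receives one event with
`V_post = u_j` sampled at the *start* of the spike step, before any reset
— an order-independent convention when several neurons spike in one step
(each source only touches its own row). The spike also queues a 1 ms
rectangular current pulse; neuron *j* receives
`Σ_{i∈spiking} ω_ij · I0_int / Σ_i ω_ij`, normalized by its **total
incoming weight**, the only per-target reading of the normalization that
bounds each neuron's recurrent drive by `I0_int` (a full volley delivers
exactly `I0_int` everywhere).

`I0_int = 2.4 A` is the reference amplitude of the 1024-neuron network
(incoming normalization ≈ 537); `default_internal_amplitude` scales it by
`(n−1)/1023`. For the 9-neuron experiments we use 2 mA: the recurrent
kicks accumulate near the slow resting fixed point (decay time constant
`C/(g̃_L·(u_critical−u_rest)) = 50 ms`), and amplitudes much above this
push undriven neurons over `u_critical`, desynchronizing the volleys that
the coding-dependent connectivity rests on.

### Rate vs temporal coding

*Rate coding* drives all pattern neurons with the constant current whose
steady rate matches the target frequency (solved by bisection on the
simulated f–I curve). Identically driven neurons spike in the same step,
each reading the partners' near-threshold (positive) membrane → symmetric
bidirectional potentiation inside the pattern; every pattern spike also
depresses the outgoing weights onto resting off-pattern neurons.

*Temporal coding* presents one item per frame (17 ms for single pixels,
19.2 ms for image sequences). The frame drive is solved so the
rest-to-threshold latency is `1.3 ×` the frame: the membrane passes
`u_critical` before its frame ends and the spike self-completes several
ms into the *successor's* frame, where the successor is already
depolarized above the set point. Hence forward links potentiate and all
other ordered pairs depress — a chain in presentation order. Driving at
the frame-matched rate current instead (latency < frame) puts every spike
inside its own frame while the successor still rests, and no chain can
form; the realized firing remains one spike per frame (≈ 59 Hz) either
way. One blank frame separates sweeps so the last item does not link onto
the first (8 chain edges among 9 neurons, not a 9-cycle).

## Metrics

Completion quality `Q(e) = (1/(a·f_max)) Σ f_n(e)` averages the recall
rates of the `a` *internal* (non-cued) target neurons; recall runs freeze
plasticity (attractor retrieval without further learning). `f_max`
defaults to the maximum internal rate observed across the cue-size grid,
which normalizes Q into [0, 1] by construction; it can be overridden. The
binary companion curve counts internal target neurons at ≥ 50 % of
`f_max` (configurable); both curves are reported because the
quantitative/qualitative distinction between the two published recall
curves is ambiguous. The connection census calls an ordered pair strong
at `ω ≥ (ω_min+ω_max)/2 = 0.525`, and the symmetry index is
`1 − Σ|ω_ij−ω_ji| / Σ(ω_ij+ω_ji)` over unordered pairs.

## Synthetic patterns

The contour generator draws 1-pixel closed outlines (circle, random
convex polygon, star-convex blob) centred on a 32×32 grid — a stand-in
for photograph-derived contours. It shares with real edge-detected
images the sparse-outline statistics and centring, but not their spatial
correlations or pixel-count variability, so network tests certify the
mechanism (completion onset below perfect completion, symmetric weight
formation), not the published photograph-specific thresholds (27 % / 85 %),
which depend on the external image set. User photographs can be run
through `load_grayscale` (block-mean resize) and `edge_detect`
(4-neighbour intensity step above threshold, then centring).

## Problem sizes

The pairing curves use the full 1–60 Hz integer grid with 60 pairings
each. Network tests run the 9-neuron system for 40 training sweeps and a
64-neuron (8×8) contour network trained for ~1.9 s with 0.8 s recalls,
sizes at which every qualitative claim above is already sharp; the
full-scale schedules (1024 neurons, 7.2 s training, 72 s recall, 500
sequence loops) are available through the CLI.

## Known limitations

- Spike times are step-end quantized; protocols align pre spikes to the
  integration grid.
- The STDP window's large-|Δt| tail reflects the finite drive ramp: pre
  spikes that precede the ramp read the resting potential and depress,
  rather than decaying to zero change as in the cellular data.
- `t_ref` and the pairing-drive geometry are free parameters constrained
  only by the protocol frequencies; the reported crossover shifts within
  a few Hz under reasonable alternatives.
- No inhibition, axonal delays, sparse connectivity, or learned
  feed-forward pathway; external cues are fixed currents.
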