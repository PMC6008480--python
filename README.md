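# memstdp

Simulation of a **memristive, voltage-based STDP rule** in quadratic
integrate-and-fire (QIF) networks — for computational neuroscientists and
neuromorphic engineers who want a minimal, fully reproducible model of how
a bounded, history-dependent conductance (a memristive synapse) supports
cellular plasticity phenomenology and, at the network level,
hippocampus-like auto-associative memory.

## The model

A synaptic weight `ω ∈ [ω_min, ω_max]` (normalized memristive conductance)
changes only when the pre-synaptic neuron spikes, in proportion to the
post-synaptic membrane potential:

    dω/dt = β ω (1 − ω/ω_max) − κω   at pre-spike times,  else  −κω
    β = k · ω · (V_post − V_critical)

so `V_post > V_critical` potentiates, `V_post < V_critical` depresses, the
logistic factor binds the weight softly to its range, and the leak κ
models both physiological forgetting and memristive retention loss.
Membranes follow the QIF equation
`C du/dt = g̃_L (u−u_rest)(u−u_critical) + I(t)` with threshold/reset and a
refractory period, integrated by classical RK4. In an all-to-all network,
a spike of neuron *i* updates every outgoing `ω_ij` with the partner's
instantaneous `u_j` and emits a current pulse normalized by the target's
total incoming weight. Rate-coded input forms **bidirectional, symmetric**
connectivity (pattern completion from fragments); temporally-coded input
forms **unidirectional chains** (sequence recall) — same engine, different
stimulus program.

## Worked example

Pairing a pre and a post spike 60 times at fixed ±10 ms offsets (6 Hz):

```python
>>> from memstdp.protocols import stdp_window, pair_frequency_curve, \
...     find_sign_crossover, ltp_failure_bound
>>> import numpy as np
>>> res = stdp_window([-10.0, 10.0])
>>> dict(zip(res.grid, res.change_percent.round(1)))
{-10.0: -18.0, 10.0: 22.0}
```

Pre-leading pairings potentiate the synapse by 22 % of its initial weight,
post-leading pairings depress it by 18 % — the classic STDP asymmetry.
Sweeping the post-pre branch over pairing frequency flips its sign:

```python
>>> curve = pair_frequency_curve(np.arange(1.0, 61.0), delta_t_ms=-10.0)
>>> round(find_sign_crossover(curve), 1)
43.6
```

Below ~44 Hz the post reads its (negative) resting potential when the pre
spike arrives → depression; above, the next pairing's depolarizing ramp
has already begun → potentiation. With the continuous forgetting rate
(0.42 %/s) switched on, pre-post pairings at 1 Hz lose more weight between
events than they gain at them:

```python
>>> leaky = pair_frequency_curve(np.arange(1.0, 61.0), delta_t_ms=10.0,
...                              leak_between=True)
>>> leaky.change_percent[0].round(1), ltp_failure_bound(leaky)
(-4.2, 2.0)
```

i.e. no net LTP below 2 Hz. At network level, presenting nine pixels
sequentially (17 ms frames) wires a 9-neuron network into a directed
chain:

```python
>>> from memstdp.config import ExperimentConfig
>>> from memstdp.experiments import run_net9_temporal
>>> sim, result, (n_bidir, n_unidir, sym) = \
...     run_net9_temporal(ExperimentConfig("net9_temporal"), sweeps=40)
>>> n_bidir, n_unidir
(0, 8)
```

eight strong unidirectional connections in presentation order and no
bidirectional pair, whereas rate-coded training of a static pattern makes
the pattern submatrix symmetric and bidirectional.

The same experiments are available as CLI subcommands, each writing a
run directory with the resolved config, rasters, weight matrices and
metric tables:

```
memstdp pair-frequency --branch post-pre --out runs/
memstdp net9-temporal --sweeps 50 --out runs/
memstdp ca3-train-recall --n-side 8 --train-ms 1920 --out runs/
```

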