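"""Bidirectional all-to-all recurrent network of QIF neurons.

Every ordered pair of distinct neurons (i, j) carries its own memristive
weight ``omega_ij`` (row = source, column = target); self-projections are
forbidden.  When neuron i spikes, (1) each of its outgoing weights
``omega_ij`` receives one plasticity event whose post-synaptic voltage is
the partner's instantaneous membrane potential ``u_j`` sampled at the
start of the spike step (before any reset), and (2) a rectangular current
pulse is queued for every other neuron j with amplitude

    I_j^int = omega_ij * I0_int / sum_i omega_ij ,

i.e. normalized by the *total incoming* weight of the target, so that a
volley of all sources delivers exactly ``I0_int`` to every neuron.  The
external drive is ``I_n^ext = I0_ext * P_n`` for a binary pattern P.

Depending on the coding of the stimulus the same engine produces
symmetric (rate-coded) or chain-like asymmetric (temporally-coded)
connectivity; only the stimulus program differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .neuron import NeuronParams, membrane_derivative
from .plasticity import PlasticityParams

__all__ = [
    "WeightMatrix",
    "StimulusProgram",
    "SimulationResult",
    "init_network",
    "external_current",
    "internal_current",
    "NetworkSimulator",
    "default_internal_amplitude",
]

#: Internal pulse amplitude of the 1024-neuron reference network (A).
I0_INT_CA3 = 2.4
#: External drive amplitude of the reference network (A).
I0_EXT_CA3 = 0.43025


def default_internal_amplitude(n: int) -> float:
    """Scale the reference 2.4 A pulse to an n-neuron network.

    Keeps the single-source kick (amplitude / total incoming weight)
    comparable across sizes: ``2.4 A * (n - 1) / 1023``.
    """
    return I0_INT_CA3 * (n - 1) / 1023.0


@dataclass
class WeightMatrix:
    """Dense n x n adjacency of weights; diagonal fixed at zero."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        self.omega = w
        np.fill_diagonal(self.omega, 0.0)

    @property
    def n(self) -> int:
        return self.omega.shape[0]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.omega.copy())

    def offdiag(self) -> np.ndarray:
        return self.omega[~np.eye(self.n, dtype=bool)]

    def save_txt(self, path) -> None:
        np.savetxt(path, self.omega, fmt="%.8f")

    @classmethod
    def load_txt(cls, path) -> "WeightMatrix":
        return cls(np.loadtxt(path))


def init_network(
    n: int,
    init_mode: str = "constant",
    seed: int | None = None,
    value: float = 0.5,
    params: PlasticityParams | None = None,
    explicit: np.ndarray | None = None,
) -> WeightMatrix:
    """Build the initial weight matrix.

    Modes: ``constant`` (all off-diagonal entries = ``value``),
    ``uniform-random`` (i.i.d. uniform on [omega_min, omega_max], seeded),
    or ``explicit`` (user-supplied matrix, diagonal zeroed).
    """
    if n < 2:
        raise ValueError("network needs at least 2 neurons")
    p = params or PlasticityParams()
    if init_mode == "constant":
        w = np.full((n, n), float(value))
    elif init_mode == "uniform-random":
        rng = np.random.default_rng(seed)
        w = rng.uniform(p.omega_min, p.omega_max, size=(n, n))
    elif init_mode == "explicit":
        if explicit is None:
            raise ValueError("explicit mode requires a matrix")
        w = np.array(explicit, dtype=float)
    else:
        raise ValueError(f"unknown init mode {init_mode!r}")
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w)


def external_current(pattern, I0_ext: float) -> np.ndarray:
    """Per-neuron external drive ``I0_ext * P`` for a binary pattern P."""
    P = np.asarray(pattern)
    if not np.all(np.isin(P, (0, 1))):
        raise ValueError("pattern must be binary (0/1)")
    return I0_ext * P.astype(float)


def internal_current(
    weights: WeightMatrix, spiking: Iterable[int], I0_int: float
) -> np.ndarray:
    """Recurrent current amplitude delivered to every neuron by a volley.

    Neuron j receives ``sum_{i in spiking} omega_ij * I0_int / sum_i omega_ij``;
    a zero incoming-weight column contributes nothing (guarded; cannot
    occur with omega_min > 0).
    """
    idx = np.fromiter(spiking, dtype=int, count=-1)
    w = weights.omega
    out = np.zeros(weights.n)
    if idx.size == 0:
        return out
    col_sums = w.sum(axis=0)
    ok = col_sums > 0
    out[ok] = w[np.ix_(idx, np.where(ok)[0])].sum(axis=0) * I0_int / col_sums[ok]
    return out


@dataclass
class StimulusProgram:
    """Time-resolved external current: (duration_ms, current vector) segments.

    The schedule may be repeated cyclically ``repeats`` times.  Currents
    are amperes per neuron; segments are contiguous and non-overlapping
    by construction.
    """

    segments: list[tuple[float, np.ndarray]]
    repeats: int = 1

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("program needs at least one segment")
        segs = []
        n = None
        for dur, cur in self.segments:
            cur = np.asarray(cur, dtype=float)
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if not np.all(np.isfinite(cur)):
                raise ValueError("segment currents must be finite")
            if n is None:
                n = cur.size
            elif cur.size != n:
                raise ValueError("inconsistent segment lengths")
            segs.append((float(dur), cur))
        self.segments = segs
        self._edges = np.cumsum([d for d, _ in segs])

    @property
    def cycle_ms(self) -> float:
        return float(self._edges[-1])

    @property
    def total_duration_ms(self) -> float:
        return self.cycle_ms * self.repeats

    def current_at(self, t_ms: float) -> np.ndarray:
        """Current vector at absolute time ``t_ms`` (zero after the end)."""
        if t_ms >= self.total_duration_ms or t_ms < 0:
            return np.zeros_like(self.segments[0][1])
        tc = t_ms % self.cycle_ms
        i = int(np.searchsorted(self._edges, tc, side="right"))
        return self.segments[min(i, len(self.segments) - 1)][1]


@dataclass
class SimulationResult:
    """Raster, weight snapshots and optional traces of one network run."""

    spike_neurons: np.ndarray
    spike_times_ms: np.ndarray
    snapshots: list[tuple[float, WeightMatrix]]
    traces: np.ndarray | None
    trace_times_ms: np.ndarray | None
    seed: int | None
    config: dict = field(default_factory=dict)

    def rates_hz(
        self, window_ms: tuple[float, float] | None = None, n: int | None = None
    ) -> np.ndarray:
        """Per-neuron firing rates over a time window (defaults to all)."""
        n = n or (int(self.spike_neurons.max()) + 1 if self.spike_neurons.size else 0)
        t0, t1 = window_ms or (0.0, float(self.spike_times_ms.max(initial=0.0)))
        if t1 <= t0:
            return np.zeros(n)
        sel = (self.spike_times_ms >= t0) & (self.spike_times_ms < t1)
        counts = np.bincount(self.spike_neurons[sel], minlength=n)
        return counts * 1000.0 / (t1 - t0)


class NetworkSimulator:
    """Integrates the coupled neuron + plasticity dynamics.

    One ``step`` advances all membranes by one RK4 step under the summed
    external and recurrent currents, applies plasticity for every spike,
    queues the outgoing current pulses, and (optionally) applies the
    continuous weight leak.
    """

    def __init__(
        self,
        weights: WeightMatrix,
        neuron_params: NeuronParams | None = None,
        plasticity_params: PlasticityParams | None = None,
        dt_ms: float = 0.05,
        I0_int: float | None = None,
        pulse_width_ms: float = 1.0,
        leak_between_spikes: bool = False,
        plasticity_on: bool = True,
    ) -> None:
        if dt_ms <= 0:
            raise ValueError("dt must be > 0")
        self.w = weights
        self.np_ = neuron_params or NeuronParams()
        self.pp = plasticity_params or PlasticityParams()
        self.dt_ms = dt_ms
        self.I0_int = default_internal_amplitude(weights.n) if I0_int is None else I0_int
        self.pulse_steps = max(int(round(pulse_width_ms / dt_ms)), 1)
        self.leak_between_spikes = leak_between_spikes
        self.plasticity_on = plasticity_on
        self._leak_factor = float(np.exp(-self.pp.kappa * dt_ms))
        n = weights.n
        self.u = np.full(n, self.np_.u_rest)
        self.refr_steps = np.zeros(n, dtype=int)
        self.t_ms = 0.0
        self._step_count = 0
        self._pulses: list[tuple[int, np.ndarray]] = []  # (expiry step, amplitude)
        self.spike_neurons: list[int] = []
        self.spike_times: list[float] = []

    # ------------------------------------------------------------------
    def _rk4(self, u: np.ndarray, I: np.ndarray) -> np.ndarray:
        dt = self.dt_ms * 1e-3
        p = self.np_
        k1 = membrane_derivative(u, I, p)
        k2 = membrane_derivative(u + 0.5 * dt * k1, I, p)
        k3 = membrane_derivative(u + 0.5 * dt * k2, I, p)
        k4 = membrane_derivative(u + dt * k3, I, p)
        return u + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0

    def step(self, I_ext: np.ndarray) -> np.ndarray:
        """Advance one step; returns the indices of neurons that spiked."""
        self._pulses = [p for p in self._pulses if p[0] > self._step_count]
        I = np.asarray(I_ext, dtype=float).copy()
        for _, amp in self._pulses:
            I += amp
        u_start = self.u.copy()
        u_new = self._rk4(self.u, I)
        refr = self.refr_steps > 0
        u_new[refr] = self.np_.u_rest
        spiking = np.where((~refr) & (u_new >= self.np_.theta_thres))[0]

        if self.plasticity_on and spiking.size:
            self._apply_plasticity(spiking, u_start)
        if spiking.size:
            amp = internal_current(self.w, spiking, self.I0_int)
            amp[spiking] = 0.0  # no self-drive within the volley
            self._pulses.append((self._step_count + 1 + self.pulse_steps, amp))
            u_new[spiking] = self.np_.u_rest
            self.refr_steps[spiking] = int(round(self.np_.t_ref_ms / self.dt_ms))
            t_spike = self.t_ms + self.dt_ms
            for i in spiking:
                self.spike_neurons.append(int(i))
                self.spike_times.append(t_spike)
        self.refr_steps[refr] -= 1
        if self.leak_between_spikes and self.pp.kappa > 0:
            w = self.w.omega
            np.multiply(w, self._leak_factor, out=w)
            np.clip(w, self.pp.omega_min, self.pp.omega_max, out=w)
            np.fill_diagonal(w, 0.0)
        self.u = u_new
        self._step_count += 1
        self.t_ms = self._step_count * self.dt_ms
        return spiking

    def _apply_plasticity(self, spiking: np.ndarray, u_snapshot: np.ndarray) -> None:
        """Update the outgoing row of every spiking source against the
        start-of-step membrane snapshot (order-independent by construction:
        each source touches only its own row)."""
        p = self.pp
        w = self.w.omega
        v = u_snapshot - p.V_critical
        for i in spiking:
            row = w[i]
            d = (p.k * v * row * row * (1.0 - row / p.omega_max) - p.kappa * row)
            row += d * p.tau_event
            np.clip(row, p.omega_min, p.omega_max, out=row)
            row[i] = 0.0

    # ------------------------------------------------------------------
    def run(
        self,
        program: StimulusProgram | None,
        duration_ms: float | None = None,
        snapshot_every_ms: float | None = None,
        record_traces: bool = False,
        seed: int | None = None,
        config: dict | None = None,
    ) -> SimulationResult:
        """Execute the program (or silence) for ``duration_ms``."""
        if duration_ms is None:
            if program is None:
                raise ValueError("need a program or an explicit duration")
            duration_ms = program.total_duration_ms
        n_steps = int(round(duration_ms / self.dt_ms))
        snap_every = (
            max(int(round(snapshot_every_ms / self.dt_ms)), 1)
            if snapshot_every_ms
            else None
        )
        zeros = np.zeros(self.w.n)
        snapshots = [(self.t_ms, self.w.copy())]
        traces = [] if record_traces else None
        trace_t = [] if record_traces else None
        for s in range(n_steps):
            I_ext = program.current_at(self.t_ms) if program is not None else zeros
            self.step(I_ext)
            if record_traces:
                traces.append(self.u.copy())
                trace_t.append(self.t_ms)
            if snap_every and (s + 1) % snap_every == 0:
                snapshots.append((self.t_ms, self.w.copy()))
        if snapshots[-1][0] != self.t_ms:
            snapshots.append((self.t_ms, self.w.copy()))
        return SimulationResult(
            spike_neurons=np.asarray(self.spike_neurons, dtype=int),
            spike_times_ms=np.asarray(self.spike_times),
            snapshots=snapshots,
            traces=np.asarray(traces) if record_traces else None,
            trace_times_ms=np.asarray(trace_t) if record_traces else None,
            seed=seed,
            config=config or {},
        )
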