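"""Quadratic integrate-and-fire (QIF) membrane dynamics.

The membrane potential obeys

    C du/dt = g_L * (u - u_rest) * (u - u_critical) + I(t)

which for I = 0 has a stable fixed point at the resting potential
``u_rest`` and an unstable one at the critical potential ``u_critical``;
above ``u_critical`` the quadratic term drives the potential to the
spiking threshold ``theta_thres``, after which it is reset to ``u_rest``
and held there for an absolute refractory period ``t_ref``.  The smallest
constant current for self-sustained spiking (rheobase) is
``g_L * ((u_critical - u_rest)/2)**2``.

State is kept in SI units (volts, amperes, farads); interface clocks are
in milliseconds.  Integration uses the classical fourth-order Runge-Kutta
scheme; threshold crossings are detected at step end and the spike time is
the step-end time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "ConfigurationError",
    "membrane_derivative",
    "rk4_step",
    "rheobase",
    "simulate_constant_current",
    "time_to_first_spike",
    "current_for_latency",
    "current_for_rate",
]


class ConfigurationError(ValueError):
    """Invalid integration or protocol configuration."""


@dataclass(frozen=True)
class NeuronParams:
    """QIF constants (SI units except ``t_ref_ms``).

    Defaults: threshold 61.75 mV, critical potential 9.00 mV, resting
    potential -11.0 mV, capacitance 1 mF, leak coefficient 1 (Ohm V)^-1.
    The refractory period is a free model parameter (default 2 ms).
    """

    C: float = 1e-3
    g_L: float = 1.0
    u_rest: float = -0.011
    u_critical: float = 0.009
    theta_thres: float = 0.06175
    t_ref_ms: float = 2.0

    def __post_init__(self) -> None:
        if not (self.u_rest < self.u_critical < self.theta_thres):
            raise ValueError(
                "need u_rest < u_critical < theta_thres, got "
                f"{self.u_rest}, {self.u_critical}, {self.theta_thres}"
            )
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError("C and g_L must be > 0")
        if self.t_ref_ms < 0:
            raise ValueError("t_ref_ms must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown neuron keys: {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass
class NeuronState:
    """Per-neuron dynamic state."""

    u: float
    refractory_remaining_ms: float = 0.0
    spike_flag: bool = False


def membrane_derivative(u, I, params: NeuronParams):
    """du/dt in V/s for membrane potential ``u`` (V) and current ``I`` (A)."""
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(I))):
        raise ValueError("non-finite input to membrane_derivative")
    return (params.g_L * (u - params.u_rest) * (u - params.u_critical) + I) / params.C


def rk4_step(state: NeuronState, I_of_t, dt_ms: float, params: NeuronParams) -> NeuronState:
    """Advance one classical RK4 step of length ``dt_ms``.

    ``I_of_t`` is either a constant current (A) or a callable of time in
    seconds relative to the step start.  During refractoriness the
    dynamics are suspended and ``u`` is held at ``u_rest``.  If the
    updated potential reaches ``theta_thres`` the neuron spikes: the flag
    is set, ``u`` is reset to ``u_rest`` and the refractory timer started.
    """
    if dt_ms <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt_ms}")
    if state.refractory_remaining_ms > 0:
        return NeuronState(
            params.u_rest, max(state.refractory_remaining_ms - dt_ms, 0.0), False
        )
    dt = dt_ms * 1e-3
    I = I_of_t if callable(I_of_t) else (lambda t, _I=I_of_t: _I)
    u = state.u
    k1 = membrane_derivative(u, I(0.0), params)
    k2 = membrane_derivative(u + 0.5 * dt * k1, I(0.5 * dt), params)
    k3 = membrane_derivative(u + 0.5 * dt * k2, I(0.5 * dt), params)
    k4 = membrane_derivative(u + dt * k3, I(dt), params)
    u_new = u + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    if u_new >= params.theta_thres:
        return NeuronState(params.u_rest, params.t_ref_ms, True)
    return NeuronState(u_new, 0.0, False)


def rheobase(params: NeuronParams) -> float:
    """Minimal constant current (A) for self-sustained spiking.

    Closed form ``g_L * ((u_critical - u_rest)/2)**2``, the depth of the
    quadratic nullcline.
    """
    return params.g_L * ((params.u_critical - params.u_rest) / 2.0) ** 2


def simulate_constant_current(
    I: float,
    params: NeuronParams,
    duration_ms: float,
    dt_ms: float = 0.05,
    u0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate under constant current; return (spike times ms, u trace)."""
    n = int(round(duration_ms / dt_ms))
    state = NeuronState(params.u_rest if u0 is None else u0)
    spikes, trace = [], np.empty(n + 1)
    trace[0] = state.u
    for i in range(n):
        state = rk4_step(state, I, dt_ms, params)
        trace[i + 1] = state.u
        if state.spike_flag:
            spikes.append((i + 1) * dt_ms)
    return np.asarray(spikes), trace


def time_to_first_spike(
    I: float, params: NeuronParams, dt_ms: float = 0.05, t_max_ms: float = 2000.0
) -> float:
    """Latency (ms) from rest to the first spike under constant current.

    Returns ``inf`` if no spike occurs within ``t_max_ms``.
    """
    state = NeuronState(params.u_rest)
    n = int(round(t_max_ms / dt_ms))
    for i in range(n):
        state = rk4_step(state, I, dt_ms, params)
        if state.spike_flag:
            return (i + 1) * dt_ms
    return math.inf


def current_for_latency(
    latency_ms: float,
    params: NeuronParams,
    dt_ms: float = 0.05,
    tol_ms: float | None = None,
) -> float:
    """Constant current whose rest-to-threshold latency equals ``latency_ms``.

    Solved by bisection on the simulated latency, which is strictly
    decreasing in the current above rheobase.
    """
    if latency_ms <= 0:
        raise ConfigurationError("latency must be > 0")
    tol = dt_ms if tol_ms is None else tol_ms
    lo = rheobase(params)  # latency -> inf
    hi = max(10.0 * lo, 1.0)
    while time_to_first_spike(hi, params, dt_ms, 4 * latency_ms) > latency_ms:
        hi *= 2.0
        if hi > 1e6:
            raise ConfigurationError(f"latency {latency_ms} ms unreachable")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        lat = time_to_first_spike(mid, params, dt_ms, 6 * latency_ms + 50.0)
        if lat > latency_ms:
            lo = mid
        else:
            hi = mid
        if abs(lat - latency_ms) <= tol and lat <= latency_ms:
            return mid
    return hi


def _steady_rate_hz(I: float, params: NeuronParams, dt_ms: float) -> float:
    """Steady-state firing rate under constant current, from spike intervals."""
    lat = time_to_first_spike(I, params, dt_ms, 3000.0)
    if not math.isfinite(lat):
        return 0.0
    period_ms = lat + params.t_ref_ms
    spikes, _ = simulate_constant_current(I, params, 3 * period_ms + 20.0, dt_ms)
    if len(spikes) < 2:
        return 0.0
    return 1000.0 / (spikes[-1] - spikes[-2])


def current_for_rate(
    target_rate_hz: float,
    params: NeuronParams,
    dt_ms: float = 0.05,
    rel_tol: float = 0.01,
) -> float:
    """Constant current whose simulated steady firing rate hits the target.

    Bisection on the (monotone non-decreasing) f-I curve; raises if the
    target exceeds the refractory-limited ceiling ``1000 / t_ref_ms``.
    """
    if target_rate_hz <= 0:
        raise ConfigurationError("target rate must be > 0")
    if params.t_ref_ms > 0 and target_rate_hz >= 1000.0 / params.t_ref_ms:
        raise ConfigurationError(
            f"rate {target_rate_hz} Hz unreachable with t_ref={params.t_ref_ms} ms"
        )
    lo = rheobase(params)
    hi = max(10.0 * lo, 1.0)
    while _steady_rate_hz(hi, params, dt_ms) < target_rate_hz:
        hi *= 2.0
        if hi > 1e6:
            raise ConfigurationError(f"rate {target_rate_hz} Hz unreachable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = _steady_rate_hz(mid, params, dt_ms)
        if r < target_rate_hz:
            lo = mid
        else:
            hi = mid
        if r > 0 and abs(r - target_rate_hz) <= rel_tol * target_rate_hz:
            return mid
    return hi
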