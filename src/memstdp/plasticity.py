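"""Memristive voltage-based synaptic plasticity rule.

The synaptic weight ``omega`` is the normalized conductance of a memristive
synapse, bounded to ``[omega_min, omega_max]``.  The weight changes only when
the pre-synaptic neuron spikes; the *direction* and magnitude of the change
are set by the instantaneous post-synaptic membrane potential ``V_post``
relative to a set-point voltage ``V_critical``.  The update follows a
modified logistic differential equation

    d(omega)/dt = beta * omega * (1 - omega / omega_max) - kappa * omega

with a weight- and voltage-proportional learning rate

    beta = k * omega * (V_post - V_critical),

so that ``omega = 0`` and ``omega = omega_max`` are exact fixed points of the
drive term and mid-range weights (around 2/3 of ``omega_max``) are the most
plastic.  Between spike events an optional exponential leak
``omega -> omega * exp(-kappa * dt)`` models both the continuous synaptic
depression seen in physiology and the retention loss of real memristive
devices.  The lower clamp ``omega_min > 0`` protects a silent connection
from being lost irreversibly.

Units: ``k`` and ``kappa`` are rates per millisecond, ``V_post`` enters as
its numeric value in volts (implicitly normalized by 1 V so that ``beta``
carries the units of ``k``), and ``tau_event`` -- the effective duration of
one spike-triggered update event -- is in milliseconds.  A single event is
one forward-Euler step of length ``tau_event``; the inter-event leak is
integrated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "PlasticityParams",
    "SynapseState",
    "learning_rate",
    "drift",
    "spike_update",
    "decay",
]

#: Continuous leak of 0.42 % per second expressed per millisecond.
KAPPA_PER_SECOND_DEFAULT = 4.17e-6


@dataclass(frozen=True)
class PlasticityParams:
    """Constants of the memristive plasticity rule.

    Parameters
    ----------
    k : float
        Learning-rate constant, per ms.
    kappa : float
        Forgetting (leak) rate, per ms.  The default corresponds to
        0.42 % per second, the continuous-depression rate used for the
        network simulations.
    omega_min, omega_max : float
        Hard weight clamps (dimensionless normalized conductance).
    V_critical : float
        Set-point voltage in volts; ``V_post`` above it potentiates,
        below it depresses.
    tau_event : float
        Effective duration of one spike-triggered update event, ms.
    V_clamp_low, V_clamp_high : float
        Admissible range of ``V_post`` for the voltage-clamp protocol,
        volts (resting potential to spiking threshold of the neuron model).
    """

    k: float = 1.21
    kappa: float = KAPPA_PER_SECOND_DEFAULT
    omega_min: float = 0.05
    omega_max: float = 1.00
    V_critical: float = 0.0
    tau_event: float = 1.0
    V_clamp_low: float = -0.011
    V_clamp_high: float = 0.06175

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.kappa >= 0):
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not (0 <= self.omega_min < self.omega_max <= 1):
            raise ValueError(
                f"need 0 <= omega_min < omega_max <= 1, got "
                f"[{self.omega_min}, {self.omega_max}]"
            )
        if not (self.V_clamp_low <= self.V_critical <= self.V_clamp_high):
            raise ValueError(
                "V_critical must lie inside the clamp range "
                f"[{self.V_clamp_low}, {self.V_clamp_high}]"
            )
        if not (self.tau_event > 0):
            raise ValueError(f"tau_event must be > 0, got {self.tau_event}")

    def clamp(self, omega):
        """Clip a weight (scalar or array) to ``[omega_min, omega_max]``."""
        return np.clip(omega, self.omega_min, self.omega_max)

    # -- flat key/value serialization ------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlasticityParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown plasticity keys: {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kw) -> "PlasticityParams":
        return replace(self, **kw)


@dataclass
class SynapseState:
    """Dynamic state of a single synapse: the weight ``omega``."""

    omega: float

    def spiked(self, V_post: float, params: PlasticityParams) -> "SynapseState":
        return SynapseState(spike_update(self.omega, V_post, params))

    def decayed(self, dt_ms: float, params: PlasticityParams) -> "SynapseState":
        return SynapseState(decay(self.omega, dt_ms, params))


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input to plasticity rule")


def learning_rate(omega, V_post, params: PlasticityParams):
    """Voltage- and weight-dependent learning rate beta, per ms.

    ``beta = k * omega * (V_post - V_critical)``; its sign equals the sign
    of ``V_post - V_critical``.
    """
    _check_finite(omega, V_post)
    return params.k * np.asarray(omega, dtype=float) * (V_post - params.V_critical)


def drift(omega, V_post, params: PlasticityParams):
    """Logistic drive term f = beta * omega * (1 - omega/omega_max), per ms.

    Exactly zero at ``omega = 0`` and ``omega = omega_max``; for fixed
    ``V_post > V_critical`` positive on the open interval with an interior
    maximum at ``2/3 * omega_max``.
    """
    om = np.asarray(omega, dtype=float)
    return learning_rate(om, V_post, params) * om * (1.0 - om / params.omega_max)


def spike_update(omega, V_post, params: PlasticityParams):
    """One spike-triggered weight update (forward-Euler over tau_event).

    ``omega <- clamp(omega + [f(omega, V_post) - kappa*omega] * tau_event)``.
    Invoked only at pre-synaptic spike times.
    """
    om = np.asarray(omega, dtype=float)
    d = (drift(om, V_post, params) - params.kappa * om) * params.tau_event
    out = params.clamp(om + d)
    return float(out) if np.isscalar(omega) else out


def decay(omega, dt_ms: float, params: PlasticityParams):
    """Exact inter-event leak ``omega <- clamp(omega * exp(-kappa*dt))``.

    Closed-form integration of the linear leak branch; unconditionally
    stable and independent of the simulation step.
    """
    if dt_ms < 0:
        raise ValueError(f"dt must be >= 0, got {dt_ms}")
    om = np.asarray(omega, dtype=float)
    out = params.clamp(om * math.exp(-params.kappa * dt_ms))
    return float(out) if np.isscalar(omega) else out
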