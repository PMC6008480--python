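"""Single-synapse plasticity protocols: voltage clamp, STDP window,
pair-frequency curves.

All drivers operate on one pre/post pair with the synapse initialized to
``omega = 0.5``.  Pre-synaptic spikes are imposed events (the rule reads
only the pre spike times and the post membrane potential); the post
neuron is a full QIF model.

In the pairing protocols the post neuron is brought to threshold by a
constant-current drive ramp of duration ``drive_window_ms`` ending at the
nominal pairing time; the amplitude is solved so the rest-to-threshold
flight time equals the window.  With the default 16 ms window the
membrane is depolarized above the set-point voltage for the final ~13 ms
before each post spike, which realizes the potentiating branch for
pre-before-post pairings, the depressing branch (post just reset to the
negative resting potential) for post-before-pre pairings, and a
depression-to-potentiation crossover of the post-pre branch near 40 Hz as
the next pairing's ramp slides under the pre spike.

Timing convention: ``delta_t = t_post_spike - t_pre_spike`` (positive =
pre leads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .neuron import ConfigurationError, NeuronParams, current_for_latency
from .plasticity import PlasticityParams

__all__ = [
    "ProtocolResult",
    "ProtocolError",
    "voltage_clamp",
    "stdp_window",
    "pair_frequency_curve",
    "find_sign_crossover",
    "ltp_failure_bound",
    "DEFAULT_DRIVE_WINDOW_MS",
]

DEFAULT_DRIVE_WINDOW_MS = 16.0
OMEGA_INIT = 0.5


class ProtocolError(ValueError):
    """Protocol configuration outside its admissible range."""


@dataclass
class ProtocolResult:
    """Grid of an independent variable vs relative weight change in %."""

    grid: np.ndarray
    change_percent: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.change_percent = np.asarray(self.change_percent, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.change_percent)):
            raise ValueError("weight changes must be finite")


# ---------------------------------------------------------------------------
def voltage_clamp(
    V_grid,
    n_pulses: int = 25,
    plasticity: PlasticityParams | None = None,
    pulse_rate_hz: float = 1.0,
    leak_between: bool = False,
    omega0: float = OMEGA_INIT,
) -> ProtocolResult:
    """Pre-spike train at a fixed (clamped) post-synaptic potential.

    For each voltage on the grid, ``n_pulses`` spike-triggered updates are
    applied (plus the inter-pulse leak when ``leak_between``); the
    relative weight change in percent of the initial weight is reported.
    The result also carries the presentation axis shifted by -29 mV, the
    convention used to overlay the model frame [-11, 61.75] mV on the
    experimental [-40, 32.75] mV scale.
    """
    p = plasticity or PlasticityParams()
    V_grid = np.asarray(V_grid, dtype=float)
    if np.any(V_grid < p.V_clamp_low - 1e-12) or np.any(V_grid > p.V_clamp_high + 1e-12):
        raise ProtocolError(
            f"clamp voltages must lie in [{p.V_clamp_low}, {p.V_clamp_high}] V"
        )
    period_ms = 1000.0 / pulse_rate_hz
    gap = max(period_ms - p.tau_event, 0.0)
    leak_factor = math.exp(-p.kappa * gap) if leak_between else 1.0
    changes = np.empty_like(V_grid)
    for m, V in enumerate(V_grid):
        om = omega0
        for _ in range(n_pulses):
            d = (p.k * (V - p.V_critical) * om * om * (1.0 - om / p.omega_max)
                 - p.kappa * om) * p.tau_event
            om = min(max(om + d, p.omega_min), p.omega_max)
            om = min(max(om * leak_factor, p.omega_min), p.omega_max)
        changes[m] = 100.0 * (om - omega0) / omega0
    return ProtocolResult(
        V_grid,
        changes,
        meta={
            "protocol": "voltage_clamp",
            "n_pulses": n_pulses,
            "pulse_rate_hz": pulse_rate_hz,
            "omega0": omega0,
            "leak_between": leak_between,
            "presentation_grid_V": V_grid - 0.029,
        },
    )


# ---------------------------------------------------------------------------
def _simulate_pairing(
    delta_t_ms: float,
    pair_freq_hz: float,
    n_pairs: int,
    plasticity: PlasticityParams,
    neuron: NeuronParams,
    dt_ms: float,
    drive_window_ms: float,
    leak_between: bool,
    omega0: float,
    drive_current: float | None = None,
) -> float:
    """Simulate one pairing series; return the final weight.

    The post neuron integrates (scalar RK4 inlined for speed) under a
    rectangular drive of duration ``T_f = min(drive_window, period - t_ref)``
    ending at each nominal pairing time.  At every pre-spike step the
    synapse receives one event update with the membrane value at the start
    of that step; the continuous leak (if on) is applied per step in exact
    exponential form.
    """
    period_ms = 1000.0 / pair_freq_hz
    if abs(delta_t_ms) >= period_ms:
        raise ProtocolError(
            f"|delta_t| = {abs(delta_t_ms)} ms must be below the pairing "
            f"period {period_ms:.2f} ms"
        )
    T_f = min(drive_window_ms, period_ms - neuron.t_ref_ms)
    if T_f <= 0:
        raise ProtocolError("pairing period shorter than the refractory period")
    if n_pairs == 0:
        return omega0
    if drive_current is None:
        drive_current = current_for_latency(T_f, neuron, dt_ms)

    t0 = min(-T_f - 1.0, -delta_t_ms - 1.0)
    t_end = (n_pairs - 1) * period_ms + max(0.0, -delta_t_ms) + 2.0
    n_steps = int(round((t_end - t0) / dt_ms))
    pre_steps = set(
        int(round((m * period_ms - delta_t_ms - t0) / dt_ms)) for m in range(n_pairs)
    )

    # locals for the tight loop
    g, C = neuron.g_L, neuron.C
    ur, uc, th = neuron.u_rest, neuron.u_critical, neuron.theta_thres
    ref_steps = int(round(neuron.t_ref_ms / dt_ms))
    dt_s = dt_ms * 1e-3
    k, kap, vc = plasticity.k, plasticity.kappa, plasticity.V_critical
    om_lo, om_hi, tau = plasticity.omega_min, plasticity.omega_max, plasticity.tau_event
    leak_f = math.exp(-kap * dt_ms) if (leak_between and kap > 0) else 1.0

    u = ur
    refr = 0
    om = omega0
    for i in range(n_steps):
        t = t0 + i * dt_ms
        if i in pre_steps:
            d = (k * (u - vc) * om * om * (1.0 - om / om_hi) - kap * om) * tau
            om = om + d
            om = om_lo if om < om_lo else (om_hi if om > om_hi else om)
        if leak_f != 1.0:
            om *= leak_f
            om = om_lo if om < om_lo else om
        if refr > 0:
            refr -= 1
            u = ur
        else:
            # drive on when t lies in [m*P - T_f, m*P) for the next pairing
            phase = t % period_ms
            if phase < 0:
                phase += period_ms
            on = (phase >= period_ms - T_f) and (t < (n_pairs - 1) * period_ms)
            I = drive_current if on else 0.0
            k1 = (g * (u - ur) * (u - uc) + I) / C
            u2 = u + 0.5 * dt_s * k1
            k2 = (g * (u2 - ur) * (u2 - uc) + I) / C
            u3 = u + 0.5 * dt_s * k2
            k3 = (g * (u3 - ur) * (u3 - uc) + I) / C
            u4 = u + dt_s * k3
            k4 = (g * (u4 - ur) * (u4 - uc) + I) / C
            u = u + dt_s * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            if u >= th:
                u = ur
                refr = ref_steps
    return om


def _pairing_change_percent(
    delta_t_ms, pair_freq_hz, n_pairs, plasticity, neuron, dt_ms,
    drive_window_ms, leak_between, omega0=OMEGA_INIT,
) -> float:
    om = _simulate_pairing(
        delta_t_ms, pair_freq_hz, n_pairs, plasticity, neuron, dt_ms,
        drive_window_ms, leak_between, omega0,
    )
    return 100.0 * (om - omega0) / omega0


def stdp_window(
    dt_grid_ms,
    n_pairs: int = 60,
    pair_freq_hz: float = 6.0,
    plasticity: PlasticityParams | None = None,
    neuron: NeuronParams | None = None,
    dt_ms: float = 0.05,
    drive_window_ms: float = DEFAULT_DRIVE_WINDOW_MS,
    leak_between: bool = False,
) -> ProtocolResult:
    """Weight change vs spike-timing offset (pairings at fixed frequency).

    ``delta_t > 0``: pre leads (post is depolarized toward threshold when
    the pre spike arrives -> potentiation); ``delta_t < 0``: post leads
    (post just reset to its negative resting potential -> depression).
    """
    p = plasticity or PlasticityParams()
    nr = neuron or NeuronParams()
    dt_grid_ms = np.asarray(dt_grid_ms, dtype=float)
    changes = np.array(
        [
            _pairing_change_percent(
                d, pair_freq_hz, n_pairs, p, nr, dt_ms, drive_window_ms, leak_between
            )
            for d in dt_grid_ms
        ]
    )
    return ProtocolResult(
        dt_grid_ms,
        changes,
        meta={
            "protocol": "stdp_window",
            "n_pairs": n_pairs,
            "pair_freq_hz": pair_freq_hz,
            "omega0": OMEGA_INIT,
            "leak_between": leak_between,
            "drive_window_ms": drive_window_ms,
        },
    )


def pair_frequency_curve(
    freq_grid_hz=None,
    delta_t_ms: float = 10.0,
    n_pairs: int = 60,
    leak_between: bool = False,
    plasticity: PlasticityParams | None = None,
    neuron: NeuronParams | None = None,
    dt_ms: float = 0.05,
    drive_window_ms: float = DEFAULT_DRIVE_WINDOW_MS,
) -> ProtocolResult:
    """Weight change vs pairing frequency at a fixed +-10 ms offset.

    ``delta_t_ms = +10`` selects the pre-post branch, ``-10`` the
    post-pre branch.  With the continuous leak on, low-frequency pre-post
    pairings yield no net potentiation because the infrequent
    spike-triggered gains cannot outrun the constant forgetting.
    """
    p = plasticity or PlasticityParams()
    nr = neuron or NeuronParams()
    if freq_grid_hz is None:
        freq_grid_hz = np.arange(1.0, 61.0)
    freq_grid_hz = np.asarray(freq_grid_hz, dtype=float)
    changes = np.array(
        [
            _pairing_change_percent(
                delta_t_ms, f, n_pairs, p, nr, dt_ms, drive_window_ms, leak_between
            )
            for f in freq_grid_hz
        ]
    )
    branch = "pre-post" if delta_t_ms > 0 else "post-pre"
    return ProtocolResult(
        freq_grid_hz,
        changes,
        meta={
            "protocol": "pair_frequency",
            "branch": branch,
            "delta_t_ms": delta_t_ms,
            "n_pairs": n_pairs,
            "omega0": OMEGA_INIT,
            "leak_between": leak_between,
            "drive_window_ms": drive_window_ms,
        },
    )


def ltp_failure_bound(result: ProtocolResult) -> float | None:
    """Largest frequency bound below which pairings yield no net gain.

    For a pair-frequency sweep this is the smallest grid frequency whose
    final weight exceeds the initial one; every grid frequency strictly
    below it failed to potentiate.  ``None`` when no grid point
    potentiates.
    """
    pos = result.grid[result.change_percent > 0]
    return float(pos.min()) if pos.size else None


def find_sign_crossover(result: ProtocolResult) -> float | None:
    """Linearly interpolated zero crossing of the weight change.

    Returns the first grid position where the change switches sign, or
    ``None`` when the curve never changes sign.
    """
    x, y = result.grid, result.change_percent
    s = np.sign(y)
    for i in range(len(x) - 1):
        if s[i] == 0:
            return float(x[i])
        if s[i] * s[i + 1] < 0:
            return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    if s[-1] == 0:
        return float(x[-1])
    return None
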