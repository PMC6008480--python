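"""Analysis metrics: completion quality, completion curves and the
bidirectional/unidirectional connection census.

The completion quality of a recall run is the mean firing rate of the
*internally* activated target neurons (those not driven externally),
normalized by the maximal internal rate f_max:

    Q(e) = (1 / (a * f_max)) * sum_{n=1..a} f_n(e)

with ``a`` the number of internal target neurons and ``e`` the number of
externally stimulated ones.  The binary companion measure counts the
share of internal target neurons whose rate exceeds a criterion fraction
of f_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSimulator, SimulationResult, StimulusProgram, WeightMatrix
from .neuron import NeuronParams
from .patterns import Pattern
from .plasticity import PlasticityParams

__all__ = [
    "completion_quality",
    "completion_curve",
    "CompletionCurve",
    "connection_census",
    "symmetry_index",
]


def completion_quality(
    result: SimulationResult,
    target: Pattern,
    externally_stimulated,
    f_max: float,
    window_ms: tuple[float, float] | None = None,
) -> float:
    """Normalized mean recall rate of the internal target neurons.

    Linear in the measured rates and invariant to relabeling; equals 1
    when every internal target neuron fires at ``f_max`` and 0 when none
    fires.  When the full target is stimulated externally there are no
    internal neurons and the quality is 1 by convention.
    """
    if f_max <= 0:
        raise ValueError("f_max must be > 0")
    stim = set(int(i) for i in np.asarray(externally_stimulated).ravel())
    internal = [i for i in target.active() if i not in stim]
    if not internal:
        return 1.0
    rates = result.rates_hz(window_ms=window_ms, n=target.n)
    return float(np.mean(rates[internal]) / f_max)


@dataclass
class CompletionCurve:
    """Completion quality and binary completion fraction vs cue size."""

    e_grid: np.ndarray
    e_fraction: np.ndarray
    Q: np.ndarray
    completed_fraction: np.ndarray
    f_max: float
    onset_fraction: float | None
    perfect_fraction: float | None
    meta: dict = field(default_factory=dict)


def completion_curve(
    trained: WeightMatrix,
    target: Pattern,
    e_grid,
    recall_duration_ms: float,
    recall_current: float,
    neuron: NeuronParams | None = None,
    plasticity: PlasticityParams | None = None,
    dt_ms: float = 0.05,
    I0_int: float | None = None,
    rate_criterion: float = 0.5,
    f_max: float | None = None,
    seed: int | None = None,
) -> CompletionCurve:
    """Recall performance of a trained network vs number of cued neurons.

    For each cue size ``e`` a fresh copy of the trained network is
    stimulated on ``e`` of the target's neurons (chosen reproducibly
    under the seed) for ``recall_duration_ms`` with plasticity frozen,
    and the internal target rates are measured.  Unless given, ``f_max``
    is the maximum internal rate observed anywhere on the curve, so that
    Q is normalized to [0, 1] by construction.  The onset threshold is
    the smallest cue fraction with any internal activity; the
    perfect-completion threshold is the smallest fraction at which every
    internal target neuron reaches ``rate_criterion * f_max``.
    """
    nr = neuron or NeuronParams()
    pp = plasticity or PlasticityParams()
    act = target.active()
    a_tot = act.size
    e_grid = np.asarray(e_grid, dtype=int)
    if np.any(e_grid > a_tot):
        raise ValueError("cue size exceeds the target's active pixel count")
    rng = np.random.default_rng(seed)
    cue_order = rng.permutation(act)

    per_e = []
    for e in e_grid:
        stim = cue_order[:e]
        internal = np.array([i for i in act if i not in set(stim)], dtype=int)
        I_ext = np.zeros(target.n)
        I_ext[stim] = recall_current
        sim = NetworkSimulator(
            trained.copy(), nr, pp, dt_ms=dt_ms, I0_int=I0_int, plasticity_on=False
        )
        res = sim.run(
            StimulusProgram([(recall_duration_ms, I_ext)]), recall_duration_ms
        )
        rates = res.rates_hz(window_ms=(0.0, recall_duration_ms), n=target.n)
        per_e.append((e, internal, rates))

    if f_max is None:
        f_max = max(
            (rates[internal].max() for _, internal, rates in per_e if internal.size),
            default=0.0,
        )
        if f_max <= 0:
            f_max = 1.0  # no internal activity anywhere: Q stays 0
    Q = np.empty(len(e_grid))
    comp = np.empty(len(e_grid))
    for m, (e, internal, rates) in enumerate(per_e):
        if internal.size == 0:
            Q[m], comp[m] = 1.0, 1.0
            continue
        r = rates[internal]
        Q[m] = float(np.mean(r) / f_max)
        comp[m] = float(np.mean(r >= rate_criterion * f_max))
    frac = e_grid / a_tot
    onset = next(
        (
            float(frac[m])
            for m, (e, internal, rates) in enumerate(per_e)
            if internal.size and rates[internal].max() > 0
        ),
        None,
    )
    perfect = next((float(frac[m]) for m in range(len(e_grid)) if comp[m] >= 1.0), None)
    return CompletionCurve(
        e_grid=e_grid,
        e_fraction=frac,
        Q=Q,
        completed_fraction=comp,
        f_max=float(f_max),
        onset_fraction=onset,
        perfect_fraction=perfect,
        meta={"rate_criterion": rate_criterion, "recall_duration_ms": recall_duration_ms},
    )


def symmetry_index(w: np.ndarray | WeightMatrix, subset=None) -> float:
    """1 - sum|w_ij - w_ji| / sum(w_ij + w_ji) over unordered pairs i<j.

    Equals 1 for a symmetric matrix; optionally restricted to the
    submatrix of a neuron subset.
    """
    m = w.omega if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        m = m[np.ix_(idx, idx)]
    iu = np.triu_indices(m.shape[0], k=1)
    num = np.abs(m[iu] - m.T[iu]).sum()
    den = (m[iu] + m.T[iu]).sum()
    return float(1.0 - num / den) if den > 0 else 1.0


def connection_census(
    w: WeightMatrix | np.ndarray,
    strong_threshold: float = 0.525,
    subset=None,
) -> tuple[int, int, float]:
    """(bidirectional pair count, unidirectional edge count, symmetry index).

    An ordered pair (i, j) is *strong* iff ``w_ij >= threshold``; an
    unordered pair is bidirectional when both directions are strong and
    unidirectional when exactly one is.  The default threshold is the
    midpoint of the weight range, (omega_min + omega_max) / 2.
    """
    m = w.omega if isinstance(w, WeightMatrix) else np.asarray(w, dtype=float)
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        m = m[np.ix_(idx, idx)]
    strong = m >= strong_threshold
    np.fill_diagonal(strong, False)
    both = strong & strong.T
    one = strong ^ strong.T
    n_bidir = int(both.sum() // 2)
    n_unidir = int(one.sum() // 2)
    return n_bidir, n_unidir, symmetry_index(m)
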