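"""Stimulus encoding: rate-coded and temporally-coded programs.

Rate coding drives all active pixels of a pattern simultaneously with a
constant current chosen for a target firing rate; the co-active neurons
then potentiate each other symmetrically.  Temporal coding presents the
sequence items one at a time, each for one frame; the frame drive is
chosen so that a neuron's rest-to-threshold flight slightly outlasts the
frame, which makes its spike fall inside the successor's frame while the
successor is already depolarized -- the substrate for unidirectional
chain connections.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .network import StimulusProgram, external_current
from .neuron import NeuronParams, current_for_latency, current_for_rate
from .patterns import Pattern

__all__ = [
    "rate_program",
    "temporal_program",
    "CHAIN_LATENCY_FACTOR",
]

#: Frame-drive latency as a multiple of the frame length for temporal coding.
CHAIN_LATENCY_FACTOR = 1.3


def rate_program(
    pattern: Pattern | np.ndarray,
    duration_ms: float,
    rate_hz: float | None = 60.0,
    drive_current: float | None = None,
    neuron: NeuronParams | None = None,
    dt_ms: float = 0.05,
    repeats: int = 1,
) -> StimulusProgram:
    """Constant drive of the pattern's neurons at a target firing rate."""
    px = pattern.pixels if isinstance(pattern, Pattern) else np.asarray(pattern)
    if drive_current is None:
        drive_current = current_for_rate(rate_hz, neuron or NeuronParams(), dt_ms)
    return StimulusProgram(
        [(duration_ms, external_current(px, drive_current))], repeats=repeats
    )


def _item_pixels(item, n: int) -> np.ndarray:
    if isinstance(item, Pattern):
        if item.n != n:
            raise ValueError("pattern size inconsistent with sequence")
        return item.pixels
    px = np.zeros(n, dtype=np.uint8)
    px[int(item)] = 1
    return px


def temporal_program(
    sequence: Sequence,
    n: int,
    per_item_ms: float = 17.0,
    loops: int = 1,
    drive_current: float | None = None,
    neuron: NeuronParams | None = None,
    dt_ms: float = 0.05,
    gap_ms: float = 0.0,
    latency_factor: float = CHAIN_LATENCY_FACTOR,
) -> StimulusProgram:
    """Cyclic program presenting sequence items one frame at a time.

    ``sequence`` holds pixel indices (single-pixel items) or whole
    ``Pattern`` objects; ``n`` is the network size.  At any instant at
    most one item is active.  When ``drive_current`` is not given it is
    solved so the rest-to-threshold latency equals
    ``latency_factor * per_item_ms``; with the default factor 1.3 each
    item's spike lands a few milliseconds into the next frame, where the
    next item's neurons are already depolarized above the set-point
    voltage, so consecutive items wire up forward and only forward.  An
    optional blank ``gap_ms`` separates loops so the last item does not
    link back onto the first.
    """
    if per_item_ms <= 0:
        raise ValueError("per_item_ms must be > 0")
    if loops < 1:
        raise ValueError("loops must be >= 1")
    if not len(sequence):
        raise ValueError("empty sequence")
    if drive_current is None:
        drive_current = current_for_latency(
            latency_factor * per_item_ms, neuron or NeuronParams(), dt_ms
        )
    segments = [
        (per_item_ms, drive_current * _item_pixels(item, n).astype(float))
        for item in sequence
    ]
    if gap_ms > 0:
        segments.append((gap_ms, np.zeros(n)))
    return StimulusProgram(segments, repeats=loops)
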