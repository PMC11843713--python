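"""Leading-edge discrimination and the adaptive timestamp pickoff.

A segmented readout yields two timestamps (T_A, T_B) per interaction.  The
adaptive pickoff selects the earlier of the two with a margin ``k``:
``T_A if T_A - T_B <= k else T_B`` — at ``k = 0`` this is the earlier
timestamp, the operating point at which the coincidence timing resolution
of a symmetric detector is best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = [
    "TriggerResult",
    "leading_edge_timestamp",
    "adaptive_timestamp",
    "adaptive_timestamp_array",
    "trigger_time_difference",
    "trigger_event",
]


@dataclass(frozen=True)
class TriggerResult:
    """Per-event trigger summary.  Absent timestamps are ``None``;
    ``delta_t`` (= T_A - T_B) is defined only when both pixels triggered."""

    t_a: float | None
    t_b: float | None
    t_adaptive: float | None
    delta_t: float | None
    threshold: float
    k_margin: float


def leading_edge_timestamp(waveform: Waveform, threshold: float) -> float | None:
    """Time of the first upward crossing of ``threshold``, or ``None``.

    The crossing time is linearly interpolated between the two samples
    bracketing the threshold, matching oscilloscope post-processing
    practice.  A trace already above threshold at its first sample triggers
    at ``t0``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    s = waveform.samples
    above = s >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(waveform.t0)
    frac = (threshold - s[i - 1]) / (s[i] - s[i - 1])
    return float(waveform.t0 + waveform.dt * (i - 1 + frac))


def adaptive_timestamp(
    t_a: float | None, t_b: float | None, k: float = 0.0
) -> float | None:
    """Adaptive pickoff: the earlier timestamp with margin ``k``.

    Returns ``t_a`` when ``t_a - t_b <= k``, else ``t_b``; with ``k = 0``
    this is ``min(t_a, t_b)``.  If only one timestamp is defined it is
    returned as-is; if neither, ``None``.
    """
    if t_a is None:
        return t_b
    if t_b is None:
        return t_a
    return t_a if t_a - t_b <= k else t_b


def adaptive_timestamp_array(
    t_a: np.ndarray, t_b: np.ndarray, k: float = 0.0
) -> np.ndarray:
    """Vectorized :func:`adaptive_timestamp`; NaN marks absent timestamps."""
    t_a = np.asarray(t_a, float)
    t_b = np.asarray(t_b, float)
    with np.errstate(invalid="ignore"):
        pick_a = (t_a - t_b) <= k
    out = np.where(pick_a, t_a, t_b)
    out = np.where(np.isnan(t_a), t_b, out)
    out = np.where(np.isnan(t_b), np.where(np.isnan(t_a), np.nan, t_a), out)
    return out


def trigger_time_difference(t_a: float | None, t_b: float | None) -> float | None:
    """Trigger time difference T_A - T_B; ``None`` unless both defined."""
    if t_a is None or t_b is None:
        return None
    return t_a - t_b


def trigger_event(
    waveform_a: Waveform,
    waveform_b: Waveform,
    threshold: float,
    k: float = 0.0,
) -> TriggerResult:
    """Discriminate both pixel waveforms and combine the timestamps."""
    t_a = leading_edge_timestamp(waveform_a, threshold)
    t_b = leading_edge_timestamp(waveform_b, threshold)
    return TriggerResult(
        t_a=t_a,
        t_b=t_b,
        t_adaptive=adaptive_timestamp(t_a, t_b, k),
        delta_t=trigger_time_difference(t_a, t_b),
        threshold=threshold,
        k_margin=k,
    )
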