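"""Foot-strike angle (FSA) extraction.

The running foot-angle trace is rescaled by subtracting the mean foot
angle of a standing static trial, so that 0 deg corresponds to a foot
parallel to the ground (dorsiflexion positive, plantar flexion
negative).  The FSA of a stride is the rescaled angle at the
foot-strike instant, taken from the nearest kinematic sample at or
before the force-detected event (no future information at contact).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .gait_events import GaitEvents
from .traces import AngleTrace

__all__ = ["FootStrikeAngle", "rescale_to_static", "fsa_at_footstrike", "average_fsa"]


@dataclass(frozen=True)
class FootStrikeAngle:
    fsa: float  # degrees, dorsiflexion positive
    stride_index: int
    fs_time: float  # s


def rescale_to_static(running: AngleTrace, static: AngleTrace) -> AngleTrace:
    """Subtract the scalar mean of the static trial from the running trace."""
    valid = static.samples[~np.isnan(static.samples)]
    if valid.size == 0:
        raise ValueError("static trace has no valid samples")
    return replace(running, samples=running.samples - float(valid.mean()))


def fsa_at_footstrike(rescaled: AngleTrace, events: GaitEvents) -> list[FootStrikeAngle]:
    """Sample the rescaled trace at each foot-strike; one record per stride.

    Foot strikes outside the trace span (or landing on a missing sample)
    are skipped with a warning.
    """
    out: list[FootStrikeAngle] = []
    n = len(rescaled)
    for i, t in enumerate(events.foot_strikes):
        idx = rescaled.index_at_or_before(t)
        if idx < 0 or idx >= n:
            warnings.warn(f"foot-strike at t={t:.3f}s outside angle trace; skipped",
                          stacklevel=2)
            continue
        value = rescaled.samples[idx]
        if np.isnan(value):
            warnings.warn(f"foot-strike at t={t:.3f}s lands on a missing sample; skipped",
                          stacklevel=2)
            continue
        out.append(FootStrikeAngle(fsa=float(value), stride_index=i, fs_time=float(t)))
    return out


def average_fsa(angles: list[FootStrikeAngle], n: int) -> float:
    """Mean FSA over the first ``n`` strides (degrees)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(angles) < n:
        raise ValueError(f"only {len(angles)} foot-strike angles available, need {n}")
    return float(np.mean([a.fsa for a in angles[:n]]))
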