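"""Conditioning of raw force and kinematic traces.

Three steps mirror the standard motion-capture processing chain:
cubic-polynomial gap filling of kinematic dropouts, low-pass Butterworth
filtering (20 Hz, 4th order by default), and integer-factor decimation
of the force signal to the kinematic rate.

The Butterworth filter is applied bidirectionally by default (zero phase
lag), which preserves event timing; the nominal order is the per-pass
order, so the effective attenuation of a zero-lag pass corresponds to
twice that order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .traces import AngleTrace, ForceTrace

__all__ = ["FilterSpec", "GapFillResult", "fill_gaps", "lowpass", "downsample"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings.

    cutoff : corner frequency in Hz (must lie below Nyquist)
    order : per-pass filter order
    zero_lag : apply forward and backward (no phase shift) when True
    """

    cutoff: float = 20.0
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


class GapFillResult(NamedTuple):
    trace: AngleTrace
    unfilled: pd.DataFrame  # columns: start_frame, length, reason


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) index ranges of True runs in ``mask``."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def fill_gaps(trace: AngleTrace, max_gap: int = 20, fit_window: int = 3) -> GapFillResult:
    """Fill missing runs with a cubic least-squares polynomial.

    Each missing run of length <= ``max_gap`` is replaced by evaluating a
    third-order polynomial fitted to ``fit_window`` valid frames on each
    side of the gap.  Longer runs, and runs without ``fit_window``
    contiguous valid frames on both sides (trace boundaries), are left
    missing and reported.  Observed samples are never modified.
    """
    y = trace.samples.copy()
    n = y.size
    unfilled: list[dict] = []
    for start, end in _missing_runs(np.isnan(y)):
        length = end - start
        left = np.arange(start - fit_window, start)
        right = np.arange(end, end + fit_window)
        if length > max_gap:
            unfilled.append({"start_frame": start, "length": length, "reason": "too_long"})
            continue
        if (
            left[0] < 0
            or right[-1] >= n
            or np.isnan(y[left]).any()
            or np.isnan(y[right]).any()
        ):
            warnings.warn(
                f"gap at frames [{start}, {end}) lacks {fit_window} valid frames "
                "on one side; left unfilled",
                stacklevel=2,
            )
            unfilled.append({"start_frame": start, "length": length, "reason": "boundary"})
            continue
        x = np.concatenate([left, right])
        coeffs = np.polyfit(x - start, y[x], deg=3)
        y[start:end] = np.polyval(coeffs, np.arange(length))
    report = pd.DataFrame(unfilled, columns=["start_frame", "length", "reason"])
    return GapFillResult(replace(trace, samples=y), report)


def lowpass(trace, spec: FilterSpec = FilterSpec()):
    """Low-pass Butterworth filter a trace; returns a new trace of the same type."""
    if np.isnan(trace.samples).any():
        raise ValueError("trace has missing samples; fill gaps before filtering")
    nyquist = trace.rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyquist} Hz")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=trace.rate, output="sos")
    if spec.zero_lag:
        filtered = sps.sosfiltfilt(sos, trace.samples)
    else:
        filtered = sps.sosfilt(sos, trace.samples)
    return replace(trace, samples=np.asarray(filtered))


def downsample(trace: ForceTrace, target_rate: float) -> ForceTrace:
    """Keep every k-th sample, k = source_rate / target_rate (must be integer).

    The caller is expected to low-pass filter first; no anti-alias filter
    is applied here.  Timestamps of the kept samples are preserved.
    """
    ratio = trace.rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"source rate {trace.rate} Hz is not an integer multiple of "
            f"target rate {target_rate} Hz"
        )
    k = int(round(ratio))
    return replace(trace, samples=trace.samples[::k].copy(), rate=target_rate)
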