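"""Force-threshold gait event detection and stride temporal variables.

Foot-strike (FS) and toe-off (TO) are found by thresholding the vertical
ground-reaction force at 20 N: within each step, FS is the first sample at
or above the threshold and TO the last.  From consecutive same-foot events
the stride variables follow:

    contact time   tc = TO - FS
    stride time    T  = FS_next - FS
    swing time     ts = T - tc
    stride freq.   SF = 1 / T
    duty factor    DF = tc / (tc + ts) = tc * SF

Running requires DF < 0.5 (an aerial phase exists).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import ForceTrace

__all__ = [
    "GaitEvents",
    "StrideMetrics",
    "StrideSummary",
    "detect_events",
    "stride_metrics",
    "average_strides",
    "metrics_frame",
]

#: contacts shorter than this are treated as noise artifacts and dropped
MIN_CONTACT_S = 0.025


@dataclass(frozen=True)
class GaitEvents:
    """Ordered foot-strike and toe-off times (s) for one trial, same foot."""

    foot_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        fs = np.asarray(self.foot_strikes, dtype=float)
        to = np.asarray(self.toe_offs, dtype=float)
        object.__setattr__(self, "foot_strikes", fs)
        object.__setattr__(self, "toe_offs", to)
        if abs(fs.size - to.size) > 1:
            raise ValueError("foot-strike and toe-off lists differ by more than one")
        k = min(fs.size, to.size)
        if k and not np.all(fs[:k] < to[:k]):
            raise ValueError("events must alternate FS < TO")
        if fs.size >= 2 and not np.all(to[: fs.size - 1] < fs[1:]):
            raise ValueError("events must alternate TO < next FS")

    @property
    def n_strides(self) -> int:
        """Number of complete FS-to-FS cycles."""
        return max(self.foot_strikes.size - 1, 0)


def detect_events(
    trace: ForceTrace,
    threshold: float = 20.0,
    min_contact_s: float = MIN_CONTACT_S,
) -> GaitEvents:
    """Detect FS/TO by thresholding a (filtered) vertical force trace.

    Each maximal run of samples >= ``threshold`` is one contact.  A contact
    touching the start or end of the trace is partial and discarded; runs
    shorter than ``min_contact_s`` are discarded as artifacts.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    # at the threshold-0 limit a contact is the strictly positive support,
    # otherwise zero-force swing samples would merge all contacts into one
    above = trace.samples > 0 if threshold == 0 else trace.samples >= threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]  # half-open index runs
    times = trace.times()
    fs_times, to_times = [], []
    n = trace.samples.size
    for start, end in zip(starts, ends):
        if start == 0 or end == n:
            continue  # partial contact at a trace boundary
        if (end - 1 - start) / trace.rate < min_contact_s:
            continue
        fs_times.append(times[start])
        to_times.append(times[end - 1])
    if not fs_times:
        warnings.warn("no contacts found above threshold", stacklevel=2)
    return GaitEvents(np.array(fs_times), np.array(to_times))


@dataclass(frozen=True)
class StrideMetrics:
    """Temporal variables of one complete stride."""

    tc: float
    ts: float
    stride_time: float
    sf: float
    df: float


@dataclass(frozen=True)
class StrideSummary(StrideMetrics):
    """Per-trial average over n strides.

    ``df`` is the mean of per-stride duty factors (the primary value);
    ``df_ratio_of_means`` recomputes it as mean(tc)/mean(stride time) for
    sensitivity checks — the two differ only under stride-to-stride
    variability.
    """

    df_ratio_of_means: float = float("nan")
    n_strides: int = 0


def stride_metrics(events: GaitEvents) -> list[StrideMetrics]:
    """One record per complete FS-to-FS cycle of the same foot."""
    if events.n_strides < 1:
        raise ValueError("need at least two foot-strikes for one complete stride")
    out = []
    fs, to = events.foot_strikes, events.toe_offs
    for i in range(events.n_strides):
        tc = to[i] - fs[i]
        stride_time = fs[i + 1] - fs[i]
        ts = stride_time - tc
        if tc <= 0 or ts <= 0:
            raise ValueError(f"non-positive contact or swing time in stride {i}")
        out.append(
            StrideMetrics(
                tc=tc, ts=ts, stride_time=stride_time, sf=1.0 / stride_time,
                df=tc / stride_time,
            )
        )
    return out


def average_strides(metrics: list[StrideMetrics], n: int) -> StrideSummary:
    """Arithmetic mean of each stride variable over the first ``n`` strides."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(metrics) < n:
        raise ValueError(f"only {len(metrics)} complete strides available, need {n}")
    sel = metrics[:n]
    tc = float(np.mean([m.tc for m in sel]))
    ts = float(np.mean([m.ts for m in sel]))
    stride_time = float(np.mean([m.stride_time for m in sel]))
    return StrideSummary(
        tc=tc,
        ts=ts,
        stride_time=stride_time,
        sf=float(np.mean([m.sf for m in sel])),
        df=float(np.mean([m.df for m in sel])),
        df_ratio_of_means=tc / stride_time,
        n_strides=n,
    )


def metrics_frame(metrics: list[StrideMetrics], **ids) -> pd.DataFrame:
    """Tidy per-stride table; ``ids`` become leading constant columns."""
    rows = [
        {**ids, "stride_index": i, "tc_s": m.tc, "ts_s": m.ts,
         "stride_time_s": m.stride_time, "sf_hz": m.sf, "df": m.df}
        for i, m in enumerate(metrics)
    ]
    return pd.DataFrame(rows)
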