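"""Uniformly sampled signal containers for gait analysis.

Two trace types flow through the pipeline: the vertical ground-reaction
force (N, typically 1000 Hz) and the sagittal foot segment angle
(degrees, dorsiflexion positive, typically 200 Hz).  Missing kinematic
frames are represented as NaN in :class:`AngleTrace`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForceTrace", "AngleTrace"]


@dataclass(eq=False)
class _Trace:
    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.rate

    def index_at_or_before(self, t: float) -> int:
        """Index of the nearest sample at or before time ``t`` (no future data)."""
        # small epsilon so an event lying exactly on a sample maps to that sample
        return int(np.floor((t - self.t0) * self.rate + 1e-9))


@dataclass(eq=False)
class ForceTrace(_Trace):
    """Vertical ground-reaction force signal; values in newtons, all finite."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force trace must be finite everywhere")


@dataclass(eq=False)
class AngleTrace(_Trace):
    """Sagittal foot segment angle in degrees; NaN samples flag missing frames."""

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.samples)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.samples).sum())
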