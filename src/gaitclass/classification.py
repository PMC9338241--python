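"""Runner classification schemes.

Two per-speed classifications are compared throughout the package:

* foot-strike pattern (FSP) from fixed FSA thresholds — rearfoot (RFS)
  if FSA >= 8 deg, midfoot (MFS) if -1.6 <= FSA < 8 deg, forefoot (FFS)
  if FSA < -1.6 deg;
* duty-factor terciles — the floor(n/3) highest DF values form DF_high,
  the next floor(n/3) DF_mid, and the remainder (the low end, one extra
  runner when n is not divisible by 3) DF_low.

An absolute-FSA variant applies the same tercile rule to FSA values
(highest third labelled RFS_abs, etc.).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FSP_LABELS",
    "DF_GROUP_LABELS",
    "FSA_TERCILE_LABELS",
    "classify_fsp",
    "classify_terciles",
    "SwitchSummary",
    "group_switch_rate",
]

FSP_LABELS: tuple[str, ...] = ("RFS", "MFS", "FFS")
DF_GROUP_LABELS: tuple[str, ...] = ("DF_high", "DF_mid", "DF_low")
FSA_TERCILE_LABELS: tuple[str, ...] = ("RFS_abs", "MFS_abs", "FFS_abs")

RFS_MIN_DEG = 8.0
MFS_MIN_DEG = -1.6


def classify_fsp(fsa: float, rfs_min: float = RFS_MIN_DEG, mfs_min: float = MFS_MIN_DEG) -> str:
    """Foot-strike pattern label from the foot-strike angle (degrees)."""
    if not np.isfinite(fsa):
        raise ValueError(f"FSA must be finite, got {fsa}")
    if rfs_min <= mfs_min:
        raise ValueError("rfs_min must exceed mfs_min")
    if fsa >= rfs_min:
        return "RFS"
    if fsa >= mfs_min:
        return "MFS"
    return "FFS"


def classify_terciles(values: pd.Series, group_names: tuple[str, str, str] = DF_GROUP_LABELS) -> pd.Series:
    """Tercile labels for one speed; index = runner id, values = the measure.

    Values are sorted in descending order; the first floor(n/3) get
    ``group_names[0]``, the next floor(n/3) ``group_names[1]``, the
    remainder ``group_names[2]``.  Ties straddling a boundary are broken
    by the stable order of runner ids and logged with a warning.
    Invariant to any strictly increasing transform of the values.
    """
    s = pd.Series(values).sort_index(kind="mergesort")
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 runners to form terciles")
    if s.isna().any():
        missing = list(s.index[s.isna()])
        raise ValueError(f"missing values for runners {missing}")
    k = n // 3
    v = s.to_numpy(dtype=float)
    order = np.lexsort((np.arange(n), -v))  # descending value, ties by id order
    labels = np.empty(n, dtype=object)
    labels[order[:k]] = group_names[0]
    labels[order[k : 2 * k]] = group_names[1]
    labels[order[2 * k :]] = group_names[2]
    sorted_v = v[order]
    for boundary in (k, 2 * k):
        if sorted_v[boundary - 1] == sorted_v[boundary]:
            warnings.warn(
                f"tie at tercile boundary (value {sorted_v[boundary]}); "
                "resolved by runner-id order",
                stacklevel=2,
            )
    return pd.Series(labels, index=s.index, name=s.name)


@dataclass(frozen=True)
class SwitchSummary:
    """How many runners change group label across speeds (one scheme)."""

    n_runners: int
    n_switched: int
    fraction: float
    per_group: dict  # label at the slowest speed -> count of switchers
    n_excluded: int  # runners missing a label at some speed


def group_switch_rate(labels: pd.DataFrame) -> SwitchSummary:
    """Fraction of runners whose label is not constant across speeds.

    ``labels``: index = runner id, one column per speed, values = group
    labels of a single scheme.  Runners with a missing label at any speed
    are excluded and counted in ``n_excluded``.
    """
    if labels.shape[1] < 2:
        raise ValueError("need labels at two or more speeds")
    complete = labels.dropna()
    n_excluded = len(labels) - len(complete)
    if len(complete) == 0:
        raise ValueError("no runner has labels at every speed")
    switched = complete.nunique(axis=1) > 1
    first_speed = sorted(labels.columns)[0]
    per_group = (
        complete.loc[switched, first_speed].value_counts().to_dict() if switched.any() else {}
    )
    return SwitchSummary(
        n_runners=len(complete),
        n_switched=int(switched.sum()),
        fraction=float(switched.mean()),
        per_group=per_group,
        n_excluded=n_excluded,
    )
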