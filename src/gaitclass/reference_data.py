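"""Published summary data from the reference treadmill cohort.

A cohort of 100 recreational runners ran at 9, 11 and 13 km/h; runners
were classified by foot-strike pattern (FSP: rearfoot/midfoot/forefoot,
from the foot-strike angle) and, independently, into duty-factor (DF)
terciles.  The tables below are the published group counts, FSA summary
statistics, DF tercile ranges and the cross-classification counts.  They
serve two purposes:

* calibration defaults for the synthetic cohort generator, and
* inputs for reproducing the published concordance analysis directly
  from counts (``gaitclass concord`` / ``reproduce-table2``).
"""
from __future__ import annotations

import numpy as np

SPEEDS_KMH: tuple[float, ...] = (9.0, 11.0, 13.0)

FSP_ORDER: tuple[str, ...] = ("RFS", "MFS", "FFS")
DF_GROUP_ORDER: tuple[str, ...] = ("DF_high", "DF_mid", "DF_low")

#: FSP counts per speed (RFS, MFS, FFS); columns of the FSP-by-speed table.
FSP_COUNTS: dict[float, tuple[int, int, int]] = {
    9.0: (27, 34, 39),
    11.0: (31, 33, 36),
    13.0: (38, 23, 39),
}

#: FSA mean and SD (degrees) per FSP group and speed.
FSA_GROUP_STATS: dict[float, dict[str, tuple[float, float]]] = {
    9.0: {"RFS": (13.3, 2.9), "MFS": (4.3, 4.2), "FFS": (-6.7, 4.7)},
    11.0: {"RFS": (13.2, 2.8), "MFS": (3.4, 2.7), "FFS": (-7.7, 3.3)},
    13.0: {"RFS": (11.7, 4.1), "MFS": (1.4, 4.1), "FFS": (-5.9, 5.6)},
}

#: DF tercile ranges (fractions) per speed: {speed: {"low": (min,max), ...}}.
DF_TERCILE_RANGES: dict[float, dict[str, tuple[float, float]]] = {
    9.0: {"low": (0.316, 0.363), "mid": (0.364, 0.384), "high": (0.386, 0.453)},
    11.0: {"low": (0.285, 0.334), "mid": (0.334, 0.357), "high": (0.358, 0.402)},
    13.0: {"low": (0.270, 0.314), "mid": (0.315, 0.335), "high": (0.335, 0.376)},
}

#: 3x3 cross-classification counts per speed.
#: Rows: FSP (RFS, MFS, FFS); columns: DF group (DF_high, DF_mid, DF_low).
CONTINGENCY_COUNTS: dict[float, np.ndarray] = {
    9.0: np.array([[15, 8, 4], [11, 12, 11], [7, 13, 19]]),
    11.0: np.array([[18, 8, 5], [9, 14, 10], [6, 11, 19]]),
    13.0: np.array([[21, 9, 8], [5, 11, 7], [7, 13, 19]]),
}

#: Published concordance percentages per speed, keyed by pair row label
#: (RFS↔DF_high, MFS↔DF_mid, FFS↔DF_low), as printed.  The MFS agreement
#: values are NOT derivable from CONTINGENCY_COUNTS (which give 57/62/66%);
#: see gaitclass.concordance_stats.compare_with_published.
PUBLISHED_CONCORDANCE: dict[float, dict[str, dict[str, int]]] = {
    9.0: {
        "agreement": {"RFS": 70, "MFS": 76, "FFS": 65},
        "sensitivity": {"RFS": 56, "MFS": 35, "FFS": 49},
        "specificity": {"RFS": 75, "MFS": 68, "FFS": 75},
    },
    11.0: {
        "agreement": {"RFS": 72, "MFS": 81, "FFS": 68},
        "sensitivity": {"RFS": 58, "MFS": 42, "FFS": 53},
        "specificity": {"RFS": 78, "MFS": 72, "FFS": 77},
    },
    13.0: {
        "agreement": {"RFS": 71, "MFS": 85, "FFS": 65},
        "sensitivity": {"RFS": 55, "MFS": 48, "FFS": 49},
        "specificity": {"RFS": 81, "MFS": 71, "FFS": 75},
    },
}

#: FSA mixture calibration for the generator: per speed, a tuple of
#: (weight, mean deg, sd deg) components, one per FSP group, with weights
#: taken from the observed group proportions.
FSA_MIXTURES: dict[float, tuple[tuple[float, float, float], ...]] = {
    speed: tuple(
        (count / 100.0, *FSA_GROUP_STATS[speed][grp])
        for grp, count in zip(FSP_ORDER, FSP_COUNTS[speed])
    )
    for speed in SPEEDS_KMH
}

#: DF marginal calibration: normal mean/sd (fraction) per speed, back-solved
#: from the tercile boundary values (tercile edges of a normal sit at
#: mu +/- 0.4307 sigma).
DF_NORMAL_PARAMS: dict[float, tuple[float, float]] = {
    9.0: (0.374, 0.025),
    11.0: (0.346, 0.027),
    13.0: (0.325, 0.024),
}

#: Published FSA-DF Pearson correlations (r, ci_low, ci_high) per speed.
FSA_DF_CORRELATIONS: dict[float, tuple[float, float, float]] = {
    9.0: (0.39, 0.21, 0.55),
    11.0: (0.42, 0.24, 0.57),
    13.0: (0.48, 0.31, 0.62),
}
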