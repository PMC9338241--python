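"""Concordance and association statistics between the two classifications.

The 3x3 cross-classification of foot-strike pattern (rows: RFS, MFS,
FFS) against duty-factor tercile (columns: DF_high, DF_mid, DF_low) is
collapsed into three 2x2 tables, one per presumed-corresponding pair
(RFS-DF_high, MFS-DF_mid, FFS-DF_low).  On each 2x2 table with cells
tp, fn, fp, tn (N = total):

    agreement   = (tp + tn) / N
    sensitivity = tp / (tp + fn)      (share of the FSP group found in
                                       the corresponding DF group)
    specificity = tn / (tn + fp)

Binomial 95% confidence intervals use the normal approximation (Wald)
by default, with Clopper-Pearson available.  The module also provides
the chi-squared homogeneity test of the FSP distribution across speeds,
Pearson correlations with Fisher-z intervals and interpretation bands,
and Cohen's d with interpretation bands.

Report-table percentages are rounded half-away-from-zero to integers;
full precision is retained on every result object.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .classification import DF_GROUP_LABELS, FSP_LABELS

__all__ = [
    "ContingencyTable",
    "TwoByTwo",
    "PairConcordance",
    "CorrelationResult",
    "EffectSize",
    "PAIRS",
    "build_contingency",
    "collapse_pair",
    "pair_concordance",
    "binomial_ci",
    "chi_squared_homogeneity",
    "pearson_with_ci",
    "cohens_d",
    "footwear_correlations",
    "concordance_table",
    "compare_with_published",
    "round_half_away",
]

#: presumed-corresponding (FSP, DF group) pairs
PAIRS: tuple[tuple[str, str], ...] = (
    ("RFS", "DF_high"),
    ("MFS", "DF_mid"),
    ("FFS", "DF_low"),
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report style)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 FSP-by-DF-group counts for one speed."""

    counts: np.ndarray
    speed: float
    row_labels: tuple[str, ...] = FSP_LABELS
    col_labels: tuple[str, ...] = DF_GROUP_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(f"counts shape {c.shape} does not match labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.row_labels),
                          columns=list(self.col_labels))
        df["row_total"] = df.sum(axis=1)
        df.loc["col_total"] = df.sum(axis=0)
        return df


def build_contingency(labels: pd.DataFrame, speed: float,
                      row_col: str = "fsp", col_col: str = "df_group") -> ContingencyTable:
    """Cross-tabulate per-runner labels (one speed) into a 3x3 table."""
    for col in (row_col, col_col):
        if labels[col].isna().any():
            missing = list(labels.index[labels[col].isna()])
            raise ValueError(f"runners {missing} lack a {col} label")
    counts = np.zeros((len(FSP_LABELS), len(DF_GROUP_LABELS)), dtype=int)
    row_idx = {lab: i for i, lab in enumerate(FSP_LABELS)}
    col_idx = {lab: j for j, lab in enumerate(DF_GROUP_LABELS)}
    for _, row in labels.iterrows():
        counts[row_idx[row[row_col]], col_idx[row[col_col]]] += 1
    return ContingencyTable(counts=counts, speed=speed)


@dataclass(frozen=True)
class TwoByTwo:
    """Collapsed 2x2 counts for one (FSP, DF group) pair."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def collapse_pair(table: ContingencyTable, pair: tuple[str, str]) -> TwoByTwo:
    """Collapse a 3x3 table to the 2x2 of one corresponding pair.

    tp = the pair's cell; fn = rest of the FSP row; fp = rest of the DF
    column; tn = everything else.
    """
    fsp, df_group = pair
    if fsp not in table.row_labels or df_group not in table.col_labels:
        raise ValueError(f"unknown pair {pair}")
    i = table.row_labels.index(fsp)
    j = table.col_labels.index(df_group)
    tp = int(table.counts[i, j])
    fn = int(table.counts[i].sum()) - tp
    fp = int(table.counts[:, j].sum()) - tp
    tn = table.n - tp - fn - fp
    return TwoByTwo(tp=tp, fn=fn, fp=fp, tn=tn)


def binomial_ci(x: int, n: int, method: str = "wald", level: float = 0.95) -> tuple[float, float]:
    """Binomial confidence interval for x successes in n trials (fractions).

    ``method``: "wald" (normal approximation, truncated to [0, 1]) or
    "clopper-pearson" (exact, via the beta-quantile relation).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n <= 0 or not 0 <= x <= n:
        raise ValueError(f"invalid binomial counts x={x}, n={n}")
    sm_method = {"wald": "normal", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    low, high = proportion_confint(x, n, alpha=1 - level, method=sm_method)
    return (float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0)))


@dataclass(frozen=True)
class PairConcordance:
    """Agreement/sensitivity/specificity for one collapsed pair.

    Point estimates and CI bounds are fractions in [0, 1]; NaN marks a
    statistic with a zero denominator (listed in ``undefined``).
    """

    pair: tuple[str, str]
    counts: TwoByTwo
    agreement: float
    sensitivity: float
    specificity: float
    ci: dict  # statistic -> (low, high) fractions
    ci_method: str
    undefined: tuple[str, ...] = ()

    def to_percent_row(self) -> dict:
        """Report-style row: integer percents, half rounded away from zero."""
        row = {"pair": f"{self.pair[0]}-{self.pair[1]}",
               "tp": self.counts.tp, "fn": self.counts.fn,
               "fp": self.counts.fp, "tn": self.counts.tn}
        for name in ("agreement", "sensitivity", "specificity"):
            value = getattr(self, name)
            if np.isnan(value):
                row[f"{name}_pct"] = np.nan
                row[f"{name}_ci_low_pct"] = np.nan
                row[f"{name}_ci_high_pct"] = np.nan
            else:
                low, high = self.ci[name]
                row[f"{name}_pct"] = round_half_away(100 * value)
                row[f"{name}_ci_low_pct"] = round_half_away(100 * low)
                row[f"{name}_ci_high_pct"] = round_half_away(100 * high)
        row["ci_method"] = self.ci_method
        return row


def pair_concordance(counts: TwoByTwo, ci_method: str = "wald",
                     level: float = 0.95,
                     pair: tuple[str, str] = ("", "")) -> PairConcordance:
    """Agreement, sensitivity and specificity with binomial CIs for a 2x2 table."""
    n = counts.n
    if n <= 0:
        raise ValueError("empty 2x2 table")
    stats_def = {
        "agreement": (counts.tp + counts.tn, n),
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
    }
    values: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    undefined: list[str] = []
    for name, (x, denom) in stats_def.items():
        if denom == 0:
            values[name] = float("nan")
            ci[name] = (float("nan"), float("nan"))
            undefined.append(name)
        else:
            values[name] = x / denom
            ci[name] = binomial_ci(x, denom, method=ci_method, level=level)
    return PairConcordance(
        pair=pair, counts=counts, agreement=values["agreement"],
        sensitivity=values["sensitivity"], specificity=values["specificity"],
        ci=ci, ci_method=ci_method, undefined=tuple(undefined),
    )


def chi_squared_homogeneity(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity on an r x c count table.

    Returns (statistic, degrees of freedom, p).  Expected counts come
    from the product of the marginals; a zero row or column marginal is
    rejected.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or (c < 0).any():
        raise ValueError("counts must be a non-negative 2-D table")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(c, correction=False)
    return float(stat), int(dof), float(p)


#: |r| interpretation band edges -> labels
_R_BANDS = ((0.30, "negligible"), (0.50, "low"), (0.70, "moderate"),
            (0.90, "high"), (1.01, "very high"))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    interpretation: str


def interpret_r(r: float) -> str:
    for edge, label in _R_BANDS:
        if abs(r) < edge:
            return label
    return "very high"


def pearson_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z confidence interval and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=level)
    return CorrelationResult(
        r=float(res.statistic), ci_low=float(ci.low), ci_high=float(ci.high),
        p=float(res.pvalue), n=int(x.size), interpretation=interpret_r(res.statistic),
    )


#: midpoints between the anchors 0.01, 0.2, 0.5, 0.8 -> labels
_D_BANDS = ((0.105, "very small"), (0.35, "small"), (0.65, "moderate"))


@dataclass(frozen=True)
class EffectSize:
    d: float
    interpretation: str


def interpret_d(d: float) -> str:
    for edge, label in _D_BANDS:
        if abs(d) < edge:
            return label
    return "large"


def cohens_d(group_a, group_b) -> EffectSize:
    """Cohen's d: mean difference over the pooled (n-1 weighted) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    d = (a.mean() - b.mean()) / pooled
    return EffectSize(d=float(d), interpretation=interpret_d(d))


def footwear_correlations(runner_metrics: pd.DataFrame,
                          shoe_vars: tuple[str, ...] = ("shoe_mass_g", "shoe_drop_mm"),
                          gait_vars: tuple[str, ...] = ("df", "fsa_deg"),
                          level: float = 0.95) -> pd.DataFrame:
    """Pearson r per (shoe variable, gait variable, speed), tidy output.

    Constant shoe variables are flagged (r and CI reported as NaN) rather
    than raised, so one degenerate column does not abort the table.
    """
    rows = []
    for speed, grp in runner_metrics.groupby("speed_kmh"):
        for sv in shoe_vars:
            for gv in gait_vars:
                try:
                    res = pearson_with_ci(grp[sv], grp[gv], level=level)
                    rows.append({"speed_kmh": speed, "x": sv, "y": gv,
                                 "r": res.r, "ci_low": res.ci_low,
                                 "ci_high": res.ci_high, "p": res.p,
                                 "interpretation": res.interpretation,
                                 "flag": ""})
                except ValueError as err:
                    rows.append({"speed_kmh": speed, "x": sv, "y": gv,
                                 "r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "p": np.nan, "interpretation": "undefined",
                                 "flag": str(err)})
    return pd.DataFrame(rows)


def concordance_table(tables: dict[float, ContingencyTable],
                      ci_method: str = "wald", level: float = 0.95) -> pd.DataFrame:
    """Tidy concordance table over speeds and pairs (report percentages).

    Also carries the unrounded fractions for downstream averaging.
    """
    rows = []
    for speed in sorted(tables):
        table = tables[speed]
        for pair in PAIRS:
            pc = pair_concordance(collapse_pair(table, pair), ci_method=ci_method,
                                  level=level, pair=pair)
            row = {"speed_kmh": speed, **pc.to_percent_row(),
                   "agreement": pc.agreement, "sensitivity": pc.sensitivity,
                   "specificity": pc.specificity}
            rows.append(row)
    return pd.DataFrame(rows)


def compare_with_published(computed: pd.DataFrame,
                           published: dict[float, dict[str, dict[str, int]]]) -> pd.DataFrame:
    """Flag differences between count-derived and published percentages.

    ``computed`` is the output of :func:`concordance_table`; ``published``
    maps speed -> statistic -> FSP label -> printed integer percent.  Any
    mismatch is reported with ``match=False`` — kept visible because the
    published midfoot agreement values are not derivable from the
    published counts (a constant +19-point offset), while every
    sensitivity and specificity is.
    """
    rows = []
    for _, row in computed.iterrows():
        fsp = row["pair"].split("-")[0]
        for statistic in ("agreement", "sensitivity", "specificity"):
            pub = published[row["speed_kmh"]][statistic][fsp]
            got = row[f"{statistic}_pct"]
            rows.append({"speed_kmh": row["speed_kmh"], "pair": row["pair"],
                         "statistic": statistic, "count_derived_pct": got,
                         "published_pct": pub, "match": bool(got == pub)})
    return pd.DataFrame(rows)
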