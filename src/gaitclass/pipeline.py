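"""End-to-end pipeline: simulate/load -> condition -> detect -> measure ->
classify -> concord.

A single :class:`RunConfig` drives a reproducible run that writes tidy
CSV tables (stride metrics, foot-strike angles, runner metrics, labels,
per-speed contingency tables, concordance, correlations, effect sizes),
a ``summary.json`` and a run manifest.  ``run_from_counts`` bypasses the
signal stages and computes the concordance outputs directly from 3x3
count tables, which is how the published cross-classification is
reproduced.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import reference_data as ref
from .classification import (
    DF_GROUP_LABELS,
    FSA_TERCILE_LABELS,
    FSP_LABELS,
    classify_fsp,
    classify_terciles,
    group_switch_rate,
)
from .concordance_stats import (
    ContingencyTable,
    build_contingency,
    chi_squared_homogeneity,
    cohens_d,
    concordance_table,
    footwear_correlations,
    pearson_with_ci,
    round_half_away,
)
from .foot_strike import average_fsa, fsa_at_footstrike, rescale_to_static
from .gait_events import average_strides, detect_events, stride_metrics
from .signal_processing import FilterSpec, downsample, fill_gaps, lowpass
from .synthetic_cohort import (
    ANGLE_RATE_HZ,
    CohortConfig,
    draw_cohort,
    draw_shoes,
    read_cohort,
    simulate_trial,
)
from .traces import AngleTrace, ForceTrace

__all__ = ["RunConfig", "run_pipeline", "run_from_counts", "analyze_trial"]


@dataclass(frozen=True)
class RunConfig:
    """Settings of one full pipeline run; defaults match the reference study."""

    cohort: CohortConfig | str = field(default_factory=CohortConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    threshold_n: float = 20.0
    n_strides: int = 10
    rfs_min_deg: float = 8.0
    mfs_min_deg: float = -1.6
    ci_method: str = "wald"
    #: detect events on the 20 Hz-filtered force instead of the raw force.
    #: Off by default: zero-phase low-pass filtering spreads the contact
    #: pulse, which moves the 20 N crossings outward by several
    #: milliseconds and biases the duty factor upward by ~0.01.
    detect_on_filtered: bool = False
    detect_at_kinematic_rate: bool = False
    seed: int | None = None  # overrides cohort.seed when simulating

    def __post_init__(self) -> None:
        if self.rfs_min_deg <= self.mfs_min_deg:
            raise ValueError("FSP thresholds must be ordered: rfs_min > mfs_min")
        if self.threshold_n < 0:
            raise ValueError("detection threshold must be >= 0")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.get("cohort", {})
        if isinstance(cohort, dict):
            if "speeds" in cohort:
                cohort["speeds"] = tuple(float(s) for s in cohort["speeds"])
            mix = cohort.get("fsa_mixture")
            if isinstance(mix, dict):
                cohort["fsa_mixture"] = {
                    float(k): tuple(tuple(c) for c in v) for k, v in mix.items()
                }
            elif isinstance(mix, list):
                cohort["fsa_mixture"] = tuple(tuple(c) for c in mix)
            if isinstance(cohort.get("df_mean_by_speed"), dict):
                cohort["df_mean_by_speed"] = {
                    float(k): float(v) for k, v in cohort["df_mean_by_speed"].items()
                }
            cohort = CohortConfig(**cohort)
        filt = raw.get("filter", {})
        if isinstance(filt, dict):
            filt = FilterSpec(**filt)
        kwargs = {k: v for k, v in raw.items() if k not in ("cohort", "filter")}
        return cls(cohort=cohort, filter=filt, **kwargs)


def analyze_trial(
    force: ForceTrace,
    angle: AngleTrace,
    static: AngleTrace,
    config: RunConfig,
) -> dict:
    """Run the signal chain on one trial and return its averaged measures."""
    detection_force = lowpass(force, config.filter) if config.detect_on_filtered else force
    if config.detect_at_kinematic_rate:
        detection_force = downsample(
            lowpass(detection_force, config.filter) if not config.detect_on_filtered
            else detection_force,
            ANGLE_RATE_HZ,
        )
    events = detect_events(detection_force, threshold=config.threshold_n)
    per_stride = stride_metrics(events)
    summary = average_strides(per_stride, config.n_strides)

    filled, gap_report = fill_gaps(angle)
    conditioned = lowpass(filled, config.filter)
    rescaled = rescale_to_static(conditioned, static)
    angles = fsa_at_footstrike(rescaled, events)
    fsa = average_fsa(angles, config.n_strides)
    return {
        "summary": summary,
        "per_stride": per_stride,
        "fsa_deg": fsa,
        "per_stride_fsa": angles,
        "n_unfilled_gaps": len(gap_report),
        "events": events,
    }


def _effect_sizes(runner_metrics: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Cohen's d of DF between FSP groups and of FSA between DF groups."""
    merged = runner_metrics.merge(labels, on=["runner_id", "speed_kmh"])
    rows = []
    comparisons = [
        ("df", "fsp", ("RFS", "MFS")), ("df", "fsp", ("RFS", "FFS")),
        ("df", "fsp", ("MFS", "FFS")),
        ("fsa_deg", "df_group", ("DF_high", "DF_mid")),
        ("fsa_deg", "df_group", ("DF_high", "DF_low")),
        ("fsa_deg", "df_group", ("DF_mid", "DF_low")),
    ]
    for speed, grp in merged.groupby("speed_kmh"):
        for measure, scheme, (a, b) in comparisons:
            va = grp.loc[grp[scheme] == a, measure]
            vb = grp.loc[grp[scheme] == b, measure]
            row = {"speed_kmh": speed, "measure": measure,
                   "group_a": a, "group_b": b}
            try:
                es = cohens_d(va, vb)
                row.update({"d": es.d, "interpretation": es.interpretation, "flag": ""})
            except ValueError as err:
                row.update({"d": np.nan, "interpretation": "undefined", "flag": str(err)})
            rows.append(row)
    return pd.DataFrame(rows)


def _correlations(runner_metrics: pd.DataFrame) -> pd.DataFrame:
    """FSA against DF, contact time and stride frequency, per speed."""
    rows = []
    for speed, grp in runner_metrics.groupby("speed_kmh"):
        for var in ("df", "tc_s", "sf_hz"):
            res = pearson_with_ci(grp["fsa_deg"], grp[var])
            rows.append({"speed_kmh": speed, "x": "fsa_deg", "y": var,
                         "r": res.r, "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "p": res.p, "interpretation": res.interpretation, "flag": ""})
    return pd.DataFrame(rows)


def _classify_cohort(runner_metrics: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rows = []
    for speed, grp in runner_metrics.groupby("speed_kmh"):
        grp = grp.set_index("runner_id")
        fsp = grp["fsa_deg"].map(
            lambda v: classify_fsp(v, config.rfs_min_deg, config.mfs_min_deg)
        )
        df_group = classify_terciles(grp["df"], DF_GROUP_LABELS)
        fsa_terc = classify_terciles(grp["fsa_deg"], FSA_TERCILE_LABELS)
        for rid in grp.index:
            rows.append({"runner_id": rid, "speed_kmh": speed, "fsp": fsp[rid],
                         "df_group": df_group[rid], "fsa_tercile_group": fsa_terc[rid]})
    return pd.DataFrame(rows)


def _concordance_outputs(labels: pd.DataFrame, ci_method: str):
    tables = {
        speed: build_contingency(grp, speed)
        for speed, grp in labels.groupby("speed_kmh")
    }
    return tables, concordance_table(tables, ci_method=ci_method)


def _summary(labels: pd.DataFrame, concordance: pd.DataFrame, seed) -> dict:
    summary: dict = {"seed": seed}
    for name in ("agreement", "sensitivity", "specificity"):
        mean_pct = 100 * concordance[name].mean()
        summary[f"avg_{name}_pct"] = round_half_away(mean_pct)
        summary[f"avg_{name}_pct_unrounded"] = float(mean_pct)
    speeds = sorted(labels["speed_kmh"].unique())
    if len(speeds) >= 2:
        fsp_by_speed = np.array([
            [
                int(((labels["speed_kmh"] == s) & (labels["fsp"] == lab)).sum())
                for s in speeds
            ]
            for lab in FSP_LABELS
        ])
        stat, dof, p = chi_squared_homogeneity(fsp_by_speed)
        summary["fsp_chi_squared"] = {"statistic": float(stat), "df": dof, "p": float(p)}
        switch = {}
        for scheme in ("fsp", "df_group", "fsa_tercile_group"):
            wide = labels.pivot(index="runner_id", columns="speed_kmh", values=scheme)
            s = group_switch_rate(wide)
            switch[scheme] = {"n_switched": s.n_switched, "fraction": s.fraction}
        summary["group_switch"] = switch
    return summary


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write every output table under ``out_dir``.

    Returns the run manifest.  On error, partially written outputs are
    removed before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        p = out / name
        frame.to_csv(p, index=False)
        written.append(p)

    try:
        # --- stage 1: obtain traces -------------------------------------
        if isinstance(config.cohort, (str, Path)):
            metadata, trials = read_cohort(config.cohort)
            seed = None
        else:
            cohort_cfg = config.cohort
            if config.seed is not None:
                cohort_cfg = CohortConfig(**{**cohort_cfg.to_dict(), "seed": config.seed,
                                             "speeds": cohort_cfg.speeds,
                                             "fsa_mixture": cohort_cfg.fsa_mixture,
                                             "df_mean_by_speed": cohort_cfg.df_mean_by_speed})
            seed = cohort_cfg.seed
            runners = draw_cohort(cohort_cfg)
            shoes = draw_shoes(cohort_cfg)
            metadata_rows, trials = [], {}
            for r in runners:
                trials[(r.runner_id, r.speed)] = simulate_trial(r, cohort_cfg)
                shoe = shoes.loc[shoes["runner_id"] == r.runner_id].iloc[0]
                metadata_rows.append({
                    "runner_id": r.runner_id, "speed_kmh": r.speed,
                    "body_mass_kg": r.body_mass, "shoe_mass_g": shoe["shoe_mass_g"],
                    "shoe_drop_mm": shoe["shoe_drop_mm"], "true_df": r.true_df,
                    "true_fsa": r.true_fsa, "true_sf": r.true_sf,
                })
            metadata = pd.DataFrame(metadata_rows)
        write_csv("metadata.csv", metadata)

        # --- stage 2: condition, detect, measure -------------------------
        stride_rows, fsa_rows, metric_rows = [], [], []
        for _, meta in metadata.iterrows():
            rid, speed = int(meta["runner_id"]), float(meta["speed_kmh"])
            trial = trials[(rid, speed)]
            force = trial.force if hasattr(trial, "force") else trial["force"]
            angle = trial.angle if hasattr(trial, "angle") else trial["angle"]
            static = trial.static if hasattr(trial, "static") else trial["static"]
            try:
                result = analyze_trial(force, angle, static, config)
            except ValueError as err:
                raise ValueError(f"runner {rid} at {speed} km/h: {err}") from err
            for i, m in enumerate(result["per_stride"][: config.n_strides]):
                stride_rows.append({"runner_id": rid, "speed_kmh": speed,
                                    "stride_index": i, "tc_s": m.tc, "ts_s": m.ts,
                                    "stride_time_s": m.stride_time,
                                    "sf_hz": m.sf, "df": m.df})
            for a in result["per_stride_fsa"][: config.n_strides]:
                fsa_rows.append({"runner_id": rid, "speed_kmh": speed,
                                 "stride_index": a.stride_index, "fsa_deg": a.fsa})
            s = result["summary"]
            metric_rows.append({
                "runner_id": rid, "speed_kmh": speed, "df": s.df, "fsa_deg":
                result["fsa_deg"], "tc_s": s.tc, "ts_s": s.ts,
                "stride_time_s": s.stride_time, "sf_hz": s.sf,
                "df_ratio_of_means": s.df_ratio_of_means,
                "shoe_mass_g": meta["shoe_mass_g"], "shoe_drop_mm": meta["shoe_drop_mm"],
            })
        write_csv("stride_metrics.csv", pd.DataFrame(stride_rows))
        write_csv("fsa.csv", pd.DataFrame(fsa_rows))
        runner_metrics = pd.DataFrame(metric_rows)
        write_csv("runner_metrics.csv", runner_metrics)

        # --- stage 3: classify and concord -------------------------------
        labels = _classify_cohort(runner_metrics, config)
        write_csv("labels.csv", labels)
        tables, concordance = _concordance_outputs(labels, config.ci_method)
        for speed, table in sorted(tables.items()):
            write_csv(f"contingency_{speed:g}.csv", table.to_frame().reset_index(names="fsp"))
        write_csv("concordance.csv", concordance)
        correlations = pd.concat(
            [_correlations(runner_metrics), footwear_correlations(runner_metrics)],
            ignore_index=True,
        )
        write_csv("correlations.csv", correlations)
        write_csv("effect_sizes.csv", _effect_sizes(runner_metrics, labels))

        summary = _summary(labels, concordance, seed)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(out / "summary.json")

        config_repr = {
            "threshold_n": config.threshold_n, "n_strides": config.n_strides,
            "rfs_min_deg": config.rfs_min_deg, "mfs_min_deg": config.mfs_min_deg,
            "ci_method": config.ci_method,
            "detect_at_kinematic_rate": config.detect_at_kinematic_rate,
            "filter": {"cutoff": config.filter.cutoff, "order": config.filter.order,
                       "zero_lag": config.filter.zero_lag},
            "cohort": (str(config.cohort) if isinstance(config.cohort, (str, Path))
                       else config.cohort.to_dict()),
        }
        manifest = {
            "version": __version__,
            "seed": seed,
            "config": config_repr,
            "config_sha256": hashlib.sha256(
                json.dumps(config_repr, sort_keys=True).encode()
            ).hexdigest(),
            "row_counts": {
                "runner_metrics": len(runner_metrics),
                "labels": len(labels),
                "concordance": len(concordance),
            },
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(out / "run_manifest.json")
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_from_counts(
    counts: dict[float, np.ndarray | ContingencyTable],
    ci_method: str = "wald",
) -> dict:
    """Concordance outputs straight from 3x3 count tables (one per speed).

    Equivalent to the concordance stage of :func:`run_pipeline` applied
    to labels that cross-tabulate to the same counts.
    """
    tables = {
        float(speed): (c if isinstance(c, ContingencyTable)
                       else ContingencyTable(counts=np.asarray(c), speed=float(speed)))
        for speed, c in counts.items()
    }
    concordance = concordance_table(tables, ci_method=ci_method)
    summary: dict = {}
    for name in ("agreement", "sensitivity", "specificity"):
        mean_pct = 100 * concordance[name].mean()
        summary[f"avg_{name}_pct"] = round_half_away(mean_pct)
        summary[f"avg_{name}_pct_unrounded"] = float(mean_pct)
    if len(tables) >= 2:
        speeds = sorted(tables)
        fsp_by_speed = np.column_stack([tables[s].counts.sum(axis=1) for s in speeds])
        stat, dof, p = chi_squared_homogeneity(fsp_by_speed)
        summary["fsp_chi_squared"] = {"statistic": float(stat), "df": dof, "p": float(p)}
    return {"tables": tables, "concordance": concordance, "summary": summary}
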