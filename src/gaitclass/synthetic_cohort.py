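"""Synthetic runner cohort generator.

Draws a cohort with a controlled joint distribution of duty factor (DF)
and foot-strike angle (FSA) and renders every runner-speed trial as raw
vertical force (1000 Hz) and sagittal foot-angle (200 Hz) traces plus a
standing static trial, so the whole analysis chain can be exercised
end-to-end.

Latent model
------------
Per speed, FSA follows a three-component Gaussian mixture (one component
per foot-strike group, calibrated by default to the reference cohort's
group proportions, means and SDs) and DF a normal marginal whose mean/SD
reproduce the reference tercile boundaries.  The two are linked by a
Gaussian copula: the FSA quantile is mapped to a normal score and mixed
with independent noise to produce the DF score at the requested Pearson
correlation.  Stride frequency is drawn independently of FSA, matching
the negligible FSA-SF correlation observed in treadmill cohorts.

A runner keeps one latent normal score across speeds, perturbed by a
small per-speed jitter, so a minority of runners change group between
speeds — as real cohorts do — without altering any single-speed
distribution.

Force waveform
--------------
Each ground contact of duration tc = DF/SF is a half-sine with peak

    F_peak = (pi / 2) * body_mass * g / DF

so the stride-averaged force equals body weight (impulse conservation);
the swing phase is exactly zero before noise.  No impact transient is
modelled: event detection uses only threshold crossings and timing, not
loading rate.

The running angle trace equals ``static_offset + true_fsa`` exactly at
every foot-strike instant and swings sinusoidally in between; the static
trace is the constant mounting offset.  Subtracting the static mean
downstream therefore recovers the latent FSA.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import reference_data as ref
from .gait_events import GaitEvents
from .traces import AngleTrace, ForceTrace

__all__ = [
    "G_M_PER_S2",
    "DEFAULT_SEED",
    "CohortConfig",
    "LatentRunner",
    "GaussianMixture1D",
    "draw_cohort",
    "draw_shoes",
    "true_events",
    "synthesize_force",
    "synthesize_angle",
    "simulate_trial",
    "write_cohort",
    "read_cohort",
]

G_M_PER_S2 = 9.81
DEFAULT_SEED = 20220729

MixtureSpec = tuple[tuple[float, float, float], ...]  # (weight, mean deg, sd deg)


@dataclass(frozen=True)
class GaussianMixture1D:
    """Univariate Gaussian mixture with CDF and an interpolated quantile."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def from_spec(cls, spec: MixtureSpec) -> "GaussianMixture1D":
        w, m, s = (np.array(col, dtype=float) for col in zip(*spec))
        if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must be positive and sum to 1")
        if (s < 0).any():
            raise ValueError("mixture SDs must be non-negative")
        return cls(weights=w, means=m, sds=s)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return (self.weights * stats.norm.cdf(x[:, None], self.means, self.sds)).sum(axis=1)

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Quantile via dense monotone interpolation of the CDF."""
        lo = float((self.means - 8 * self.sds).min())
        hi = float((self.means + 8 * self.sds).max())
        grid = np.linspace(lo, hi, 8193)
        c = self.cdf(grid)
        u = np.clip(np.asarray(u, dtype=float), c[0], c[-1])
        return np.interp(u, c, grid)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the reference treadmill cohort: 100 runners at
    9/11/13 km/h, per-speed FSA mixtures and DF marginals calibrated to
    the published group statistics, and an FSA-DF copula correlation of
    0.45 (the published per-speed values span 0.39-0.48).
    """

    n_runners: int = 100
    speeds: tuple[float, ...] = ref.SPEEDS_KMH
    seed: int = DEFAULT_SEED
    #: single mixture applied to all speeds, or a per-speed mapping
    fsa_mixture: MixtureSpec | dict[float, MixtureSpec] | None = None
    df_mean_by_speed: dict[float, float] | None = None
    df_sd: float | None = None
    fsa_df_corr: float = 0.45
    sf_mean: float = 1.40  # Hz at 11 km/h; scaled by +/-1% per km/h
    sf_sd: float = 0.07
    body_mass_mean: float = 70.0
    body_mass_sd: float = 7.0
    noise_sd_force: float = 5.0  # N
    noise_sd_angle: float = 0.2  # deg
    n_strides: int = 10
    # --- trace-shape and realism knobs (not part of the latent model) ---
    angle_amplitude: float = 20.0  # deg swing of the foot-angle waveform
    static_offset_sd: float = 2.0  # deg, marker-mounting offset
    static_duration_s: float = 5.0
    between_speed_jitter: float = 0.2  # per-speed latent-score jitter
    n_gaps_per_trial: int = 2
    max_gap_frames: int = 8
    shoe_mass_mean: float = 257.0  # g
    shoe_mass_sd: float = 49.0
    shoe_drop_mean: float = 7.0  # mm
    shoe_drop_sd: float = 3.0
    shoe_mass_drop_corr: float = 0.52

    def __post_init__(self) -> None:
        if self.n_runners < 3:
            raise ValueError("n_runners must be >= 3 (terciles must be constructible)")
        if not -1.0 <= self.fsa_df_corr <= 1.0:
            raise ValueError(f"fsa_df_corr must lie in [-1, 1], got {self.fsa_df_corr}")
        for name in ("df_sd", "sf_sd", "body_mass_sd", "noise_sd_force",
                     "noise_sd_angle", "static_offset_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if not self.speeds:
            raise ValueError("at least one speed required")

    # -- calibration lookups -------------------------------------------------
    def mixture_for(self, speed: float) -> GaussianMixture1D:
        mix = self.fsa_mixture
        if mix is None:
            mix = ref.FSA_MIXTURES
        if isinstance(mix, dict):
            if speed not in mix:
                raise ValueError(f"no FSA mixture configured for speed {speed}")
            mix = mix[speed]
        return GaussianMixture1D.from_spec(mix)

    def df_params_for(self, speed: float) -> tuple[float, float]:
        if self.df_mean_by_speed is None:
            mean, sd = ref.DF_NORMAL_PARAMS.get(speed, (None, None))
            if mean is None:
                raise ValueError(f"no DF calibration for speed {speed}")
        else:
            if speed not in self.df_mean_by_speed:
                raise ValueError(f"no DF mean configured for speed {speed}")
            mean = self.df_mean_by_speed[speed]
            sd = self.df_sd if self.df_sd is not None else 0.025
        if not 0 < mean < 0.5:
            raise ValueError(f"DF mean must lie in (0, 0.5), got {mean}")
        return float(mean), float(self.df_sd if self.df_sd is not None else sd)

    def sf_mean_for(self, speed: float) -> float:
        return self.sf_mean * (1.0 + 0.01 * (speed - 11.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["speeds"] = list(self.speeds)
        if isinstance(d["fsa_mixture"], dict):
            d["fsa_mixture"] = {str(k): [list(c) for c in v]
                                for k, v in d["fsa_mixture"].items()}
        return d


@dataclass(frozen=True)
class LatentRunner:
    """Ground truth for one runner at one speed (recovery-test oracle)."""

    runner_id: int
    speed: float
    true_df: float
    true_fsa: float
    true_sf: float
    body_mass: float
    static_offset: float

    def __post_init__(self) -> None:
        if not 0 < self.true_df < 0.5:
            raise ValueError(f"true_df must lie in (0, 0.5), got {self.true_df}")
        if self.true_sf <= 0:
            raise ValueError("true_sf must be positive")


def draw_cohort(config: CohortConfig) -> list[LatentRunner]:
    """Draw the latent cohort; deterministic given ``config.seed``.

    Returns one :class:`LatentRunner` per runner per speed, ordered by
    speed then runner id.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_runners
    rho = config.fsa_df_corr
    j = config.between_speed_jitter
    carry = float(np.sqrt(max(0.0, 1.0 - j * j)))

    z_fsa_base = rng.standard_normal(n)
    z_df_noise_base = rng.standard_normal(n)
    body_mass = np.clip(rng.normal(config.body_mass_mean, config.body_mass_sd, n), 40.0, None)
    static_offset = rng.normal(0.0, config.static_offset_sd, n)

    runners: list[LatentRunner] = []
    for speed in config.speeds:
        mixture = config.mixture_for(speed)
        df_mean, df_sd = config.df_params_for(speed)
        z_fsa = carry * z_fsa_base + j * rng.standard_normal(n)
        z_noise = carry * z_df_noise_base + j * rng.standard_normal(n)
        z_df = rho * z_fsa + np.sqrt(1.0 - rho * rho) * z_noise
        fsa = mixture.quantile(stats.norm.cdf(z_fsa))
        df = np.clip(df_mean + df_sd * z_df, 0.05, 0.495)
        sf = np.clip(rng.normal(config.sf_mean_for(speed), config.sf_sd, n), 0.5, None)
        for i in range(n):
            runners.append(
                LatentRunner(
                    runner_id=i + 1, speed=float(speed), true_df=float(df[i]),
                    true_fsa=float(fsa[i]), true_sf=float(sf[i]),
                    body_mass=float(body_mass[i]), static_offset=float(static_offset[i]),
                )
            )
    return runners


def draw_shoes(config: CohortConfig) -> pd.DataFrame:
    """Per-runner shoe metadata: mass (g) and heel-to-toe drop (mm).

    The two are drawn jointly with the configured correlation and are
    independent of every gait variable (the null the footwear
    correlation table is meant to exhibit).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_runners
    r = config.shoe_mass_drop_corr
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(n)
    mass = np.clip(config.shoe_mass_mean + config.shoe_mass_sd * z1, 100.0, None)
    drop = np.clip(config.shoe_drop_mean + config.shoe_drop_sd * z2, 0.0, None)
    return pd.DataFrame({
        "runner_id": np.arange(1, n + 1),
        "shoe_mass_g": mass,
        "shoe_drop_mm": drop,
    })


# ---------------------------------------------------------------------------
# trace synthesis

FORCE_RATE_HZ = 1000.0
ANGLE_RATE_HZ = 200.0
#: swing fraction of a stride placed before the first contact
_LEAD_FRACTION = 0.35
#: extra contacts beyond n_strides so edge contacts never clip the analysis
_EXTRA_CONTACTS = 2


def _trial_rng(config: CohortConfig, runner: LatentRunner, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, stream, runner.runner_id, int(round(runner.speed * 10))]
    )


def _timing(runner: LatentRunner, config: CohortConfig):
    stride_t = 1.0 / runner.true_sf
    tc = runner.true_df * stride_t
    lead = _LEAD_FRACTION * stride_t
    n_contacts = config.n_strides + _EXTRA_CONTACTS
    duration = lead + n_contacts * stride_t + _LEAD_FRACTION * stride_t
    return stride_t, tc, lead, n_contacts, duration


def true_events(runner: LatentRunner, config: CohortConfig) -> GaitEvents:
    """Analytic foot-strike/toe-off times of the generated waveform."""
    stride_t, tc, lead, n_contacts, _ = _timing(runner, config)
    fs = lead + stride_t * np.arange(n_contacts)
    return GaitEvents(foot_strikes=fs, toe_offs=fs + tc)


def synthesize_force(runner: LatentRunner, config: CohortConfig) -> ForceTrace:
    """Render the vertical force trace of one trial (1000 Hz).

    Within each contact the force is a half-sine whose peak makes the
    stride-mean force equal body weight; swing is zero.  Gaussian noise
    of sd ``noise_sd_force`` is added and the result truncated at 0 N.
    """
    if runner.true_df >= 0.5:
        raise ValueError("duty factor >= 0.5: no aerial phase, not running")
    stride_t, tc, lead, n_contacts, duration = _timing(runner, config)
    peak = 0.5 * np.pi * runner.body_mass * G_M_PER_S2 / runner.true_df
    t = np.arange(int(round(duration * FORCE_RATE_HZ))) / FORCE_RATE_HZ
    tau = np.mod(t - lead, stride_t)
    in_contact = (t >= lead) & (t < lead + n_contacts * stride_t) & (tau < tc)
    force = np.where(in_contact, peak * np.sin(np.pi * np.clip(tau, 0, tc) / tc), 0.0)
    if config.noise_sd_force > 0:
        rng = _trial_rng(config, runner, 2)
        force = force + rng.normal(0.0, config.noise_sd_force, force.size)
    return ForceTrace(samples=np.maximum(force, 0.0), rate=FORCE_RATE_HZ)


def synthesize_angle(
    runner: LatentRunner, events: GaitEvents, config: CohortConfig
) -> tuple[AngleTrace, AngleTrace]:
    """Render the running and static foot-angle traces (200 Hz).

    The running curve equals ``static_offset + true_fsa`` at every
    foot-strike instant (a local extremum, so nearest-sample lookup
    incurs only second-order error) and swings with the configured
    amplitude in between.  Short missing-frame gaps are inserted away
    from trace edges to exercise gap filling.  The static trace is the
    constant mounting offset.  Noise sd ``noise_sd_angle`` on both.
    """
    if events.foot_strikes.size == 0:
        raise ValueError("cannot synthesize an angle trace without foot-strike events")
    _, _, _, _, duration = _timing(runner, config)
    rng = _trial_rng(config, runner, 3)
    t = np.arange(int(round(duration * ANGLE_RATE_HZ))) / ANGLE_RATE_HZ
    phase = 2.0 * np.pi * runner.true_sf * (t - events.foot_strikes[0])
    angle = runner.static_offset + runner.true_fsa + config.angle_amplitude * (
        np.cos(phase) - 1.0
    ) / 2.0
    if config.noise_sd_angle > 0:
        angle = angle + rng.normal(0.0, config.noise_sd_angle, angle.size)
    # insert short gaps in the interior, clear of trace edges and of each
    # other so every gap keeps a full fit window of valid frames around it
    placed: list[tuple[int, int]] = []
    for _ in range(config.n_gaps_per_trial):
        length = int(rng.integers(2, config.max_gap_frames + 1))
        for _attempt in range(20):
            start = int(rng.integers(10, angle.size - length - 10))
            if all(start + length + 5 <= s or e + 5 <= start for s, e in placed):
                angle[start : start + length] = np.nan
                placed.append((start, start + length))
                break
    running = AngleTrace(samples=angle, rate=ANGLE_RATE_HZ)

    n_static = int(round(config.static_duration_s * ANGLE_RATE_HZ))
    static = runner.static_offset * np.ones(n_static)
    if config.noise_sd_angle > 0:
        static = static + rng.normal(0.0, config.noise_sd_angle, n_static)
    return running, AngleTrace(samples=static, rate=ANGLE_RATE_HZ)


@dataclass(frozen=True)
class TrialTraces:
    force: ForceTrace
    angle: AngleTrace
    static: AngleTrace
    events: GaitEvents  # analytic ground-truth events


def simulate_trial(runner: LatentRunner, config: CohortConfig) -> TrialTraces:
    force = synthesize_force(runner, config)
    events = true_events(runner, config)
    angle, static = synthesize_angle(runner, events, config)
    return TrialTraces(force=force, angle=angle, static=static, events=events)


# ---------------------------------------------------------------------------
# on-disk cohort layout


def _fmt_speed(speed: float) -> str:
    return f"{speed:g}"


def _write_csv(path: Path, frame: pd.DataFrame) -> str:
    frame.to_csv(path, index=False)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_cohort(
    runners: list[LatentRunner],
    shoes: pd.DataFrame,
    traces: dict[tuple[int, float], TrialTraces],
    path: str | Path,
    config: CohortConfig | None = None,
) -> dict:
    """Write a cohort directory and return its manifest.

    Layout: ``metadata.csv`` plus per trial ``force_<id>_<speed>.csv``
    (time_s, fz_n), ``angle_<id>_<speed>.csv`` (time_s, foot_angle_deg,
    missing cells empty) and per runner ``static_<id>.csv``.  The
    manifest lists every file with its sha256 checksum.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    meta_rows = []
    for r in runners:
        shoe = shoes.loc[shoes["runner_id"] == r.runner_id]
        meta_rows.append({
            "runner_id": r.runner_id, "speed_kmh": r.speed,
            "body_mass_kg": r.body_mass,
            "shoe_mass_g": float(shoe["shoe_mass_g"].iloc[0]) if len(shoe) else np.nan,
            "shoe_drop_mm": float(shoe["shoe_drop_mm"].iloc[0]) if len(shoe) else np.nan,
            "true_df": r.true_df, "true_fsa": r.true_fsa, "true_sf": r.true_sf,
        })
    metadata = pd.DataFrame(
        meta_rows,
        columns=["runner_id", "speed_kmh", "body_mass_kg", "shoe_mass_g",
                 "shoe_drop_mm", "true_df", "true_fsa", "true_sf"],
    )
    files["metadata.csv"] = _write_csv(path / "metadata.csv", metadata)

    statics_written: set[int] = set()
    for (runner_id, speed), trial in sorted(traces.items()):
        tag = f"{runner_id:03d}_{_fmt_speed(speed)}"
        files[f"force_{tag}.csv"] = _write_csv(
            path / f"force_{tag}.csv",
            pd.DataFrame({"time_s": trial.force.times(), "fz_n": trial.force.samples}),
        )
        files[f"angle_{tag}.csv"] = _write_csv(
            path / f"angle_{tag}.csv",
            pd.DataFrame({"time_s": trial.angle.times(),
                          "foot_angle_deg": trial.angle.samples}),
        )
        if runner_id not in statics_written:
            files[f"static_{runner_id:03d}.csv"] = _write_csv(
                path / f"static_{runner_id:03d}.csv",
                pd.DataFrame({"time_s": trial.static.times(),
                              "foot_angle_deg": trial.static.samples}),
            )
            statics_written.add(runner_id)

    manifest = {
        "seed": config.seed if config is not None else None,
        "n_runners": len({r.runner_id for r in runners}),
        "speeds": sorted({r.speed for r in runners}),
        "config": config.to_dict() if config is not None else None,
        "files": files,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_cohort(path: str | Path):
    """Read a cohort directory written by :func:`write_cohort`.

    Returns (metadata DataFrame, {(runner_id, speed): dict of traces}).
    """
    path = Path(path)
    # round_trip parsing so written samples are recovered bit-identically
    read = lambda p: pd.read_csv(p, float_precision="round_trip")
    metadata = read(path / "metadata.csv")
    trials: dict[tuple[int, float], dict] = {}
    for _, row in metadata.iterrows():
        runner_id = int(row["runner_id"])
        speed = float(row["speed_kmh"])
        tag = f"{runner_id:03d}_{_fmt_speed(speed)}"
        force_df = read(path / f"force_{tag}.csv")
        angle_df = read(path / f"angle_{tag}.csv")
        static_df = read(path / f"static_{runner_id:03d}.csv")
        trials[(runner_id, speed)] = {
            "force": ForceTrace(samples=force_df["fz_n"].to_numpy(), rate=FORCE_RATE_HZ),
            "angle": AngleTrace(samples=angle_df["foot_angle_deg"].to_numpy(),
                                rate=ANGLE_RATE_HZ),
            "static": AngleTrace(samples=static_df["foot_angle_deg"].to_numpy(),
                                 rate=ANGLE_RATE_HZ),
        }
    return metadata, trials
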