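"""Seeded synthetic cage growth, environment, and intake generators.

Emulates the statistical structure of a small cage-rearing study: a few
breeds reared in batches over ~77 days, sigmoidal (Gompertz) growth to a
breed-specific mature weight, daily-cyclic environmental traces whose
per-day gas maxima fall in configured ranges, and a monotonically
increasing per-bird intake profile tied to growth through a target feed
conversion ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "EnvRanges",
    "SyntheticDatasetConfig",
    "BREED_PRESETS",
    "gompertz",
    "gen_cage_trajectory",
    "gen_env_series",
    "gen_intake_profile",
    "gen_dataset",
    "read_daily_records",
    "write_daily_records",
    "read_env_table",
    "write_env_table",
]

RECORD_COLUMNS = [
    "date",
    "batch_id",
    "cage_id",
    "breed",
    "n_birds",
    "feed_offered_g",
    "feed_refused_g",
    "feed_spilled_g",
    "cage_weight_g",
]

ENV_COLUMNS = ["timestamp", "cage_id", "temp_c", "rh_pct", "co_ppm", "h2s_ppm", "nh3_ppm"]


@dataclass(frozen=True)
class GrowthParams:
    """Gompertz growth-curve parameters for one breed's cage trajectory.

    The mean curve is ``A * exp(-b * exp(-k * t))`` with age ``t`` in days;
    cage-level observations add Gaussian noise with SD ``obs_noise_sd``.
    """

    asymptote_A: float
    shape_b: float
    rate_k: float
    obs_noise_sd: float = 0.0
    birds_per_cage: int = 4

    def __post_init__(self) -> None:
        if self.asymptote_A <= 0:
            raise ValueError(f"asymptote_A must be > 0, got {self.asymptote_A}")
        if self.shape_b <= 0:
            raise ValueError(f"shape_b must be > 0, got {self.shape_b}")
        if self.rate_k <= 0:
            raise ValueError(f"rate_k must be > 0, got {self.rate_k}")
        if self.obs_noise_sd < 0:
            raise ValueError(f"obs_noise_sd must be >= 0, got {self.obs_noise_sd}")
        if self.birds_per_cage < 1:
            raise ValueError(f"birds_per_cage must be >= 1, got {self.birds_per_cage}")


#: Default per-breed growth presets; mature weights differ by breed and the
#: fastest-growing breed carries higher observation noise. All overridable.
BREED_PRESETS: dict[str, GrowthParams] = {
    "guzao": GrowthParams(asymptote_A=2600.0, shape_b=4.2, rate_k=0.040, obs_noise_sd=15.0),
    "huangjin": GrowthParams(asymptote_A=3000.0, shape_b=4.2, rate_k=0.040, obs_noise_sd=15.0),
    "red_junglefowl": GrowthParams(asymptote_A=3300.0, shape_b=4.2, rate_k=0.042, obs_noise_sd=30.0),
}


@dataclass(frozen=True)
class EnvRanges:
    """Distributional targets for the environmental sensor generator.

    Temperature and relative humidity follow a sinusoidal daily cycle
    around ``*_mean`` with amplitude ``*_amp``; each gas draws its per-day
    maximum uniformly from ``*_max_range`` and scales the intra-day
    profile to peak exactly at that value.
    """

    temp_mean: float = 26.0
    temp_amp: float = 3.0
    rh_mean: float = 65.0
    rh_amp: float = 8.0
    co_max_range: tuple[float, float] = (0.5, 3.0)
    h2s_max_range: tuple[float, float] = (0.2, 4.5)
    nh3_max_range: tuple[float, float] = (0.3, 4.0)
    samples_per_day: int = 24

    def __post_init__(self) -> None:
        for name in ("co_max_range", "h2s_max_range", "nh3_max_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < 0:
                raise ValueError(f"{name} endpoints must be >= 0, got ({lo}, {hi})")
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound: ({lo}, {hi})")
        if self.samples_per_day < 1:
            raise ValueError(f"samples_per_day must be >= 1, got {self.samples_per_day}")


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Layout of a synthetic dataset: batches, days, breeds, start dates."""

    n_batches: int = 3
    n_days: int = 77
    breeds: tuple[str, ...] = ("guzao", "huangjin", "red_junglefowl")
    batch_start_dates: tuple[str, ...] = ("2024-11-05", "2024-11-12", "2024-11-19")
    seed: int = 0
    #: target interval feed conversion ratio tying intake to growth
    fcr_target: float = 3.3
    #: unnormalized shape endpoints of the per-bird intake profile (g/day)
    intake_start_g: float = 57.0
    intake_end_g: float = 145.0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError(f"n_days must be >= 2, got {self.n_days}")
        if self.n_batches < 1:
            raise ValueError(f"n_batches must be >= 1, got {self.n_batches}")
        if len(self.batch_start_dates) != self.n_batches:
            raise ValueError(
                f"need {self.n_batches} batch_start_dates, got {len(self.batch_start_dates)}"
            )
        if len(set(self.batch_start_dates)) != self.n_batches:
            raise ValueError("batch_start_dates must be distinct")
        if not self.breeds:
            raise ValueError("at least one breed required")


def gompertz(t: np.ndarray | float, A: float, b: float, k: float) -> np.ndarray | float:
    """Gompertz mean weight ``A * exp(-b * exp(-k * t))`` at age ``t`` days."""
    return A * np.exp(-b * np.exp(-k * np.asarray(t, dtype=float)))


def gen_cage_trajectory(params: GrowthParams, n_days: int, seed: int) -> np.ndarray:
    """Per-day cage mean weights (g) for ages ``0 .. n_days-1``.

    Deterministic given ``seed``; the expected value follows the Gompertz
    curve of ``params`` and observations add i.i.d. Gaussian noise.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    ages = np.arange(n_days, dtype=float)
    mean = gompertz(ages, params.asymptote_A, params.shape_b, params.rate_k)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.obs_noise_sd, size=n_days) if params.obs_noise_sd > 0 else 0.0
    return np.maximum(mean + noise, 1.0)


def _daily_gas_profile(rng: np.random.Generator, n: int, hours: np.ndarray) -> np.ndarray:
    """Positive intra-day shape with a single afternoon-ish peak, max 1."""
    phase = rng.uniform(12.0, 18.0)
    shape = 0.55 + 0.45 * np.cos(2.0 * np.pi * (hours - phase) / 24.0)
    shape = shape * (1.0 + rng.uniform(-0.05, 0.05, size=n))
    shape = np.clip(shape, 0.05, None)
    return shape / shape.max()


def gen_env_series(
    ranges: EnvRanges,
    n_days: int,
    seed: int,
    start: str | date = "2024-11-05",
    cage_id: str = "cage-1",
) -> pd.DataFrame:
    """Timestamped environmental samples over ``n_days`` days.

    Emits ``ranges.samples_per_day`` evenly spaced samples per day. Each
    gas's per-day maximum is drawn uniformly inside its configured max
    range and the intra-day profile is scaled to peak exactly there, so
    every simulated day's maximum lies inside the range by construction.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    rng = np.random.default_rng(seed)
    start_dt = datetime.fromisoformat(str(start))
    n = ranges.samples_per_day
    step_h = 24.0 / n
    rows: list[pd.DataFrame] = []
    for d in range(n_days):
        hours = step_h * np.arange(n) + step_h / 2.0
        ts = [start_dt + timedelta(days=d, hours=float(h)) for h in hours]
        temp = (
            ranges.temp_mean
            + ranges.temp_amp * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)
            + rng.normal(0.0, 0.3, size=n)
        )
        rh = np.clip(
            ranges.rh_mean
            - ranges.rh_amp * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)
            + rng.normal(0.0, 1.0, size=n),
            0.0,
            100.0,
        )
        gases = {}
        for col, (lo, hi) in (
            ("co_ppm", ranges.co_max_range),
            ("h2s_ppm", ranges.h2s_max_range),
            ("nh3_ppm", ranges.nh3_max_range),
        ):
            day_max = rng.uniform(lo, hi)
            gases[col] = day_max * _daily_gas_profile(rng, n, hours)
        rows.append(
            pd.DataFrame(
                {
                    "timestamp": [t.isoformat() for t in ts],
                    "cage_id": cage_id,
                    "temp_c": temp,
                    "rh_pct": rh,
                    **gases,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[ENV_COLUMNS]


def gen_intake_profile(
    n_days: int, start_g: float, end_g: float, shape: str = "linear"
) -> np.ndarray:
    """Monotone non-decreasing per-bird daily intake profile (g/day).

    Used both as a realistic daily-feed series and as the unnormalized
    allocation shape for ration planning.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    if start_g <= 0 or end_g <= 0:
        raise ValueError("start_g and end_g must be > 0")
    if end_g < start_g:
        raise ValueError("end_g must be >= start_g for a non-decreasing profile")
    if shape != "linear":
        raise ValueError(f"unknown profile shape {shape!r}")
    return np.linspace(start_g, end_g, n_days)


def _batch_records(
    breed: str,
    batch_idx: int,
    start_date: str,
    params: GrowthParams,
    cfg: SyntheticDatasetConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_days = cfg.n_days
    # between-batch growth/intake scale (+/-2%): batches fed a little more
    # grow a little larger, so feed carries real signal for weight models
    batch_scale = float(rng.uniform(0.98, 1.02))
    traj = batch_scale * gen_cage_trajectory(params, n_days, int(rng.integers(0, 2**31)))
    mean0 = batch_scale * float(gompertz(0.0, params.asymptote_A, params.shape_b, params.rate_k))
    # emulate the on-farm intake check: initial weights are verified/adjusted
    # to sit within a tight band so all fall within +/-5% of their joint mean
    traj[0] = float(np.clip(traj[0], 0.985 * mean0, 1.015 * mean0))

    mean_gain = batch_scale * float(
        gompertz(n_days - 1, params.asymptote_A, params.shape_b, params.rate_k)
        - gompertz(0.0, params.asymptote_A, params.shape_b, params.rate_k)
    )
    profile = gen_intake_profile(n_days, cfg.intake_start_g, cfg.intake_end_g)
    per_bird_feed = profile * (cfg.fcr_target * mean_gain) / profile.sum()

    n_birds = params.birds_per_cage
    consumed = per_bird_feed * n_birds
    refused = consumed * rng.uniform(0.00, 0.03, size=n_days)
    spilled = consumed * rng.uniform(0.00, 0.015, size=n_days)
    offered = consumed + refused + spilled

    d0 = date.fromisoformat(start_date)
    return pd.DataFrame(
        {
            "date": [(d0 + timedelta(days=i)).isoformat() for i in range(n_days)],
            "batch_id": f"batch-{batch_idx + 1}",
            "cage_id": f"{breed}-b{batch_idx + 1}",
            "breed": breed,
            "n_birds": n_birds,
            "feed_offered_g": np.round(offered, 2),
            "feed_refused_g": np.round(refused, 2),
            "feed_spilled_g": np.round(spilled, 2),
            "cage_weight_g": np.round(traj * n_birds, 1),
        }
    )


def gen_dataset(
    config: SyntheticDatasetConfig,
    growth: dict[str, GrowthParams] | None = None,
    env: EnvRanges | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (daily record table, environmental sample table).

    Per breed the record table holds ``n_batches * n_days`` rows; one
    environmental series is generated per cage. Deterministic given
    ``config.seed``.
    """
    growth = dict(BREED_PRESETS) if growth is None else growth
    env = EnvRanges() if env is None else env
    missing = [b for b in config.breeds if b not in growth]
    if missing:
        raise ValueError(f"no GrowthParams for breeds: {missing}")

    rng = np.random.default_rng(config.seed)
    record_frames: list[pd.DataFrame] = []
    env_frames: list[pd.DataFrame] = []
    for breed in config.breeds:
        for j, start_date in enumerate(config.batch_start_dates):
            record_frames.append(_batch_records(breed, j, start_date, growth[breed], config, rng))
            env_frames.append(
                gen_env_series(
                    env,
                    config.n_days,
                    seed=int(rng.integers(0, 2**31)),
                    start=start_date,
                    cage_id=f"{breed}-b{j + 1}",
                )
            )
    records = pd.concat(record_frames, ignore_index=True)
    env_table = pd.concat(env_frames, ignore_index=True)
    env_table[["temp_c", "rh_pct", "co_ppm", "h2s_ppm", "nh3_ppm"]] = env_table[
        ["temp_c", "rh_pct", "co_ppm", "h2s_ppm", "nh3_ppm"]
    ].round(4)
    return records, env_table


def write_daily_records(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_daily_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"batch_id": str, "cage_id": str, "breed": str})


def write_env_table(env_table: pd.DataFrame, path: str | Path) -> None:
    env_table[ENV_COLUMNS].to_csv(path, index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cage_id": str})
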