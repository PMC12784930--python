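"""Leakage-safe preprocessing: ages, per-bird feed, 24-h environmental
aggregation, train-only imputation/scaling, temporal splits, blocked CV
folds, and construction of training pairs for both models."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WEIGHT_FEATURES",
    "ENV_FEATURES",
    "INTERVAL_FEATURES",
    "EnvDailySummary",
    "IntervalSpec",
    "TransformState",
    "SplitSpec",
    "compute_age",
    "per_bird_feed",
    "summarize_env",
    "fit_transform_state",
    "apply_transform",
    "inverse_transform",
    "temporal_split",
    "blocked_cv_folds",
    "build_weight_matrix",
    "build_interval_examples",
]

#: Fixed feature order of the daily body-weight model input vector.
WEIGHT_FEATURES = [
    "age_days",
    "temp_mean_c",
    "rh_mean_pct",
    "feed_g_per_bird",
    "co_max_ppm",
    "h2s_max_ppm",
    "nh3_max_ppm",
]

#: The five environmental features (used by environmental-only models).
ENV_FEATURES = ["temp_mean_c", "rh_mean_pct", "co_max_ppm", "h2s_max_ppm", "nh3_max_ppm"]

#: Input features of the interval total-feed model.
INTERVAL_FEATURES = ["w_start_g", "w_target_g", "d_remain"]


@dataclass(frozen=True)
class IntervalSpec:
    """Input of the interval total-feed model: start weight, target
    weight (both g/bird) and remaining rearing days."""

    w_start: float
    w_target: float
    d_remain: int

    def __post_init__(self) -> None:
        if self.w_start <= 0:
            raise ValueError(f"w_start must be > 0, got {self.w_start}")
        if self.w_target <= self.w_start:
            raise ValueError(
                f"w_target ({self.w_target}) must exceed w_start ({self.w_start})"
            )
        if self.d_remain < 1:
            raise ValueError(f"d_remain must be >= 1, got {self.d_remain}")


def compute_age(t_i: str | date, t_batch0: str | date) -> int:
    """Whole days elapsed from the batch start date to ``t_i``."""
    try:
        d_i = date.fromisoformat(str(t_i)[:10])
        d_0 = date.fromisoformat(str(t_batch0)[:10])
    except ValueError as exc:
        raise ValueError(f"unparseable ISO-8601 date: {exc}") from exc
    age = (d_i - d_0).days
    if age < 0:
        raise ValueError(f"record date {d_i} precedes batch start {d_0}")
    return age


def per_bird_feed(F_i: float, N_i: int) -> float:
    """Average daily feed allowance per bird, ``F_i / N_i`` (g/day)."""
    if N_i < 1:
        raise ZeroDivisionError(f"bird count must be >= 1 to compute per-bird feed, got {N_i}")
    if F_i < 0:
        raise ValueError(f"total feed must be >= 0, got {F_i}")
    return F_i / N_i


@dataclass(frozen=True)
class EnvDailySummary:
    """Per-day environmental aggregates over the pre-weighing window."""

    temp_mean_c: float
    rh_mean_pct: float
    co_max_ppm: float
    h2s_max_ppm: float
    nh3_max_ppm: float

    def is_missing(self) -> bool:
        return math.isnan(self.temp_mean_c)

    def as_dict(self) -> dict[str, float]:
        return {
            "temp_mean_c": self.temp_mean_c,
            "rh_mean_pct": self.rh_mean_pct,
            "co_max_ppm": self.co_max_ppm,
            "h2s_max_ppm": self.h2s_max_ppm,
            "nh3_max_ppm": self.nh3_max_ppm,
        }


MISSING_SUMMARY = EnvDailySummary(*(float("nan"),) * 5)


def summarize_env(samples: pd.DataFrame, weighing_time: datetime) -> EnvDailySummary:
    """Aggregate sensor samples over the half-open 24 h window
    ``(weighing_time - 24 h, weighing_time]``.

    Means for temperature and RH, maxima for the three gases. An empty
    window yields the missing-summary marker (imputed downstream).
    """
    ts = pd.to_datetime(samples["timestamp"])
    lo = weighing_time - timedelta(hours=24)
    in_window = samples[(ts > lo) & (ts <= weighing_time)]
    if in_window.empty:
        logger.warning("no environmental samples in 24 h window ending %s", weighing_time)
        return MISSING_SUMMARY
    return EnvDailySummary(
        temp_mean_c=float(in_window["temp_c"].mean()),
        rh_mean_pct=float(in_window["rh_pct"].mean()),
        co_max_ppm=float(in_window["co_ppm"].max()),
        h2s_max_ppm=float(in_window["h2s_ppm"].max()),
        nh3_max_ppm=float(in_window["nh3_ppm"].max()),
    )


@dataclass
class TransformState:
    """Per-feature statistics fitted exclusively on training rows.

    Stores min/max (for [0,1) scaling), mean/std (for imputation and the
    alternative z-score transform) and the categorical mode.
    """

    feature_names: list[str]
    mins: dict[str, float]
    maxs: dict[str, float]
    means: dict[str, float]
    stds: dict[str, float]
    modes: dict[str, object] = field(default_factory=dict)
    epsilon: float = 1e-8


def fit_transform_state(
    train: pd.DataFrame,
    feature_names: list[str] | None = None,
    categorical: list[str] | None = None,
    epsilon: float = 1e-8,
) -> TransformState:
    """Fit imputation and scaling statistics on training rows only."""
    categorical = categorical or []
    if feature_names is None:
        feature_names = [c for c in train.columns if c not in categorical]
    if len(train) < 1:
        raise ValueError("at least one training row required")
    mins, maxs, means, stds = {}, {}, {}, {}
    for col in feature_names:
        observed = pd.to_numeric(train[col], errors="coerce").dropna()
        if observed.empty:
            raise ValueError(f"feature {col!r} entirely missing in training data")
        mins[col] = float(observed.min())
        maxs[col] = float(observed.max())
        means[col] = float(observed.mean())
        stds[col] = float(observed.std(ddof=0))
    modes = {}
    for col in categorical:
        observed = train[col].dropna()
        if observed.empty:
            raise ValueError(f"categorical feature {col!r} entirely missing in training data")
        modes[col] = observed.mode().iloc[0]
    return TransformState(feature_names, mins, maxs, means, stds, modes, epsilon)


def apply_transform(
    rows: pd.DataFrame, state: TransformState, method: str = "minmax"
) -> pd.DataFrame:
    """Impute with training mean/mode, then scale.

    ``minmax`` maps to [0, 1): ``z = (x - min) / (max - min + eps)``.
    ``zscore`` standardizes with training moments.
    """
    out = rows.copy()
    for col in state.feature_names:
        x = pd.to_numeric(out[col], errors="coerce").fillna(state.means[col])
        if method == "minmax":
            out[col] = (x - state.mins[col]) / (state.maxs[col] - state.mins[col] + state.epsilon)
        elif method == "zscore":
            out[col] = (x - state.means[col]) / (state.stds[col] or 1.0)
        else:
            raise ValueError(f"unknown scaling method {method!r}")
    for col, mode in state.modes.items():
        out[col] = out[col].fillna(mode)
    return out


def inverse_transform(
    rows: pd.DataFrame, state: TransformState, method: str = "minmax"
) -> pd.DataFrame:
    """Inverse of :func:`apply_transform` for non-missing values."""
    out = rows.copy()
    for col in state.feature_names:
        z = pd.to_numeric(out[col], errors="coerce")
        if method == "minmax":
            out[col] = z * (state.maxs[col] - state.mins[col] + state.epsilon) + state.mins[col]
        elif method == "zscore":
            out[col] = z * (state.stds[col] or 1.0) + state.means[col]
        else:
            raise ValueError(f"unknown scaling method {method!r}")
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Positional train/test indices of a batch-wise temporal split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    test_fraction: float = 0.1


def temporal_split(
    records: pd.DataFrame,
    test_fraction: float = 0.1,
    batch_col: str = "batch_id",
    date_col: str = "date",
) -> SplitSpec:
    """Batch-wise temporal split at a 9:1 ratio (default).

    Within each batch's temporal order the last ``ceil(test_fraction * n)``
    records form the test subset; the union over batches is the test set.
    Batches with fewer than 2 records go wholly to train with a warning.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for batch, grp in records.groupby(batch_col, sort=False):
        order = grp.sort_values(date_col, kind="stable").index.to_numpy()
        n = len(order)
        if n < 2:
            logger.warning("batch %s has %d record(s); placed wholly in train", batch, n)
            train_parts.append(order)
            continue
        n_test = math.ceil(test_fraction * n)
        train_parts.append(order[: n - n_test])
        test_parts.append(order[n - n_test :])
    train_idx = np.concatenate(train_parts) if train_parts else np.array([], dtype=int)
    test_idx = np.concatenate(test_parts) if test_parts else np.array([], dtype=int)
    return SplitSpec(np.sort(train_idx), np.sort(test_idx), test_fraction)


def blocked_cv_folds(
    records: pd.DataFrame,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    batch_col: str = "batch_id",
    date_col: str = "date",
) -> np.ndarray:
    """Repeated blocked cross-validation fold labels.

    Returns an integer array of shape ``(repeats, len(records))`` where
    entry ``[r, i]`` is the fold (0..k-1) of record ``i`` in repeat ``r``.
    Within each batch the folds are contiguous temporal blocks; repeats
    jitter the block boundaries deterministically from ``seed``. Repeat 0
    uses un-jittered equal splits.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    labels = np.empty((repeats, len(records)), dtype=int)
    for batch, grp in records.groupby(batch_col, sort=False):
        order = grp.sort_values(date_col, kind="stable").index.to_numpy()
        positions = records.index.get_indexer(order)
        n = len(order)
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} records of batch {batch}")
        base_cuts = np.array([round(j * n / k) for j in range(1, k)], dtype=int)
        jitter_scale = max(1, n // (4 * k))
        for r in range(repeats):
            cuts = base_cuts.copy()
            if r > 0:
                cuts = cuts + rng.integers(-jitter_scale, jitter_scale + 1, size=k - 1)
                cuts = np.clip(np.sort(cuts), 1, n - 1)
                # keep cuts strictly increasing so no fold is empty
                for j in range(1, k - 1):
                    cuts[j] = max(cuts[j], cuts[j - 1] + 1)
                cuts = np.minimum(cuts, np.arange(n - (k - 1), n))
            fold_of_pos = np.searchsorted(cuts, np.arange(n), side="right")
            labels[r, positions] = fold_of_pos
    return labels


def _env_lookup(env_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {cid: grp for cid, grp in env_table.groupby("cage_id", sort=False)}


def build_weight_matrix(
    records: pd.DataFrame,
    env_table: pd.DataFrame,
    weighing_time: str = "08:00",
) -> pd.DataFrame:
    """Assemble the daily body-weight model matrix.

    One row per cage-day with the 7 features in fixed order plus the
    target ``y_g_per_bird`` (cage weight / bird count) and bookkeeping
    columns (``date``, ``batch_id``, ``cage_id``, ``breed``). Daily intake
    is feed offered minus refusals, corrected for spillage.
    """
    weigh_t = time.fromisoformat(weighing_time)
    batch_starts = records.groupby("batch_id")["date"].min().to_dict()
    by_cage = _env_lookup(env_table)
    rows = []
    for rec in records.itertuples(index=False):
        consumed = rec.feed_offered_g - rec.feed_refused_g - rec.feed_spilled_g
        f_i = per_bird_feed(max(consumed, 0.0), rec.n_birds)
        weigh_dt = datetime.combine(date.fromisoformat(rec.date), weigh_t)
        cage_env = by_cage.get(rec.cage_id)
        summary = (
            summarize_env(cage_env, weigh_dt) if cage_env is not None else MISSING_SUMMARY
        )
        rows.append(
            {
                "date": rec.date,
                "batch_id": rec.batch_id,
                "cage_id": rec.cage_id,
                "breed": rec.breed,
                "age_days": compute_age(rec.date, batch_starts[rec.batch_id]),
                **summary.as_dict(),
                "feed_g_per_bird": f_i,
                "y_g_per_bird": rec.cage_weight_g / rec.n_birds,
            }
        )
    cols = ["date", "batch_id", "cage_id", "breed", *WEIGHT_FEATURES, "y_g_per_bird"]
    return pd.DataFrame(rows)[cols]


def build_interval_examples(
    matrix: pd.DataFrame,
    min_days: int = 7,
    horizon: int | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Interval training pairs for the total-feed model.

    For every cage and ordered day pair ``(s, e)`` with
    ``min_days <= e - s <= horizon`` (stride over ``s``), emit
    ``(w_start, w_target, d_remain)`` with target total feed
    ``sum of per-bird feed over days s+1 .. e`` (exclusive of the start
    day, inclusive of the end day). Pairs with non-increasing weight are
    skipped and counted in the log.
    """
    out = []
    skipped = 0
    for _, grp in matrix.groupby("cage_id", sort=False):
        grp = grp.sort_values("age_days", kind="stable")
        ages = grp["age_days"].to_numpy()
        y = grp["y_g_per_bird"].to_numpy()
        f = grp["feed_g_per_bird"].to_numpy()
        cum_f = np.concatenate([[0.0], np.cumsum(f)])
        n = len(grp)
        max_len = horizon if horizon is not None else n - 1
        for s in range(0, n - min_days, stride):
            for e in range(s + min_days, min(s + max_len, n - 1) + 1):
                if y[e] <= y[s]:
                    skipped += 1
                    continue
                out.append(
                    {
                        "w_start_g": y[s],
                        "w_target_g": y[e],
                        "d_remain": int(ages[e] - ages[s]),
                        "total_feed_g": float(cum_f[e + 1] - cum_f[s + 1]),
                    }
                )
    if skipped:
        logger.warning("skipped %d non-monotone interval pairs", skipped)
    return pd.DataFrame(out, columns=INTERVAL_FEATURES + ["total_feed_g"])
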