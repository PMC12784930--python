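"""Closed-loop ration scheduling.

Forecast the interval feed total, shape it into a constrained daily
ration plan, simulate the resulting weight trajectory with the daily
body-weight model, and proportionally correct the interval total until
the simulated terminal weight matches the target (or the iteration
budget is exhausted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fowlplan.preprocessing import ENV_FEATURES, INTERVAL_FEATURES, WEIGHT_FEATURES, IntervalSpec

logger = logging.getLogger(__name__)

__all__ = [
    "RationPlan",
    "ScheduleConfig",
    "ScheduleResult",
    "climatology_forecast",
    "forecast_interval_feed",
    "allocate_profile",
    "allocate_arithmetic",
    "enforce_constraints",
    "simulate_trajectory",
    "update_interval_total",
    "run_schedule",
    "compute_fcr",
]


@dataclass(frozen=True)
class RationPlan:
    """Per-bird daily ration sequence for one interval.

    The interval total is the exact sum of the daily rations (mass
    conservation); cage-level rations scale by the bird count.
    """

    rations_g: np.ndarray
    ages: np.ndarray
    n_birds: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "rations_g", np.asarray(self.rations_g, dtype=float))
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        if len(self.rations_g) != len(self.ages):
            raise ValueError("rations and ages must have equal length")
        if (self.rations_g < 0).any():
            raise ValueError("daily rations must be >= 0")

    @property
    def interval_total_g(self) -> float:
        return float(self.rations_g.sum())

    @property
    def cage_rations_g(self) -> np.ndarray:
        return self.rations_g * self.n_birds

    def to_frame(self, predicted_weights: np.ndarray | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "age_days": self.ages,
                "per_bird_ration_g": self.rations_g,
                "cage_ration_g": self.cage_rations_g,
            }
        )
        if predicted_weights is not None:
            out["predicted_weight_g"] = np.asarray(predicted_weights, dtype=float)
        return out


@dataclass(frozen=True)
class ScheduleConfig:
    """Tolerances, iteration budget and operational ration constraints."""

    tolerance_g: float = 10.0
    max_iterations: int = 20
    daily_min_g: float = 10.0
    daily_max_g: float = 250.0
    max_rel_change: float = 0.10
    gain_clip_g: tuple[float, float] | None = (0.0, 80.0)

    def __post_init__(self) -> None:
        if self.tolerance_g <= 0:
            raise ValueError("tolerance_g must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.max_rel_change <= 1:
            raise ValueError("max_rel_change must be in (0, 1]")
        if not 0 <= self.daily_min_g <= self.daily_max_g:
            raise ValueError("need 0 <= daily_min_g <= daily_max_g")


@dataclass(frozen=True)
class ScheduleResult:
    """Outcome of one closed-loop scheduling run."""

    plan: RationPlan
    trajectory_g: np.ndarray
    terminal_weights_g: list[float]
    iterations: int
    terminal_error_g: float
    converged: bool
    fcr: float


def climatology_forecast(env_daily: pd.DataFrame, n_days: int, trailing: int = 7) -> pd.DataFrame:
    """Default environmental forecast: the mean of the trailing observed
    days, repeated for every interval day."""
    if env_daily.empty:
        raise ValueError("need at least one observed environmental day")
    tail = env_daily[ENV_FEATURES].tail(trailing).mean()
    return pd.DataFrame([tail] * n_days).reset_index(drop=True)


def forecast_interval_feed(spec: IntervalSpec, feed_model, cfg: ScheduleConfig | None = None) -> float:
    """Predicted per-bird total feed (g) for the interval.

    A non-positive prediction is flagged and floored at
    ``daily_min_g * d_remain`` so downstream allocation stays feasible.
    """
    cfg = cfg or ScheduleConfig()
    row = pd.DataFrame(
        [[spec.w_start, spec.w_target, spec.d_remain]], columns=INTERVAL_FEATURES
    )
    pred = float(feed_model.predict(row)[0])
    floor = max(cfg.daily_min_g, 1e-6) * spec.d_remain
    if pred <= 0:
        logger.warning("feed model predicted %.2f g <= 0; flooring at %.2f g", pred, floor)
        return floor
    return max(pred, floor)


def allocate_profile(total_g: float, profile) -> np.ndarray:
    """Distribute the interval total over days proportionally to a
    non-negative unnormalized profile; the sum is exact (the last day
    absorbs the floating-point residual)."""
    pi = np.asarray(profile, dtype=float)
    if (pi < 0).any():
        raise ValueError("profile weights must be >= 0")
    s = pi.sum()
    if s <= 0:
        raise ValueError("profile weights sum to zero")
    f = total_g * pi / s
    f[-1] = total_g - f[:-1].sum()
    return f


def allocate_arithmetic(total_g: float, n_days: int, first_term: float, common_diff: float) -> np.ndarray:
    """Arithmetic-progression allocation scaled to the interval total."""
    m = np.arange(1, n_days + 1, dtype=float)
    raw = first_term + (m - 1) * common_diff
    bad = np.nonzero(raw <= 0)[0]
    if bad.size:
        raise ValueError(
            f"arithmetic progression is non-positive on day {bad[0] + 1} "
            f"(a={first_term}, d={common_diff})"
        )
    return allocate_profile(total_g, raw)


def _check_feasible(total_g: float, n: int, cfg: ScheduleConfig) -> None:
    if total_g < cfg.daily_min_g * n - 1e-9:
        raise ValueError(
            f"interval total {total_g:.2f} g below daily minimum x {n} days "
            f"({cfg.daily_min_g * n:.2f} g): daily_min_g is binding"
        )
    if total_g > cfg.daily_max_g * n + 1e-9:
        raise ValueError(
            f"interval total {total_g:.2f} g above daily maximum x {n} days "
            f"({cfg.daily_max_g * n:.2f} g): daily_max_g is binding"
        )


def _band_ok(f: np.ndarray, band: float, tol: float = 1e-9) -> bool:
    prev = f[:-1]
    return bool(
        np.all(f[1:] >= prev * (1 - band) - tol) and np.all(f[1:] <= prev * (1 + band) + tol)
    )


def _feasible(f: np.ndarray, total: float, cfg: ScheduleConfig) -> bool:
    return (
        bool(np.all(f >= cfg.daily_min_g - 1e-9) and np.all(f <= cfg.daily_max_g + 1e-9))
        and _band_ok(f, cfg.max_rel_change)
        and abs(f.sum() - total) <= 1e-6 * max(total, 1.0)
    )


def enforce_constraints(plan: RationPlan, cfg: ScheduleConfig) -> RationPlan:
    """Project the plan onto the operational constraint set while keeping
    the interval total fixed.

    Alternating projection: clip to [daily min, daily max], run forward
    and backward passes that clip day-to-day relative changes into the
    band, then rescale to restore the total; repeated until all
    constraints hold within 1e-6 relative (at most 50 rounds). If the
    projection cycles, the plan is blended toward the uniform allocation
    (always feasible once the total passes the bound check, since the
    constraint set is convex) by bisection on the blend weight.
    """
    f = plan.rations_g.copy()
    total = float(f.sum())
    if total <= 0:
        raise ValueError("plan total must be > 0")
    n = len(f)
    _check_feasible(total, n, cfg)
    band = cfg.max_rel_change
    if _feasible(f, total, cfg):
        return plan
    for _ in range(50):
        f = np.clip(f, cfg.daily_min_g, cfg.daily_max_g)
        for i in range(1, n):
            f[i] = np.clip(f[i], f[i - 1] * (1 - band), f[i - 1] * (1 + band))
        for i in range(n - 2, -1, -1):
            hi = f[i + 1] / (1 - band) if band < 1 else np.inf
            f[i] = np.clip(f[i], f[i + 1] / (1 + band), hi)
        s = f.sum()
        if s <= 0:
            raise ValueError("constraint projection collapsed the plan to zero")
        f *= total / s
        if _feasible(f, total, cfg):
            return replace(plan, rations_g=f)
    # bisection blend toward the (feasible, total-conserving) uniform plan
    uniform = np.full(n, total / n)
    lo_t, hi_t = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        if _feasible((1 - mid) * f + mid * uniform, total, cfg):
            hi_t = mid
        else:
            lo_t = mid
    blended = (1 - hi_t) * f + hi_t * uniform
    if not _feasible(blended, total, cfg):
        raise ValueError(
            "could not satisfy ration constraints while conserving the interval total; "
            f"check daily bounds [{cfg.daily_min_g}, {cfg.daily_max_g}] and band {band}"
        )
    logger.warning("constraint projection cycled; blended %.1f%% toward uniform", 100 * hi_t)
    return replace(plan, rations_g=blended)


def simulate_trajectory(
    plan: RationPlan,
    env: pd.DataFrame,
    weight_model,
    cfg: ScheduleConfig | None = None,
    w_start: float | None = None,
) -> np.ndarray:
    """Simulate per-day predicted weights over the interval.

    Each day's features are (age, environmental forecast, planned
    ration); daily gains are optionally clipped into ``cfg.gain_clip_g``
    with the clipped weight propagated to the next day's comparison.
    """
    cfg = cfg or ScheduleConfig()
    if len(env) != len(plan.rations_g):
        raise ValueError(f"need one env row per interval day: {len(env)} vs {len(plan.rations_g)}")
    X = pd.DataFrame(
        {
            "age_days": plan.ages.astype(float),
            **{c: env[c].to_numpy(dtype=float) for c in ENV_FEATURES},
            "feed_g_per_bird": plan.rations_g,
        }
    )[WEIGHT_FEATURES]
    raw = weight_model.predict(X)
    if cfg.gain_clip_g is None:
        return raw
    lo, hi = cfg.gain_clip_g
    out = np.empty_like(raw)
    if w_start is None:
        out[0], prev, start = float(raw[0]), float(raw[0]), 1
    else:
        prev, start = float(w_start), 0
    for i in range(start, len(raw)):
        out[i] = float(np.clip(raw[i], prev + lo, prev + hi))
        prev = out[i]
    return out


def update_interval_total(total_g: float, w_end_g: float, w_target_g: float) -> float:
    """Proportional correction of the interval feed total."""
    if w_end_g <= 0:
        raise ValueError(f"simulated terminal weight must be > 0, got {w_end_g}")
    return total_g * w_target_g / w_end_g


def run_schedule(
    spec: IntervalSpec,
    feed_model,
    weight_model,
    env: pd.DataFrame,
    cfg: ScheduleConfig | None = None,
    profile=None,
    first_term: float = 1.0,
    common_diff: float | None = None,
    start_age: int = 0,
    n_birds: int = 1,
) -> ScheduleResult:
    """Run the closed scheduling loop.

    forecast -> allocate -> constrain -> simulate -> proportional update,
    until the terminal error is within tolerance or the iteration budget
    is reached. Reallocation after each update rescales every day by the
    same factor, preserving the allocation shape, and re-enforces the
    constraints. The best (lowest |terminal error|) iterate is returned
    when the loop does not converge.
    """
    cfg = cfg or ScheduleConfig()
    n = spec.d_remain
    ages = start_age + 1 + np.arange(n)
    total = forecast_interval_feed(spec, feed_model, cfg)
    total = float(np.clip(total, cfg.daily_min_g * n, cfg.daily_max_g * n))
    if profile is not None:
        rations = allocate_profile(total, profile)
    else:
        if common_diff is None:
            # default shape: rations double across the interval
            common_diff = first_term / (n - 1) if n > 1 else 0.0
        rations = allocate_arithmetic(total, n, first_term, common_diff)
    plan = enforce_constraints(RationPlan(rations, ages, n_birds), cfg)

    terminal_weights: list[float] = []
    best: tuple[float, RationPlan, np.ndarray] | None = None
    converged = False
    iterations = 0
    for _ in range(cfg.max_iterations):
        iterations += 1
        traj = simulate_trajectory(plan, env, weight_model, cfg, w_start=spec.w_start)
        w_end = float(traj[-1])
        terminal_weights.append(w_end)
        err = w_end - spec.w_target
        if best is None or abs(err) < abs(best[0]):
            best = (err, plan, traj)
        if abs(err) <= cfg.tolerance_g:
            converged = True
            break
        if len(terminal_weights) >= 2 and abs(w_end - terminal_weights[-2]) <= 1e-6 * max(
            abs(w_end), 1.0
        ):
            logger.warning(
                "terminal weight stagnated at %.1f g after %d iterations "
                "(model unresponsive to feed updates); stopping early",
                w_end,
                iterations,
            )
            break
        new_total = update_interval_total(plan.interval_total_g, w_end, spec.w_target)
        new_total = float(np.clip(new_total, cfg.daily_min_g * n, cfg.daily_max_g * n))
        scaled = plan.rations_g * (new_total / plan.interval_total_g)
        plan = enforce_constraints(replace(plan, rations_g=scaled), cfg)

    err, plan, traj = best
    return ScheduleResult(
        plan=plan,
        trajectory_g=traj,
        terminal_weights_g=terminal_weights,
        iterations=iterations,
        terminal_error_g=float(err),
        converged=converged,
        fcr=compute_fcr(plan.rations_g, spec.w_start, float(traj[-1]))
        if traj[-1] > spec.w_start
        else float("nan"),
    )


def compute_fcr(rations, w_start_g: float, w_end_g: float) -> float:
    """Interval feed conversion ratio: total per-bird feed over weight gain."""
    if w_end_g <= w_start_g:
        raise ValueError(
            f"FCR undefined: terminal weight {w_end_g} g does not exceed start {w_start_g} g"
        )
    return float(np.sum(np.asarray(rations, dtype=float)) / (w_end_g - w_start_g))
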