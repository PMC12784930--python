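"""Partial-budget evaluation of feeding-schedule outcomes.

Translates an FCR improvement into feed mass saved per batch and its
monetary value. All results are computed at full precision; display
rounding is a separate, explicit step that never feeds back into
computation.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EconomicScenario:
    """Inputs of the partial-budget calculation.

    ``fcr_baseline`` and ``fcr_improved`` are the two regimens' feed
    conversion ratios; ``gain_kg`` is live-weight gain per bird and
    ``feed_price`` is per kg of feed (currency is a free label).
    """

    n_birds: int
    gain_kg: float
    fcr_baseline: float
    fcr_improved: float
    feed_price: float
    currency: str = "NTD"

    def __post_init__(self) -> None:
        if self.n_birds < 1:
            raise ValueError(f"n_birds must be >= 1, got {self.n_birds}")
        if self.gain_kg <= 0:
            raise ValueError(f"gain_kg must be > 0, got {self.gain_kg}")
        if self.feed_price < 0:
            raise ValueError(f"feed_price must be >= 0, got {self.feed_price}")

    @property
    def delta_fcr(self) -> float:
        return self.fcr_baseline - self.fcr_improved


@dataclass(frozen=True)
class EconomicResult:
    """Full-precision feed saving (kg) and its monetary value."""

    delta_feed_kg: float
    saving: float
    currency: str = "NTD"

    @property
    def delta_feed_display(self) -> float:
        return round(self.delta_feed_kg, 2)

    @property
    def saving_display(self) -> float:
        """Saving rounded for display: one decimal for small values, the
        integer part for values of 1000 and above."""
        if abs(self.saving) >= 1000:
            return float(int(self.saving))
        return round(self.saving, 1)


def partial_budget(scenario: EconomicScenario) -> EconomicResult:
    """Feed saved and its value for a batch under an FCR improvement.

    ``delta_feed = delta_FCR * gain_kg * n_birds`` (kg) and
    ``saving = delta_feed * feed_price``.
    """
    delta_feed = scenario.delta_fcr * scenario.gain_kg * scenario.n_birds
    return EconomicResult(
        delta_feed_kg=delta_feed,
        saving=delta_feed * scenario.feed_price,
        currency=scenario.currency,
    )


def fcr_contrast(
    intake_baseline_g: float,
    gain_baseline_g: float,
    intake_improved_g: float,
    gain_improved_g: float,
) -> tuple[float, float, float]:
    """FCR of two regimens and the relative reduction (%).

    Returns ``(fcr_baseline, fcr_improved, reduction_pct)`` with
    ``reduction = 100 * (FCR0 - FCR1) / FCR0``. Following the reporting
    convention for interval FCRs, the reduction is computed from the
    FCRs rounded to two decimals (the precision at which they are
    quoted); the returned FCRs themselves are full precision. A negative
    reduction (the improved group is worse) is reported as-is.
    """
    if gain_baseline_g <= 0 or gain_improved_g <= 0:
        raise ValueError("weight gains must be > 0 to compute FCR")
    fcr0 = intake_baseline_g / gain_baseline_g
    fcr1 = intake_improved_g / gain_improved_g
    r0, r1 = round(fcr0, 2), round(fcr1, 2)
    return fcr0, fcr1, 100.0 * (r0 - r1) / r0
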