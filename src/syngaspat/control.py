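"""Operational decision rules: acetate feed law, dilution bookkeeping, gas alarms.

Three small pieces of logic sit between the soft sensors and the operator:

* the fed-batch acetic-acid feed law, 0.17 mmol per OD600 unit, per litre and
  per hour, applied as long as residual acetate stays consumed, and held or
  reduced to the measured consumption rate once acetate accumulates;
* chemostat bookkeeping (dilution rate from medium flow and working volume,
  acetate concentration of the combined feed, inoculation dilution);
* a two-level latching alarm state machine for CO (ppm) and H2 (vol%) room
  detectors: level 1 warns, level 2 closes the gas supply valves, as do a
  power loss or an emergency switch, and a shutdown latches until readings
  are back below level 1 *and* an operator resets it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

#: Empirical fed-batch acetate demand, mmol per OD600 unit per litre per hour.
FEED_COEFFICIENT_MMOL_PER_OD_L_H = 0.17

#: Residual acetate (mM) above which the culture counts as accumulating.
ACCUMULATION_THRESHOLD_MM = 0.5

ACETIC_ACID_MOLAR_MASS_G_MOL = 60.052

FeedMode = Literal["law", "hold", "reduced"]
AlarmLevel = Literal["none", "warn", "shutdown"]


@dataclass(frozen=True)
class FeedCommand:
    """One acetate feed-rate decision."""

    time_h: float
    acetate_feed_mmol_h: float
    mode: FeedMode

    def __post_init__(self) -> None:
        if self.acetate_feed_mmol_h < 0:
            raise ValueError("feed rate must be >= 0")


def feed_rate(
    od600: float,
    volume_l: float,
    residual_acetate_mm: float,
    previous_feed_mmol_h: float | None = None,
    measured_consumption_mmol_h: float | None = None,
    time_h: float = 0.0,
    accumulation_threshold_mm: float = ACCUMULATION_THRESHOLD_MM,
    coefficient: float = FEED_COEFFICIENT_MMOL_PER_OD_L_H,
) -> FeedCommand:
    """Acetic-acid feed command from the current OD600 and residual acetate.

    While residual acetate stays at or below the accumulation threshold the
    demand law ``coefficient * OD600 * V`` applies. Once acetate accumulates,
    the feed is capped at the smaller of the previous set point and the
    measured consumption rate (mode ``reduced`` when the consumption estimate
    is binding, ``hold`` otherwise).
    """
    if od600 < 0 or volume_l <= 0 or residual_acetate_mm < 0:
        raise ValueError("OD600 and residual acetate must be >= 0, volume > 0")
    law_value = coefficient * od600 * volume_l
    if residual_acetate_mm <= accumulation_threshold_mm:
        return FeedCommand(time_h, law_value, "law")
    previous = law_value if previous_feed_mmol_h is None else previous_feed_mmol_h
    if measured_consumption_mmol_h is not None and measured_consumption_mmol_h < previous:
        return FeedCommand(time_h, max(measured_consumption_mmol_h, 0.0), "reduced")
    return FeedCommand(time_h, previous, "hold")


def dilution_rate(medium_flow_ml_h: float, working_volume_l: float) -> float:
    """Chemostat dilution rate D in h^-1 from medium flow (ml/h) and volume (l)."""
    if medium_flow_ml_h < 0 or working_volume_l <= 0:
        raise ValueError("flow must be >= 0 and working volume > 0")
    return (medium_flow_ml_h / 1000.0) / working_volume_l


def combined_feed_acetate_mm(
    medium_flow_ml_h: float,
    stock_feed_g_h: float,
    stock_molarity_m: float = 2.0,
    stock_density_g_ml: float = 1.0,
) -> float:
    """Acetate concentration (mM) of the combined chemostat feed.

    The acid stock is dosed gravimetrically: ``stock_feed_g_h`` grams of stock
    *solution* per hour at ``stock_density_g_ml`` joins ``medium_flow_ml_h``
    of fresh medium.
    """
    if medium_flow_ml_h <= 0 or stock_feed_g_h < 0:
        raise ValueError("medium flow must be > 0 and stock feed >= 0")
    stock_ml_h = stock_feed_g_h / stock_density_g_ml
    acetate_mmol_h = stock_ml_h * stock_molarity_m
    total_l_h = (medium_flow_ml_h + stock_ml_h) / 1000.0
    return acetate_mmol_h / total_l_h


def inoculation_od(stock_od: float, inoculum_ml: float, medium_ml: float) -> float:
    """OD600 after diluting an inoculum into medium (combined final volume)."""
    if stock_od < 0 or inoculum_ml < 0 or medium_ml <= 0:
        raise ValueError("negative volumes or OD are not physical")
    return stock_od * inoculum_ml / (medium_ml + inoculum_ml)


@dataclass(frozen=True)
class AlarmConfig:
    """Two-level gas alarm thresholds: CO in ppm, H2 in vol%."""

    co_warn_ppm: float = 100.0
    co_shutdown_ppm: float = 150.0
    h2_warn_volpct: float = 0.8
    h2_shutdown_volpct: float = 1.6

    def __post_init__(self) -> None:
        if not (0 <= self.co_warn_ppm < self.co_shutdown_ppm):
            raise ValueError("CO level-1 threshold must be below level-2")
        if not (0 <= self.h2_warn_volpct < self.h2_shutdown_volpct):
            raise ValueError("H2 level-1 threshold must be below level-2")


@dataclass(frozen=True)
class AlarmState:
    """Current alarm level and valve position; shutdown latches."""

    level: AlarmLevel = "none"
    latched: bool = False
    last_event: str = ""

    @property
    def valves(self) -> Literal["open", "closed"]:
        return "closed" if self.level == "shutdown" else "open"


def alarm_step(
    state: AlarmState,
    co_ppm: float,
    h2_volpct: float,
    events: Iterable[str] = (),
    config: AlarmConfig = AlarmConfig(),
) -> AlarmState:
    """Advance the alarm state machine by one reading.

    Shutdown (valves closed) triggers at level-2 readings, on ``power_loss``
    or ``emergency`` events, or while a previous shutdown is latched. A
    warning is raised at level-1 readings. Increasing a reading can never
    lower the resulting level.
    """
    if co_ppm < 0 or h2_volpct < 0:
        raise ValueError("detector readings must be >= 0")
    events = tuple(events)
    hard = (
        co_ppm >= config.co_shutdown_ppm
        or h2_volpct >= config.h2_shutdown_volpct
        or "power_loss" in events
        or "emergency" in events
    )
    if hard or state.latched:
        return AlarmState(
            level="shutdown",
            latched=True,
            last_event=",".join(events) if events else state.last_event,
        )
    if co_ppm >= config.co_warn_ppm or h2_volpct >= config.h2_warn_volpct:
        return AlarmState(level="warn", latched=False, last_event=state.last_event)
    return AlarmState(level="none", latched=False, last_event=state.last_event)


def alarm_reset(
    state: AlarmState,
    co_ppm: float,
    h2_volpct: float,
    config: AlarmConfig = AlarmConfig(),
) -> AlarmState:
    """Operator reset: clears a latched shutdown only once readings are below level 1."""
    if co_ppm < config.co_warn_ppm and h2_volpct < config.h2_warn_volpct:
        return AlarmState(level="none", latched=False, last_event="reset")
    return replace(state)
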