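"""Inert-gas-balanced gas consumption and production rates.

With N2 as a non-reacting tracer, the outlet molar flow follows from N2
conservation and the CO consumption rate (mol min^-1) is

    n_CO = (F_G / V_m) * (X_CO_in - X_CO_out * X_N2_in / X_N2_out) / 100

where F_G is the total feed gas flow (ml min^-1), V_m the molar volume
(ml mol^-1, default ideal gas at 25 C and 1 atm) and X the mole percents of
the feed and off-gas. H2 and CO2 production rates use the same balance with
the opposite orientation so that both consumption (CO) and production
(H2, CO2) are reported as positive numbers during normal operation.

Compositions are renormalized to 100 % before balancing so deconvolution
residuals cannot leak into the rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import INERT_GAS, GasComposition

#: Ideal-gas molar volume at 25 C, 1 atm, in ml mol^-1.
MOLAR_VOLUME_25C_ML_MOL = 24465.0


@dataclass(frozen=True)
class GasFeedSpec:
    """Feed gas definition: total flow, composition and molar volume."""

    flow_ml_min: float
    composition: GasComposition
    molar_volume_ml_mol: float = MOLAR_VOLUME_25C_ML_MOL

    def __post_init__(self) -> None:
        if self.flow_ml_min <= 0:
            raise ValueError("gas flow must be > 0")
        if self.molar_volume_ml_mol <= 0:
            raise ValueError("molar volume must be > 0")
        if self.composition[INERT_GAS] <= 0:
            raise ValueError(f"feed must contain the inert gas {INERT_GAS}")

    @property
    def total_molar_flow(self) -> float:
        """Total feed molar flow in mol min^-1."""
        return self.flow_ml_min / self.molar_volume_ml_mol


@dataclass(frozen=True)
class RatePoint:
    """Gas rates at one time point (mol min^-1; CO consumption positive,
    H2/CO2 production positive)."""

    time_h: float
    n_co: float
    n_h2: float
    n_co2: float
    flag: bool = False


def _balanced_out_percent(feed: GasComposition, offgas: GasComposition, gas: str) -> float:
    """Off-gas percent of `gas` rescaled to the feed N2 basis."""
    if offgas[INERT_GAS] <= 0:
        raise ValueError(f"inert gas {INERT_GAS} absent from off-gas")
    return offgas[gas] * feed[INERT_GAS] / offgas[INERT_GAS]


def co_consumption_rate(feed: GasFeedSpec, offgas: GasComposition) -> float:
    """CO consumption rate in mol min^-1 (positive when CO is consumed)."""
    xin = feed.composition.normalized()
    xout = offgas.normalized()
    return feed.total_molar_flow * (xin["CO"] - _balanced_out_percent(xin, xout, "CO")) / 100.0


def production_rate(gas: str, feed: GasFeedSpec, offgas: GasComposition) -> float:
    """Production rate of H2 or CO2 in mol min^-1 (positive when produced)."""
    if gas not in ("H2", "CO2"):
        raise ValueError(f"production_rate is defined for H2 and CO2, got {gas!r}")
    xin = feed.composition.normalized()
    xout = offgas.normalized()
    return feed.total_molar_flow * (_balanced_out_percent(xin, xout, gas) - xin[gas]) / 100.0


def rate_point(
    time_h: float,
    feed: GasFeedSpec,
    offgas: GasComposition,
    flag: bool = False,
) -> RatePoint:
    return RatePoint(
        time_h=time_h,
        n_co=co_consumption_rate(feed, offgas),
        n_h2=production_rate("H2", feed, offgas),
        n_co2=production_rate("CO2", feed, offgas),
        flag=flag,
    )


def rate_series(
    compositions: Sequence[tuple[float, GasComposition]],
    feed: GasFeedSpec,
    flags: Sequence[bool] | None = None,
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Pointwise rates for a time-sorted composition series.

    Returns a DataFrame with columns ``time_h, n_co_mol_min, n_h2_mol_min,
    n_co2_mol_min, flag``. ``smooth_window`` applies a centred rolling median
    to the three rate columns (off by default).
    """
    times = [t for t, _ in compositions]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("compositions must be time-sorted")
    if flags is None:
        flags = [False] * len(compositions)
    pts = [rate_point(t, feed, comp, flag) for (t, comp), flag in zip(compositions, flags)]
    df = pd.DataFrame(
        {
            "time_h": [p.time_h for p in pts],
            "n_co_mol_min": [p.n_co for p in pts],
            "n_h2_mol_min": [p.n_h2 for p in pts],
            "n_co2_mol_min": [p.n_co2 for p in pts],
            "flag": [p.flag for p in pts],
        }
    )
    if smooth_window:
        for col in ("n_co_mol_min", "n_h2_mol_min", "n_co2_mol_min"):
            df[col] = (
                df[col].rolling(smooth_window, center=True, min_periods=1).median()
            )
    return df
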