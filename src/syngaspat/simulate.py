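"""Mechanistic bioreactor simulator for *Rhodospirillum rubrum* on syngas.

Generates every data stream the analytics pipeline consumes — off-gas
compositions and QMS channel scans, OD600/CDW/TCC/mean-FL1 samples,
dissolved CO, redox potential and balance weight — for batch, fed-batch and
chemostat operation, from a deliberately minimal mechanistic model:

* Growth follows a double Monod law on residual acetate S (mM) and dissolved
  CO ``C`` (uM): ``mu = mu_max * S/(K_S+S) * C/(K_Cg+C)``; acetate is the
  carbon cosubstrate, CO the energy substrate via CO dehydrogenase.
* CO uptake ``q_CO = q_CO_max * C/(K_C+C)`` (mmol per g residual biomass per
  hour) runs the biological water-gas shift: every mole of CO oxidized with
  water yields one mole of CO2 and one of H2 (1:1:1), returned to the gas
  phase.
* Gas-liquid transfer is first order, ``kLa * (C* - C)``, with the
  saturation concentration C* set by Henry's law from the CO partial
  pressure of the feed gas.
* PHB is synthesized from acetate when acetate is available but growth
  slows: ``q_PHB = q_PHB_max * S/(K_S+S) * (1 - mu/mu_max)`` (g per g
  residual biomass per hour). Total cell dry weight is residual biomass plus
  PHB; the total cell count tracks only the residual (dividing) biomass.
* The redox potential is a monotone saturating map of dissolved CO between
  the aerobic-inoculation and fully CO-limited extremes; the instrument
  correlates with dissolved CO, it does not add independent state.

The off-gas composition follows from a quasi-steady gas balance: N2 passes
through unchanged, CO leaves the gas phase at the transfer rate, H2 and CO2
enter at the water-gas-shift rate.

Noise enters only at the instrument-emission stage
(:func:`emit_instruments`), so one ODE solution can be re-sampled under many
noise seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from . import control as ctrl
from .rates import MOLAR_VOLUME_25C_ML_MOL, GasFeedSpec
from .spectra import (
    FragmentationLibrary,
    GasComposition,
    SensitivitySet,
    synthesize_spectrum,
)

Mode = Literal["batch", "fed_batch", "chemostat"]

#: Default syngas feed composition in mol % (CO/H2/CO2/N2).
SYNGAS_PERCENTS: dict[str, float] = {"CO": 25.0, "H2": 25.0, "CO2": 5.0, "N2": 45.0}


@dataclass(frozen=True)
class NoiseModel:
    """Relative (multiplicative Gaussian) and absolute instrument noise levels."""

    qms_rel: float = 0.01
    od_rel: float = 0.02
    cdw_rel: float = 0.03
    fl1_rel: float = 0.02
    tcc_rel: float = 0.05
    dco_abs_um: float = 0.1
    redox_abs_mv: float = 3.0

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulated cultivation.

    Printed process anchors (mu_max 0.1 1/h, D 0.02 1/h, syngas 25/25/5/45,
    gassing 0.1 l l^-1 min^-1, 10 mM acetate, 0.17 mmol OD^-1 l^-1 h^-1 feed
    law) are defaults; the remaining kinetic and transfer constants are
    calibration choices documented in the methods note.
    """

    mode: Mode = "batch"
    t_end_h: float = 43.0
    sample_interval_h: float = 1.0
    seed: int = 0

    # reactor and inoculation
    volume_l: float = 2.0
    od0: float = 0.1
    od_to_cdw_g_l: float = 0.21  # g CDW per OD600 unit

    # growth / uptake kinetics
    mu_max_h: float = 0.1
    k_s_mm: float = 0.2
    k_co_growth_um: float = 2.0
    q_co_max_mmol_g_h: float = 35.0
    k_co_um: float = 2.0
    q_phb_max_g_g_h: float = 0.008
    y_xs_g_mmol: float = 0.08
    y_ps_g_mmol: float = 0.04

    # gas-liquid transfer
    kla_h: float = 50.0
    c_star_per_pct_um: float = 10.5  # Henry-law C* per mol % CO in the feed

    # gas feed
    gassing_l_l_min: float = 0.1
    feed_gas_percents: dict[str, float] = field(default_factory=lambda: dict(SYNGAS_PERCENTS))
    molar_volume_ml_mol: float = MOLAR_VOLUME_25C_ML_MOL

    # liquid phase
    s0_mm: float = 10.0
    switch_time_h: float = 43.0  # batch -> fed-batch/chemostat transition

    # fed-batch feeding
    feed_update_h: float = 12.0
    feed_coefficient: float = ctrl.FEED_COEFFICIENT_MMOL_PER_OD_L_H
    feed_stock_molarity_m: float = 2.0
    accumulation_threshold_mm: float = ctrl.ACCUMULATION_THRESHOLD_MM

    # chemostat
    dilution_rate_h: float = 0.02
    feed_acetate_mm: float = 10.0

    # redox mapping
    redox_max_mv: float = -160.0
    redox_min_mv: float = -600.0
    k_redox_um: float = 20.0

    # instrument models
    cells_per_g: float = 1.25e12
    fl1_slope_wt_per_unit: float = 0.002
    fl1_intercept_wt: float = 1.0
    fragmentation: FragmentationLibrary = field(default_factory=FragmentationLibrary.default)
    sensitivities: SensitivitySet = field(default_factory=SensitivitySet.unit)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        positive = (
            "volume_l od_to_cdw_g_l mu_max_h k_s_mm k_co_growth_um q_co_max_mmol_g_h "
            "k_co_um y_xs_g_mmol y_ps_g_mmol kla_h c_star_per_pct_um gassing_l_l_min "
            "molar_volume_ml_mol sample_interval_h t_end_h"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.od0 < 0 or self.s0_mm < 0 or self.q_phb_max_g_g_h < 0:
            raise ValueError("initial state and rates must be >= 0")

    @property
    def feed_gas(self) -> GasFeedSpec:
        return GasFeedSpec(
            flow_ml_min=self.gassing_l_l_min * self.volume_l * 1000.0,
            composition=GasComposition(self.feed_gas_percents, label="feed gas"),
            molar_volume_ml_mol=self.molar_volume_ml_mol,
        )

    @property
    def c_star_um(self) -> float:
        feed = GasComposition(self.feed_gas_percents).normalized()
        return self.c_star_per_pct_um * feed["CO"]


def batch_scenario(**overrides) -> ScenarioConfig:
    """Batch phase: 2 l, 10 mM acetate, syngas at 0.1 l l^-1 min^-1, 43 h."""
    defaults = dict(mode="batch", t_end_h=43.0)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def fed_batch_scenario(**overrides) -> ScenarioConfig:
    """Fed-batch: 10 l working volume, acetic-acid feed law after 43 h, 184 h total."""
    defaults = dict(mode="fed_batch", volume_l=10.0, t_end_h=184.0)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def chemostat_scenario(**overrides) -> ScenarioConfig:
    """Chemostat: 2 l, D = 0.02 1/h with 10 mM acetate feed after 43 h."""
    defaults = dict(mode="chemostat", volume_l=2.0, t_end_h=343.0)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@dataclass(frozen=True)
class SimulationResult:
    """Ground-truth trajectory plus the true off-gas composition series."""

    config: ScenarioConfig
    process: pd.DataFrame
    offgas: pd.DataFrame
    feed_commands: tuple[ctrl.FeedCommand, ...]

    def offgas_composition(self, row: int) -> GasComposition:
        r = self.offgas.iloc[row]
        return GasComposition(
            {g: float(r[g]) for g in ("H2", "CO", "CO2", "N2") if r[g] > 0},
            label=f"t={r['time_h']:.1f} h",
        )


def redox_potential_mv(config: ScenarioConfig, c_um: float) -> float:
    """Monotone saturating redox map of dissolved CO, bounded by the extremes."""
    span = config.redox_max_mv - config.redox_min_mv
    return config.redox_max_mv - span * config.k_redox_um / (config.k_redox_um + max(c_um, 0.0))


def _specific_rates(config: ScenarioConfig, s_mm: float, c_um: float) -> tuple[float, float, float]:
    """(mu, q_phb, q_co) from the current acetate and dissolved CO levels."""
    s = max(s_mm, 0.0)
    c = max(c_um, 0.0)
    monod_s = s / (config.k_s_mm + s)
    mu = config.mu_max_h * monod_s * c / (config.k_co_growth_um + c)
    q_phb = config.q_phb_max_g_g_h * monod_s * max(1.0 - mu / config.mu_max_h, 0.0)
    q_co = config.q_co_max_mmol_g_h * c / (config.k_co_um + c)
    return mu, q_phb, q_co


def derivatives(
    t: float,
    y: Sequence[float],
    config: ScenarioConfig,
    phase: Mode,
    feed_mmol_h: float,
) -> np.ndarray:
    """Time derivatives of the state vector ``[V, X_r, P, S, C]``.

    V in l, residual biomass X_r and PHB P in g/l, acetate S in mM, dissolved
    CO C in uM. ``phase`` is the operating phase at time t and ``feed_mmol_h``
    the current acetate feed set point (fed-batch only).
    """
    v, xr, p, s, c = y
    if v <= 0:
        raise ValueError("working volume must stay positive during integration")
    xr = max(xr, 0.0)
    p = max(p, 0.0)
    mu, q_phb, q_co = _specific_rates(config, s, c)

    dv = 0.0
    d_dil = 0.0  # dilution of concentrations, 1/h
    s_in = 0.0  # acetate supply, mM/h
    if phase == "fed_batch":
        q_in_l_h = feed_mmol_h / (config.feed_stock_molarity_m * 1000.0)
        dv = q_in_l_h
        d_dil = q_in_l_h / v
        s_in = feed_mmol_h / v
    elif phase == "chemostat":
        d_dil = config.dilution_rate_h
        s_in = config.dilution_rate_h * config.feed_acetate_mm

    q_co_vol = q_co * xr  # mmol l^-1 h^-1
    dxr = (mu - d_dil) * xr
    dp = q_phb * xr - d_dil * p
    ds = s_in - d_dil * max(s, 0.0) - mu * xr / config.y_xs_g_mmol - q_phb * xr / config.y_ps_g_mmol
    dc = config.kla_h * (config.c_star_um - c) - 1000.0 * q_co_vol - d_dil * max(c, 0.0)
    return np.array([dv, dxr, dp, ds, dc])


def _offgas_percents(config: ScenarioConfig, v: float, xr: float, c: float) -> dict[str, float]:
    """Quasi-steady off-gas mole percents from the gas balance at one state."""
    feed = config.feed_gas
    xin = feed.composition.normalized()
    n_in = feed.total_molar_flow  # mol/min
    _, _, q_co = _specific_rates(config, 1.0, c)  # acetate-independent uptake
    transfer_mol_min = config.kla_h * max(config.c_star_um - c, 0.0) * 1e-6 * v / 60.0
    shift_mol_min = q_co * max(xr, 0.0) * 1e-3 * v / 60.0
    flows = {
        "N2": n_in * xin["N2"] / 100.0,
        "CO": max(n_in * xin["CO"] / 100.0 - transfer_mol_min, 0.0),
        "H2": n_in * xin["H2"] / 100.0 + shift_mol_min,
        "CO2": n_in * xin["CO2"] / 100.0 + shift_mol_min,
    }
    total = sum(flows.values())
    return {g: 100.0 * f / total for g, f in flows.items()}


def run(config: ScenarioConfig) -> SimulationResult:
    """Integrate the scenario and return the ground-truth trajectory.

    The ODE is integrated piecewise: one segment for the batch phase and, in
    fed-batch mode, one segment per feed-adjustment interval so the feed set
    point stays constant within a segment, mirroring the operator cadence.
    """
    cfg = config
    xr0 = cfg.od0 * cfg.od_to_cdw_g_l
    y = np.array([cfg.volume_l, xr0, 0.0, cfg.s0_mm, cfg.c_star_um])

    boundaries = [0.0]
    if cfg.mode == "batch" or cfg.switch_time_h >= cfg.t_end_h:
        boundaries.append(cfg.t_end_h)
    else:
        boundaries.append(cfg.switch_time_h)
        if cfg.mode == "fed_batch":
            t = cfg.switch_time_h + cfg.feed_update_h
            while t < cfg.t_end_h:
                boundaries.append(t)
                t += cfg.feed_update_h
        boundaries.append(cfg.t_end_h)

    sample_t = np.arange(0.0, cfg.t_end_h + 1e-9, cfg.sample_interval_h)
    rows: list[dict] = []
    feed_commands: list[ctrl.FeedCommand] = []
    feed_mmol_h = 0.0
    prev_feed: float | None = None

    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        phase: Mode = "batch" if (cfg.mode == "batch" or t0 < cfg.switch_time_h) else cfg.mode
        if phase == "fed_batch":
            v, xr, p, s, c = y
            od = (xr + p) / cfg.od_to_cdw_g_l
            mu, q_phb, _ = _specific_rates(cfg, s, c)
            consumption = (mu * xr / cfg.y_xs_g_mmol + q_phb * xr / cfg.y_ps_g_mmol) * v
            cmd = ctrl.feed_rate(
                od600=od,
                volume_l=v,
                residual_acetate_mm=max(s, 0.0),
                previous_feed_mmol_h=prev_feed,
                measured_consumption_mmol_h=consumption,
                time_h=t0,
                accumulation_threshold_mm=cfg.accumulation_threshold_mm,
                coefficient=cfg.feed_coefficient,
            )
            feed_commands.append(cmd)
            feed_mmol_h = cmd.acetate_feed_mmol_h
            prev_feed = feed_mmol_h
        else:
            feed_mmol_h = 0.0

        in_segment = sample_t[(sample_t >= t0 - 1e-9) & (sample_t <= t1 + 1e-9)]
        t_eval = np.unique(np.append(in_segment, [t0, t1]))
        sol = solve_ivp(
            derivatives,
            (t0, t1),
            y,
            args=(cfg, phase, feed_mmol_h),
            method="LSODA",
            t_eval=t_eval,
            rtol=1e-8,
            atol=[1e-10, 1e-12, 1e-12, 1e-10, 1e-8],
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed in phase {phase} on [{t0}, {t1}] h: {sol.message}"
            )
        for k, t in enumerate(sol.t):
            if not np.isclose(t, in_segment, atol=1e-9).any():
                continue  # segment endpoint kept only for the state handoff
            if rows and t <= rows[-1]["time_h"] + 1e-12:
                continue
            v, xr, p, s, c = np.maximum(sol.y[:, k], 0.0)
            mu, q_phb, _ = _specific_rates(cfg, s, c)
            rows.append(
                {
                    "time_h": float(t),
                    "volume_l": v,
                    "residual_biomass_g_l": xr,
                    "phb_g_l": p,
                    "cdw_g_l": xr + p,
                    "phb_wt_pct": 100.0 * p / (xr + p) if xr + p > 0 else 0.0,
                    "acetate_mm": s,
                    "dco_um": c,
                    "redox_mv": redox_potential_mv(cfg, c),
                    "od600": (xr + p) / cfg.od_to_cdw_g_l,
                    "tcc_per_ml": xr * cfg.cells_per_g / 1000.0,
                    "mu_h": mu,
                    "feed_mmol_h": feed_mmol_h if phase == "fed_batch" else 0.0,
                    "phase": phase,
                }
            )
        y = sol.y[:, -1]

    process = pd.DataFrame(rows)
    off_rows = []
    for r in rows:
        pct = _offgas_percents(cfg, r["volume_l"], r["residual_biomass_g_l"], r["dco_um"])
        off_rows.append({"time_h": r["time_h"], **pct})
    offgas = pd.DataFrame(off_rows)
    return SimulationResult(cfg, process, offgas, tuple(feed_commands))


@dataclass(frozen=True)
class InstrumentStreams:
    """Noisy instrument emissions for one simulated run (deterministic per seed)."""

    qms: pd.DataFrame  # long format: time_h, mz, intensity
    process: pd.DataFrame  # time_h, od600, cdw_g_l, dco_um, redox_mv, balance_g
    fcm: pd.DataFrame  # time_h, mean_fl1, tcc_per_ml
    truth: pd.DataFrame  # ground-truth process merged with true off-gas


def emit_instruments(result: SimulationResult, seed: int | None = None) -> InstrumentStreams:
    """Sample every instrument channel from a trajectory, adding configured noise.

    QMS intensities are the linear response of the configured fragmentation
    library and sensitivities to the true off-gas composition, with
    multiplicative Gaussian channel noise. The same seed always reproduces
    the same streams bit for bit.
    """
    cfg = result.config
    noise = cfg.noise
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    def jitter_rel(values: np.ndarray, rel: float) -> np.ndarray:
        if rel == 0:
            return values.copy()
        return np.maximum(values * (1.0 + rel * rng.standard_normal(len(values))), 0.0)

    proc = result.process
    qms_rows = []
    for i in range(len(result.offgas)):
        comp = result.offgas_composition(i)
        spectrum = synthesize_spectrum(comp, cfg.fragmentation, cfg.sensitivities)
        t = float(result.offgas["time_h"].iloc[i])
        for mz in sorted(spectrum.intensities):
            val = spectrum.intensities[mz]
            if noise.qms_rel:
                val = max(val * (1.0 + noise.qms_rel * rng.standard_normal()), 0.0)
            qms_rows.append({"time_h": t, "mz": mz, "intensity": val})
    qms = pd.DataFrame(qms_rows)

    process = pd.DataFrame(
        {
            "time_h": proc["time_h"],
            "od600": jitter_rel(proc["od600"].to_numpy(), noise.od_rel),
            "cdw_g_l": jitter_rel(proc["cdw_g_l"].to_numpy(), noise.cdw_rel),
            "dco_um": np.maximum(
                proc["dco_um"].to_numpy()
                + noise.dco_abs_um * rng.standard_normal(len(proc)),
                0.0,
            ),
            "redox_mv": proc["redox_mv"].to_numpy()
            + noise.redox_abs_mv * rng.standard_normal(len(proc)),
            "balance_g": proc["volume_l"].to_numpy() * 1000.0,
        }
    )

    fl1_true = np.maximum(
        (proc["phb_wt_pct"].to_numpy() - cfg.fl1_intercept_wt) / cfg.fl1_slope_wt_per_unit,
        0.0,
    )
    fcm = pd.DataFrame(
        {
            "time_h": proc["time_h"],
            "mean_fl1": jitter_rel(fl1_true, noise.fl1_rel),
            "tcc_per_ml": jitter_rel(proc["tcc_per_ml"].to_numpy(), noise.tcc_rel),
        }
    )

    truth = proc.merge(result.offgas, on="time_h", suffixes=("", "_offgas"))
    return InstrumentStreams(qms=qms, process=process, fcm=fcm, truth=truth)


def fit_exponential_growth_rate(
    times_h: Sequence[float],
    od600: Sequence[float],
    window_h: tuple[float, float] = (2.0, 20.0),
) -> float:
    """Maximum specific growth rate (1/h) by log-linear regression of OD600.

    The default window covers the part of the batch phase where both acetate
    and dissolved CO are far above their half-saturation constants, so the
    slope of ln(OD) estimates mu_max.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    mask = (t >= window_h[0]) & (t <= window_h[1]) & (od > 0)
    if mask.sum() < 3:
        raise ValueError("growth-rate window contains fewer than 3 usable points")
    res = stats.linregress(t[mask], np.log(od[mask]))
    return float(res.slope)


def chemostat_steady_growth_rate(result: SimulationResult, window_h: float = 20.0) -> float:
    """Steady-state specific growth rate mu = d ln X / dt + D from the tail of a run.

    In a chemostat at steady state the biomass balance forces mu to equal the
    dilution rate; this measures it from the trajectory rather than assuming it.
    """
    cfg = result.config
    if cfg.mode != "chemostat":
        raise ValueError("steady-state growth rate is defined for chemostat runs")
    proc = result.process
    t_last = proc["time_h"].iloc[-1]
    tail = proc[proc["time_h"] >= t_last - window_h]
    res = stats.linregress(tail["time_h"], np.log(tail["residual_biomass_g_l"]))
    return float(res.slope + cfg.dilution_rate_h)
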