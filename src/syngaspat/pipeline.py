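"""End-to-end soft-sensor pipeline: simulate -> deconvolve -> rates -> PHB -> report.

Mirrors the monitoring loop of the physical platform: the simulator stands in
for the reactor and its instruments, the deconvolution and balancing stages
are exactly the ones a real QMS data stream would pass through, and the
recovery metrics compare the reconstructed process quantities with the
simulator's ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .phbcal import apply_calibration, fit_calibration
from .rates import rate_series
from .simulate import ScenarioConfig, SimulationResult, emit_instruments, run
from .spectra import ChannelSpectrum, deconvolve


@dataclass(frozen=True)
class PipelineReport:
    """All artifacts of one pipeline run plus truth-recovery metrics."""

    result: SimulationResult
    compositions: list[tuple[float, object, float]]
    rates: pd.DataFrame
    phb: pd.DataFrame
    recovery: dict[str, float]


def pipeline_run(
    config: ScenarioConfig,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Run the full monitoring loop on one simulated scenario.

    Steps: simulate the reactor, emit noisy instrument streams, deconvolve
    every QMS scan back to a gas composition, balance the inert gas to get
    CO/H2/CO2 rates, fit the FL1->PHB calibration on the GC-reference subset
    and apply it to the FCM stream, and score everything against the truth.
    When ``outdir`` is given, all streams plus a run manifest are written as
    CSV/JSON.
    """
    cfg = config if seed is None else dataclasses.replace(config, seed=seed)
    result = run(cfg)
    streams = emit_instruments(result, seed=cfg.seed)

    comps = []
    for t, group in streams.qms.groupby("time_h", sort=True):
        scan = ChannelSpectrum(
            {int(r.mz): float(r.intensity) for r in group.itertuples()}, timestamp=float(t)
        )
        dec = deconvolve(scan, cfg.fragmentation, cfg.sensitivities)
        comps.append((float(t), dec.composition, dec.relative_residual))

    flags = [res > 0.05 for _, _, res in comps]
    rates = rate_series([(t, c) for t, c, _ in comps], cfg.feed_gas, flags=flags)

    # Calibrate FL1 -> PHB on a sparse "GC reference" subset (every 6th sample,
    # as GC assays are much sparser than FCM), then apply to the whole stream.
    truth = streams.truth
    fcm = streams.fcm
    ref_idx = [i for i in range(0, len(fcm), 6) if truth["phb_wt_pct"].iloc[i] > 0]
    pairs = [
        (float(fcm["mean_fl1"].iloc[i]), float(truth["phb_wt_pct"].iloc[i])) for i in ref_idx
    ]
    phb_rows = []
    cal = None
    if len(pairs) >= 3 and np.ptp([p[0] for p in pairs]) > 0:
        cal = fit_calibration(pairs)
        for i in range(len(fcm)):
            est = apply_calibration(cal, float(fcm["mean_fl1"].iloc[i]))
            phb_rows.append(
                {
                    "time_h": float(fcm["time_h"].iloc[i]),
                    "phb_wt_pct": est.phb_wt_pct,
                    "extrapolated": est.extrapolated,
                    "low_content": est.low_content,
                }
            )
    phb = pd.DataFrame(phb_rows, columns=["time_h", "phb_wt_pct", "extrapolated", "low_content"])

    recovery = _recovery_metrics(result, comps, rates, phb)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        streams.qms.to_csv(outdir / "qms_scans.csv", index=False)
        streams.process.to_csv(outdir / "process.csv", index=False)
        streams.fcm.to_csv(outdir / "fcm.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
        sio.write_compositions(comps, outdir / "offgas_compositions.csv")
        rates.to_csv(outdir / "rates.csv", index=False)
        phb.to_csv(outdir / "phb.csv", index=False)
        if cal is not None:
            sio.write_calibration(cal, outdir / "phb_calibration.json")
        manifest = sio.RunManifest(
            config_hash=sio.RunManifest.hash_config(cfg),
            seed=cfg.seed,
            package_version=_package_version(),
            inputs=(),
            outputs=tuple(
                str(outdir / n)
                for n in (
                    "qms_scans.csv process.csv fcm.csv truth.csv "
                    "offgas_compositions.csv rates.csv phb.csv".split()
                )
            ),
        )
        sio.write_manifest(manifest, outdir / "manifest.json")
        pd.DataFrame([recovery]).to_csv(outdir / "recovery.csv", index=False)

    return PipelineReport(result, comps, rates, phb, recovery)


def _recovery_metrics(result, comps, rates, phb) -> dict[str, float]:
    """Relative errors of the reconstructed streams against the ground truth."""
    truth = result.offgas.set_index("time_h")
    errs = []
    for t, comp, _ in comps:
        true_row = truth.loc[t]
        for g in ("H2", "CO", "CO2", "N2"):
            if true_row[g] > 0:
                errs.append(abs(comp[g] - true_row[g]) / true_row[g])
    metrics = {"offgas_max_rel_err": float(max(errs)) if errs else float("nan")}

    # CO rate recovery over the quasi-steady tail (last quarter of the run),
    # comparing window means so i.i.d. channel noise averages out.
    cfg = result.config
    feed = cfg.feed_gas
    xin = feed.composition.normalized()
    n_in = feed.total_molar_flow
    truth_rates = []
    for _, r in result.offgas.iterrows():
        out = {g: r[g] for g in ("H2", "CO", "CO2", "N2")}
        truth_rates.append(n_in * (xin["CO"] - out["CO"] * xin["N2"] / out["N2"]) / 100.0)
    truth_rates = np.asarray(truth_rates)
    est = rates["n_co_mol_min"].to_numpy()
    tail = slice(3 * len(est) // 4, None)
    if np.mean(truth_rates[tail]) > 0:
        metrics["n_co_tail_rel_err"] = float(
            abs(np.mean(est[tail]) - np.mean(truth_rates[tail])) / np.mean(truth_rates[tail])
        )
    if len(phb):
        true_phb = result.process["phb_wt_pct"].to_numpy()
        est_phb = phb["phb_wt_pct"].to_numpy()
        mask = true_phb > 1.0
        if mask.any():
            metrics["phb_max_abs_err_wt"] = float(np.max(np.abs(est_phb[mask] - true_phb[mask])))
    return metrics


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("syngaspat")
    except Exception:
        return "unknown"
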