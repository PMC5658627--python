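"""CSV and config readers/writers plus run manifests.

All tabular streams are long-format, comma-separated CSV with a mandatory
header row and dot decimals; times are hours since inoculation and gases are
named by the fixed uppercase tokens H2, CO, CO2, N2, H2O, O2, AR.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .phbcal import PHBCalibration
from .spectra import ChannelSpectrum, FragmentationLibrary, GasComposition, SensitivitySet


class FormatError(ValueError):
    """Raised for malformed or empty input files, with row context where possible."""


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: no records (empty file)")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in required:
        if col in ("gas", "phase"):
            continue
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            raise FormatError(f"{path}: malformed value in column {col!r} at line {bad.idxmax() + 2}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_scans(scans: Sequence[tuple[float, ChannelSpectrum]], path: str | Path) -> None:
    rows = [
        {"time_h": t, "mz": mz, "intensity": i}
        for t, scan in scans
        for mz, i in sorted(scan.intensities.items())
    ]
    pd.DataFrame(rows, columns=["time_h", "mz", "intensity"]).to_csv(path, index=False)


def read_scans(path: str | Path) -> list[tuple[float, ChannelSpectrum]]:
    """Read a long-format QMS scan series (time_h, mz, intensity)."""
    df = _read_csv(path, ["time_h", "mz", "intensity"])
    out = []
    for t, group in df.groupby("time_h", sort=True):
        out.append(
            (float(t), ChannelSpectrum({int(r.mz): float(r.intensity) for r in group.itertuples()}, timestamp=float(t)))
        )
    return out


def write_compositions(
    series: Sequence[tuple[float, GasComposition, float]], path: str | Path
) -> None:
    """Write (time, composition, residual) triples as time_h, gas, mole_percent, residual."""
    rows = [
        {"time_h": t, "gas": g, "mole_percent": comp[g], "residual": res}
        for t, comp, res in series
        for g in comp.gases
    ]
    pd.DataFrame(rows, columns=["time_h", "gas", "mole_percent", "residual"]).to_csv(path, index=False)


def read_compositions(path: str | Path) -> list[tuple[float, GasComposition, float]]:
    df = _read_csv(path, ["time_h", "gas", "mole_percent"])
    out = []
    for t, group in df.groupby("time_h", sort=True):
        comp = GasComposition({r.gas: float(r.mole_percent) for r in group.itertuples()})
        res = float(group["residual"].iloc[0]) if "residual" in group else 0.0
        out.append((float(t), comp, res))
    return out


def read_library(path: str | Path) -> FragmentationLibrary:
    """YAML fragmentation library: {gas: {mz: abundance, ...}, ...}."""
    data = yaml.safe_load(Path(path).read_text())
    if not data:
        raise FormatError(f"{path}: no records")
    return FragmentationLibrary({g: {int(m): float(a) for m, a in pat.items()} for g, pat in data.items()})


def write_library(lib: FragmentationLibrary, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({g: dict(p) for g, p in lib.fragments.items()}))


def read_sensitivities(path: str | Path) -> SensitivitySet:
    """YAML sensitivity set: {gas: sensitivity, ...}, N2-normalized."""
    data = yaml.safe_load(Path(path).read_text())
    if not data:
        raise FormatError(f"{path}: no records")
    return SensitivitySet.normalized({g: float(s) for g, s in data.items()}, reference=str(path))


def write_sensitivities(sens: SensitivitySet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(sens.values)))


def write_calibration(cal: PHBCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cal), indent=2))


def read_calibration(path: str | Path) -> PHBCalibration:
    data = json.loads(Path(path).read_text())
    return PHBCalibration(**data)


def read_process(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["time_h"])


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written alongside every pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    @staticmethod
    def hash_config(config: object) -> str:
        """Stable SHA-256 over a dataclass/dict config (timestamps excluded)."""
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            payload = dataclasses.asdict(config)
        else:
            payload = config
        blob = json.dumps(payload, sort_keys=True, default=repr).encode()
        return hashlib.sha256(blob).hexdigest()


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2))


def read_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    data["inputs"] = tuple(data["inputs"])
    data["outputs"] = tuple(data["outputs"])
    return RunManifest(**data)
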