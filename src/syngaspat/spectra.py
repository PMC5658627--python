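"""Gas-mixture deconvolution for quadrupole-MS off-gas analysis.

A quadrupole mass spectrometer reports one ion current per mass-to-charge
channel. The gases relevant to syngas fermentation overlap heavily — CO, N2
and a CO2 fragment all contribute at m/z 28 — so mole fractions cannot be
read off single channels. Each gas ``g`` is instead modelled as a fixed
electron-ionization fragmentation pattern ``f(g, m)`` (principal peak scaled
to 1.0) times a dimensionless response factor ``s_g`` normalized to N2,
giving the linear model

    y_m = sum_g  s_g * f(g, m) * x_g

for the background-subtracted ion current ``y_m`` at channel ``m``, where
``x_g`` is proportional to the mole fraction of gas ``g``. Compositions are
recovered by non-negative least squares on that model and renormalized to
100 mol %; the residual norm is kept as a diagnostic rather than being
absorbed by the normalization.

Intensity units are arbitrary: they cancel through the N2 normalization of
the response factors, so no absolute-pressure model is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

#: Canonical gas tokens, also the documented column order of response matrices.
GASES: tuple[str, ...] = ("H2", "CO", "CO2", "N2", "H2O", "O2", "AR")

#: The inert reference gas used for calibration normalization and rate balances.
INERT_GAS = "N2"

# Default 70 eV electron-ionization fragmentation patterns (relative
# abundances, principal peak = 1.0). These are configurable defaults for a
# generic quadrupole at standard settings, not a claim about any particular
# instrument: real instruments require patterns measured under their own
# analysis settings.
DEFAULT_FRAGMENTS: dict[str, dict[int, float]] = {
    "H2": {2: 1.0, 1: 0.02},
    "CO": {28: 1.0, 12: 0.045, 16: 0.017},
    "CO2": {44: 1.0, 28: 0.11, 16: 0.085, 12: 0.06, 22: 0.019},
    "N2": {28: 1.0, 14: 0.072, 29: 0.0074},
    "H2O": {18: 1.0, 17: 0.23},
    "O2": {32: 1.0, 16: 0.11},
    "AR": {40: 1.0, 20: 0.12},
}

#: Dry-air composition (mol %) used for ambient-air calibration references.
DRY_AIR_PERCENTS: dict[str, float] = {
    "N2": 78.084,
    "O2": 20.946,
    "AR": 0.934,
    "CO2": 0.036,
}


class ConfigurationError(ValueError):
    """Raised when a library / sensitivity / channel configuration is inconsistent."""


@dataclass(frozen=True)
class ChannelSpectrum:
    """One QMS scan: mass-to-charge channel -> ion current (arbitrary units).

    Parameters
    ----------
    intensities
        Mapping of integer m/z (amu/e) to non-negative ion current.
    timestamp
        Hours since inoculation, if the scan belongs to a time series.
    """

    intensities: Mapping[int, float]
    timestamp: float | None = None

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for mz, val in self.intensities.items():
            if int(mz) != mz or mz <= 0:
                raise ValueError(f"m/z channels must be positive integers, got {mz!r}")
            v = float(val)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"intensity at m/z {mz} must be finite and >= 0, got {val!r}")
            clean[int(mz)] = v
        object.__setattr__(self, "intensities", clean)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted(self.intensities))

    def total(self) -> float:
        return float(sum(self.intensities.values()))


@dataclass(frozen=True)
class FragmentationLibrary:
    """Per-gas fragmentation patterns: gas -> {m/z -> relative abundance}.

    Every gas must have exactly one principal channel with abundance 1.0 and
    all abundances in (0, 1].
    """

    fragments: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[int, float]] = {}
        for gas, pattern in self.fragments.items():
            if not pattern:
                raise ConfigurationError(f"gas {gas} has an empty fragmentation pattern")
            pat: dict[int, float] = {}
            for mz, ab in pattern.items():
                if int(mz) != mz or mz <= 0:
                    raise ConfigurationError(f"bad m/z {mz!r} for gas {gas}")
                a = float(ab)
                if not 0.0 < a <= 1.0:
                    raise ConfigurationError(
                        f"abundance for {gas} at m/z {mz} must be in (0, 1], got {ab!r}"
                    )
                pat[int(mz)] = a
            if sum(1 for a in pat.values() if a == 1.0) != 1:
                raise ConfigurationError(
                    f"gas {gas} must have exactly one principal peak with abundance 1.0"
                )
            clean[gas] = pat
        object.__setattr__(self, "fragments", clean)

    @property
    def gases(self) -> tuple[str, ...]:
        return tuple(g for g in GASES if g in self.fragments) + tuple(
            sorted(g for g in self.fragments if g not in GASES)
        )

    @property
    def channel_union(self) -> tuple[int, ...]:
        chans: set[int] = set()
        for pattern in self.fragments.values():
            chans.update(pattern)
        return tuple(sorted(chans))

    def abundance(self, gas: str, mz: int) -> float:
        return float(self.fragments.get(gas, {}).get(mz, 0.0))

    @classmethod
    def default(cls) -> "FragmentationLibrary":
        return cls(DEFAULT_FRAGMENTS)


@dataclass(frozen=True)
class SensitivitySet:
    """N2-normalized response factors per gas (dimensionless, s_N2 = 1 exactly)."""

    values: Mapping[str, float]
    reference: str = ""

    def __post_init__(self) -> None:
        clean = {g: float(s) for g, s in self.values.items()}
        for gas, s in clean.items():
            if not math.isfinite(s) or s <= 0:
                raise ConfigurationError(f"sensitivity for {gas} must be > 0, got {s!r}")
        if INERT_GAS in clean and clean[INERT_GAS] != 1.0:
            raise ConfigurationError(
                f"s_{INERT_GAS} must be exactly 1.0 (got {clean[INERT_GAS]!r}); "
                "use SensitivitySet.normalized() to rescale"
            )
        object.__setattr__(self, "values", clean)

    @classmethod
    def normalized(cls, raw: Mapping[str, float], reference: str = "") -> "SensitivitySet":
        """Rescale raw responses so that the N2 entry is exactly 1."""
        if INERT_GAS not in raw or raw[INERT_GAS] <= 0:
            raise ConfigurationError(f"{INERT_GAS} response required for normalization")
        ref = float(raw[INERT_GAS])
        return cls({g: float(s) / ref for g, s in raw.items()}, reference=reference)

    @classmethod
    def unit(cls, gases: Iterable[str] = GASES) -> "SensitivitySet":
        return cls({g: 1.0 for g in gases}, reference="unit sensitivities")

    @property
    def gases(self) -> tuple[str, ...]:
        return tuple(g for g in GASES if g in self.values) + tuple(
            sorted(g for g in self.values if g not in GASES)
        )

    def __getitem__(self, gas: str) -> float:
        return self.values[gas]


@dataclass(frozen=True)
class GasComposition:
    """Mole-percent vector over a set of gases, summing to 100 after normalization."""

    percents: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        clean = {g: float(x) for g, x in self.percents.items()}
        for gas, x in clean.items():
            if not math.isfinite(x) or x < 0:
                raise ValueError(f"mole percent of {gas} must be finite and >= 0, got {x!r}")
        if not clean or sum(clean.values()) <= 0:
            raise ValueError("composition must contain at least one positive mole percent")
        object.__setattr__(self, "percents", clean)

    @property
    def gases(self) -> tuple[str, ...]:
        return tuple(g for g in GASES if g in self.percents) + tuple(
            sorted(g for g in self.percents if g not in GASES)
        )

    def __getitem__(self, gas: str) -> float:
        return float(self.percents.get(gas, 0.0))

    def normalized(self) -> "GasComposition":
        total = sum(self.percents.values())
        return GasComposition({g: 100.0 * x / total for g, x in self.percents.items()}, self.label)

    def vector(self, gases: Sequence[str]) -> np.ndarray:
        return np.array([self[g] for g in gases], dtype=float)

    def total(self) -> float:
        return float(sum(self.percents.values()))


@dataclass(frozen=True)
class BackgroundProfile:
    """Per-channel background ion currents, measured while flushing with pure Ar."""

    levels: Mapping[int, float]

    def __post_init__(self) -> None:
        clean = {}
        for mz, v in self.levels.items():
            if float(v) < 0:
                raise ValueError(f"background at m/z {mz} must be >= 0")
            clean[int(mz)] = float(v)
        object.__setattr__(self, "levels", clean)


@dataclass(frozen=True)
class AmbientConditions:
    """Room conditions used to compute the water content of ambient calibration air."""

    temperature_c: float
    pressure_kpa: float = 101.325
    relative_humidity: float = 0.5

    def __post_init__(self) -> None:
        if not -30.0 < self.temperature_c < 60.0:
            raise ValueError("temperature out of plausible indoor range (-30, 60) C")
        if not 80.0 < self.pressure_kpa < 110.0:
            raise ValueError("pressure out of plausible range (80, 110) kPa")
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError("relative humidity must be in [0, 1]")


@dataclass(frozen=True)
class DeconvolutionResult:
    """Deconvolved composition plus least-squares diagnostics."""

    composition: GasComposition
    relative_residual: float
    residual_flag: bool
    channels: tuple[int, ...]


@dataclass(frozen=True)
class AccuracyReport:
    """Per-gas errors of a measured composition against a known one."""

    relative_errors: Mapping[str, float]
    absolute_errors: Mapping[str, float]
    threshold: float
    passed: bool

    @property
    def max_relative_error(self) -> float:
        return max(self.relative_errors.values(), default=0.0)


def gas_order(sens: SensitivitySet, lib: FragmentationLibrary) -> tuple[str, ...]:
    """Documented column order: canonical GASES order restricted to calibrated gases."""
    return tuple(g for g in sens.gases if g in lib.fragments)


def response_matrix(
    lib: FragmentationLibrary,
    sens: SensitivitySet,
    channels: Sequence[int],
    gases: Sequence[str] | None = None,
) -> np.ndarray:
    """Channels x gases linear response matrix, entry (m, g) = s_g * f(g, m).

    Column order follows ``gases`` (default: :func:`gas_order`).
    """
    if len(channels) == 0:
        raise ValueError("channel list must be non-empty")
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channels in channel list")
    if gases is None:
        gases = sens.gases
    for g in gases:
        if g not in lib.fragments:
            raise ConfigurationError(f"gas {g} missing from fragmentation library")
        if g not in sens.values:
            raise ConfigurationError(f"gas {g} missing from sensitivity set")
    A = np.zeros((len(channels), len(gases)))
    for i, mz in enumerate(channels):
        for j, g in enumerate(gases):
            A[i, j] = sens[g] * lib.abundance(g, mz)
    return A


def subtract_background(scan: ChannelSpectrum, bg: BackgroundProfile) -> ChannelSpectrum:
    """Subtract per-channel background, clipping at zero; unknown channels pass through."""
    out = {
        mz: max(val - bg.levels.get(mz, 0.0), 0.0) for mz, val in scan.intensities.items()
    }
    return ChannelSpectrum(out, timestamp=scan.timestamp)


def synthesize_spectrum(
    composition: GasComposition,
    lib: FragmentationLibrary,
    sens: SensitivitySet,
    channels: Sequence[int] | None = None,
    scale: float = 1.0,
    timestamp: float | None = None,
) -> ChannelSpectrum:
    """Forward model: noise-free channel intensities for a known composition.

    The inverse of :func:`deconvolve` up to the arbitrary overall ``scale``.
    """
    comp = composition.normalized()
    gases = tuple(g for g in gas_order(sens, lib) if g in comp.percents or comp[g] > 0)
    if channels is None:
        channels = lib.channel_union
    A = response_matrix(lib, sens, channels, gases)
    y = scale * (A @ (comp.vector(gases) / 100.0))
    return ChannelSpectrum(dict(zip((int(m) for m in channels), y)), timestamp=timestamp)


def deconvolve(
    scan: ChannelSpectrum,
    lib: FragmentationLibrary,
    sens: SensitivitySet,
    gases: Sequence[str] | None = None,
    residual_threshold: float = 0.05,
) -> DeconvolutionResult:
    """Recover a mole-percent composition from a background-subtracted scan.

    Solves ``min ||A c - y||_2, c >= 0`` by NNLS, then renormalizes ``c`` to
    100 mol %. A relative residual above ``residual_threshold`` sets a warning
    flag in the diagnostics (it does not raise): elevated residuals indicate a
    drifting background, an uncalibrated gas, or saturated channels.
    """
    if gases is None:
        gases = gas_order(sens, lib)
    union = set(lib.channel_union)
    usable = [mz for mz in scan.channels if mz in union]
    orphans = [mz for mz in scan.channels if mz not in union]
    if orphans:
        warnings.warn(
            f"ignoring channels with no library entry for any gas: {orphans}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("empty spectrum: no usable channels")
    y = np.array([scan.intensities[mz] for mz in usable])
    if not np.any(y > 0):
        raise ValueError("empty spectrum: all usable intensities are zero")
    A = response_matrix(lib, sens, usable, gases)
    if np.linalg.matrix_rank(A) < len(gases):
        raise ConfigurationError(
            "response matrix is rank deficient on the scanned channels; "
            "add channels or drop gases"
        )
    c, rnorm = nnls(A, y)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty spectrum: non-negative fit is identically zero")
    percents = {g: 100.0 * ci / total for g, ci in zip(gases, c)}
    rel = float(rnorm / np.linalg.norm(y))
    return DeconvolutionResult(
        composition=GasComposition(percents, label=f"deconvolved t={scan.timestamp}"),
        relative_residual=rel,
        residual_flag=rel > residual_threshold,
        channels=tuple(usable),
    )


def calibrate_sensitivities(
    references: Sequence[tuple[ChannelSpectrum, GasComposition]],
    lib: FragmentationLibrary,
    gases: Sequence[str] | None = None,
) -> SensitivitySet:
    """Estimate N2-normalized response factors from reference-gas scans.

    Each reference pairs a (background-subtracted) scan with its known
    composition; the model ``y_m = k * sum_g f(g, m) * (X_g / 100) * s_g`` is
    linear in ``k * s_g``, assuming all references share the instrument's
    intensity scale ``k``, which then cancels in the N2 normalization. Every
    calibrated gas must appear with a nonzero percent in at least one
    reference, and N2 in every reference.
    """
    if not references:
        raise ValueError("at least one reference scan is required")
    if gases is None:
        gases = tuple(g for g in GASES if g in lib.fragments)
    for _, comp in references:
        if comp[INERT_GAS] <= 0:
            raise ValueError(f"{INERT_GAS} must be present in every calibration reference")
    for g in gases:
        if all(comp[g] == 0 for _, comp in references):
            raise ValueError(f"gas {g} never observed in any calibration reference")
    rows: list[np.ndarray] = []
    ys: list[float] = []
    for scan, comp in references:
        comp = comp.normalized()
        for mz in scan.channels:
            row = np.array([lib.abundance(g, mz) * comp[g] / 100.0 for g in gases])
            if row.any() or scan.intensities[mz] > 0:
                rows.append(row)
                ys.append(scan.intensities[mz])
    M = np.vstack(rows)
    if np.linalg.matrix_rank(M) < len(gases):
        raise ValueError("singular calibration design: reference scans do not span all gases")
    u, _ = nnls(M, np.asarray(ys))
    raw = dict(zip(gases, u))
    if raw.get(INERT_GAS, 0.0) <= 0:
        raise ValueError(f"calibration produced a zero {INERT_GAS} response")
    return SensitivitySet.normalized(raw, reference=f"fit from {len(references)} reference scans")


def buck_vapour_pressure_kpa(temperature_c: float) -> float:
    """Arden Buck (1981) saturation vapour pressure over liquid water, in kPa."""
    t = temperature_c
    return 0.61121 * math.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def humid_air_composition(amb: AmbientConditions, dry_air: GasComposition | None = None) -> GasComposition:
    """Ambient-air composition with the water fraction from room T, P and RH.

    Water mole percent is ``100 * RH * e_s(T) / P`` with ``e_s`` the Buck
    saturation vapour pressure; the dry percents are rescaled so the result
    sums to 100.
    """
    if dry_air is None:
        dry_air = GasComposition(DRY_AIR_PERCENTS, label="dry air")
    if dry_air["H2O"] != 0:
        raise ValueError("dry_air must have zero H2O content")
    dry = dry_air.normalized()
    e = amb.relative_humidity * buck_vapour_pressure_kpa(amb.temperature_c)
    if e >= amb.pressure_kpa:
        raise ValueError("water partial pressure exceeds total pressure")
    x_h2o = 100.0 * e / amb.pressure_kpa
    out = {g: x * (100.0 - x_h2o) / 100.0 for g, x in dry.percents.items()}
    out["H2O"] = x_h2o
    return GasComposition(out, label=f"humid air RH={amb.relative_humidity:g}")


def verify_accuracy(
    known: GasComposition,
    measured: GasComposition,
    threshold: float = 0.08,
) -> AccuracyReport:
    """Per-gas relative errors of ``measured`` against ``known`` plus a pass/fail gate.

    Gases absent from the known mixture are reported as absolute mole-percent
    errors and excluded from the relative gate.
    """
    known = known.normalized()
    measured = measured.normalized()
    rel: dict[str, float] = {}
    absolute: dict[str, float] = {}
    for g in known.gases:
        if known[g] > 0:
            rel[g] = abs(measured[g] - known[g]) / known[g]
        else:
            absolute[g] = abs(measured[g])
    passed = max(rel.values(), default=0.0) <= threshold
    return AccuracyReport(rel, absolute, threshold, passed)
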