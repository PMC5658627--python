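# Methods

This note documents the models, numerical choices and limitations behind
`syngaspat`: the QMS deconvolution, the inert-gas rate balance, the PHB
calibration, the control rules, and the mechanistic simulator that
generates all synthetic data.

## QMS off-gas deconvolution

**Model.** Under electron ionization at fixed instrument settings each gas
produces a fixed set of m/z fragments with fixed relative abundances
(principal peak ≡ 1). The background-subtracted ion current at channel *m*
is modelled as linear in the gas content:

    y_m = Σ_g s_g · f(g, m) · x_g

with *f* the fragmentation pattern and *s_g* a dimensionless per-gas
response factor normalized so that *s_N2* = 1 exactly. Intensity units are
arbitrary and cancel through that normalization; no absolute-pressure model
is attempted.

**Default fragmentation library.** The shipped defaults are representative
70 eV abundances for H2, CO, CO2, N2, H2O, O2 and Ar (e.g. CO: 28 → 1.0,
12 → 0.045, 16 → 0.017; N2: 28 → 1.0, 14 → 0.072, 29 → 0.0074). They are
configurable defaults, not instrument truth: a real quadrupole's patterns
depend on its voltage, emission and energy settings and must be measured on
the instrument itself. Every test and synthetic dataset is generated from
whatever library is configured, so nothing downstream depends on these
particular numbers. The m/z 29 entry for N2 (¹⁵N¹⁴N isotopologue) is
included so the standard channel set contains no channel that is blank for
every gas.

**Solver.** Compositions are recovered by non-negative least squares
(`scipy.optimize.nnls`) on the full channel set: NNLS enforces the physical
constraint *x_g ≥ 0* and is deterministic. The solution is renormalized to
100 mol % *after* solving, so the residual norm survives as a diagnostic —
an elevated relative residual (default threshold 0.05) flags background
drift, an uncalibrated gas or saturation, without raising. Channels with no
library entry for any gas are ignored with a warning. Degenerate inputs
(all-zero scans, rank-deficient channel sets) raise immediately.

**Calibration.** Response factors are fitted by NNLS from reference scans
with known compositions, assuming all references share the instrument's
intensity scale; the common scale cancels when the result is renormalized
to N2, which must be present in every reference (it is in all three
standard references: ambient air, a CO2/O2/N2 cylinder, syngas). The water
content of ambient air is computed from room temperature, pressure and
relative humidity with the Arden Buck (1981) over-water saturation
vapour-pressure formula — the variant choice matters only in the third
decimal of the water percent.

## Inert-gas-balanced rates

N2 passes through the reactor unreacted, so the outlet molar flow is
`F_out = F_G · X_N2_in / X_N2_out` and per-gas rates follow from mole
bookkeeping. The implementation uses the algebraically identical one-line
form (README); a property test checks equality with the explicit outlet-flow
bookkeeping to machine precision. Consumption (CO) and production (H2,
CO2) are both reported as positive numbers during normal operation — the
orientation is chosen per gas so plotted rates are positive magnitudes.
Compositions are renormalized to 100 % before balancing so deconvolution
residuals cannot leak into the rates. Gas flow is assumed pre-normalized by
the mass-flow controllers; the default molar volume is the ideal gas at
25 °C and 1 atm (24465 ml mol⁻¹ — the operating temperature is stated
upstream of the package, the pressure is an assumption).

## PHB calibration

Ordinary least squares on (mean FL1, PHB wt% by GC) pairs; R² is reported
from the fit. Predictions are clipped at 0 wt% (physical floor) and
flagged rather than refused outside the fitted FL1 range — continuous
cultures are routinely evaluated below the fed-batch calibration range, so
refusing extrapolation would make the calibration useless in its main
application. A second flag marks predictions below 5 wt%, where the
intercept contributes a non-negligible offset; fitting emits a warning when
the intercept magnitude exceeds 2 wt%. Stationary-phase staining
differences are not corrected; they can be emulated as a bias on the
simulator's FL1 channel.

## Control rules

* **Feed law:** acetate feed = 0.17 mmol OD600⁻¹ l⁻¹ h⁻¹ × OD × V while
  residual acetate stays at or below 0.5 mM. The 0.5 mM accumulation
  threshold is this package's operationalization of "acetate begins to
  accumulate" — roughly the HPLC quantification limit and well below the
  10 mM batch level. Once accumulating, the feed is capped at
  min(previous set point, measured consumption rate); `reduced` when the
  consumption estimate binds, `hold` otherwise. The adjustment cadence
  (default 12 h, i.e. twice daily) is a scheduler option.
* **Alarms:** warn at CO ≥ 100 ppm or H2 ≥ 0.8 vol%; valve shutdown at
  CO ≥ 150 ppm, H2 ≥ 1.6 vol%, power loss or emergency switch. A shutdown
  latches: it persists through recovered readings until an operator reset,
  and the reset itself is refused while any reading is at or above level 1.
  Latching semantics are a deliberate safety choice — a transient reading
  must not silently re-open gas valves.
* Only the decision logic is modelled; detectors, electrovalves and hoods
  are hardware outside the package's scope.

## Simulator

**State.** V (l), residual biomass X_r (g l⁻¹), PHB P (g l⁻¹), acetate S
(mM), dissolved CO C (µM). Total CDW is X_r + P; PHB content is
100·P/(X_r+P); total cell count is proportional to X_r only (division
tracks catalytic biomass, not storage polymer); redox is an algebraic map
of C.

**Kinetics.**

    mu    = mu_max · S/(K_S + S) · C/(K_Cg + C)          growth, 1/h
    q_CO  = q_CO_max · C/(K_C + C)                        CO uptake, mmol/g/h
    q_PHB = q_PHB_max · S/(K_S + S) · (1 − mu/mu_max)     PHB synthesis, g/g/h
    dC/dt = kLa·(C* − C) − 1000·q_CO·X_r − D·C            µM/h

All CO oxidized goes 1:1:1 to CO2 + H2 (biological water-gas shift);
biomass carbon comes from acetate (yield Y_X/S), PHB from acetate (Y_P/S).
C* follows Henry's law from the feed CO partial pressure
(10.5 µM per mol % CO ≈ 1 mM atm⁻¹ solubility at 25–30 °C); using the
*inlet* CO fraction for C* is a simplification that slightly overestimates
driving force at high conversion. The off-gas composition comes from a
quasi-steady gas balance: N2 conserved, CO removed at the transfer rate, H2
and CO2 added at the shift rate.

**Parameters.** Printed process anchors are defaults: mu_max = 0.1 h⁻¹,
D = 0.02 h⁻¹, feed gas 25/25/5/45 (CO/H2/CO2/N2), gassing
0.1 l l⁻¹ min⁻¹, 10 mM acetate in batch medium and chemostat feed, feed
law 0.17 mmol OD⁻¹ l⁻¹ h⁻¹, batch→continuous switch at 43 h. The remaining
constants are calibration choices, fixed once so that the default scenarios
reproduce the qualitative shape of the reference cultivations — batch CO
limitation (dissolved CO < 2 µM) arriving together with acetate exhaustion
near 43 h, redox descending from ≈ −190 to ≤ −550 mV, a chemostat steady
state near 0.7 g l⁻¹ CDW, and fed-batch PHB accumulation to tens of wt%:
K_S = 0.2 mM, K_Cg = K_C = 2 µM, q_CO_max = 35 mmol g⁻¹ h⁻¹,
q_PHB_max = 0.008 g g⁻¹ h⁻¹, Y_X/S = 0.08 g mmol⁻¹ (acetate plus
CO2-derived carbon), Y_P/S = 0.04 g mmol⁻¹ (≈ 93 % of the theoretical
2-acetate→monomer yield), kLa = 50 h⁻¹, OD↔CDW factor 0.21 g l⁻¹ per OD,
1.25×10¹² cells per g residual biomass, redox extremes −160/−600 mV with
half-effect at 20 µM dissolved CO. The FL1 channel is generated from an
affine ground-truth map (0.002 wt% per FL1 unit, 1 wt% offset) so the PHB
calibration stage has a real inverse problem to solve.

**Integration.** `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8), piecewise
over operating segments so the fed-batch feed set point is constant within
a segment and updated at the operator cadence from the (noise-free) OD —
the feed controller is exercised inside the simulation loop. Monod terms
clamp negative excursions of S and C to zero, and outputs are floored at
zero; a sterile reactor reduces to pure first-order gas-liquid relaxation,
which is tested in closed form.

**Noise.** Noise enters only at instrument emission: multiplicative
Gaussian per QMS channel (σ = 1 % default), on OD (2 %), CDW (3 %), FL1
(2 %) and TCC (5 %); additive on dissolved CO (0.1 µM) and redox (3 mV).
One ODE solution can therefore be re-emitted under many seeds, and a fixed
seed reproduces streams bit for bit.

**What the simulator does and does not emulate.** It produces the coupled
dynamics, stoichiometry and noise structure the analytics need — which is
what passing tests demonstrate. It does not emulate real biological
variability (adaptation, staining-state changes, maintenance metabolism),
instrument drift or background, the condenser/filter artefacts a real
off-gas line shows, pH/antifoam dynamics, photometabolism, or the
gas-recycling loop. Quantitative agreement of simulated end points with any
particular wet-lab run is therefore not claimed and not tested; printed
end points serve as qualitative shape anchors only.

## Scale of the shipped analyses

Default scenarios sample hourly: 44 samples per batch, 185 per fed-batch,
344 per chemostat (six residence times after the switch). Monte-Carlo
checks (growth-rate recovery, deconvolution error, calibration recovery)
use 100 seeded replicates. These sizes make every stochastic estimate
stable to well under the tolerances asserted while keeping the whole suite
in seconds.

## Known limitations

* The deconvolution is unweighted least squares; with multiplicative noise
  a weighted solver would be statistically more efficient for trace gases,
  at the cost of a data-dependent weight model.
* Calibration assumes a common intensity scale across reference scans
  (same detector settings); per-scan scale factors are not identifiable
  under plain N2 normalization.
* The growth model is a multiplicative double Monod; whether batch growth
  is CO- or acetate-co-limited cannot be resolved from summary process
  data, and other limitation structures (e.g. minimum-law) would fit the
  same anchors.
* Gas hold-up, headspace mixing and dissolved CO2/H2 pools are neglected in
  the off-gas balance (quasi-steady assumption); transients shorter than a
  few minutes are not meaningful.
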