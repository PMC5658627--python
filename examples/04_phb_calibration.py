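"""Fit and apply the mean-FL1 -> PHB calibration line.

A handful of fed-batch samples with both flow-cytometric mean FL1 and a GC
reference measurement define the line; afterwards PHB can be followed from
FCM alone (as in a chemostat, where no GC samples are taken).
"""

import numpy as np

import syngaspat as sg

rng = np.random.default_rng(4)
fl1 = np.linspace(800, 9500, 10)
phb_gc = 0.002 * fl1 + 1.0 + rng.normal(0, 0.5, len(fl1))  # ~0.5 wt% assay scatter

cal = sg.fit_calibration(list(zip(fl1, phb_gc)))
print(f"slope     {cal.slope:.5f} wt% per FL1 unit")
print(f"intercept {cal.intercept:.2f} wt%")
print(f"R^2       {cal.r_squared:.3f}  (n = {cal.n_points})")

for reading in (1500.0, 6000.0, 12000.0):
    est = sg.apply_calibration(cal, reading)
    flags = []
    if est.extrapolated:
        flags.append("extrapolated")
    if est.low_content:
        flags.append("<5 wt% caution")
    print(f"mean FL1 {reading:7.0f} -> {est.phb_wt_pct:5.1f} wt% PHB  {' '.join(flags)}")
# The low-content flag reminds the operator that near the intercept the
# calibration line contributes a non-negligible offset.
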