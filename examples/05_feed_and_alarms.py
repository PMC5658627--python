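"""Operational logic: acetate feed law, chemostat bookkeeping, gas alarms."""

import syngaspat as sg
from syngaspat.control import AlarmState

# --- fed-batch acetate feed -------------------------------------------------
cmd = sg.feed_rate(od600=1.0, volume_l=1.0, residual_acetate_mm=0.0)
print(f"OD 1, 1 l, acetate consumed  -> feed {cmd.acetate_feed_mmol_h:.2f} mmol/h ({cmd.mode})")

cmd = sg.feed_rate(od600=23.5, volume_l=10.0, residual_acetate_mm=0.0)
print(f"OD 23.5, 10 l                -> feed {cmd.acetate_feed_mmol_h:.2f} mmol/h ({cmd.mode})")

cmd = sg.feed_rate(
    od600=23.5, volume_l=10.0, residual_acetate_mm=4.0,
    previous_feed_mmol_h=40.0, measured_consumption_mmol_h=30.0,
)
print(f"acetate accumulating          -> feed {cmd.acetate_feed_mmol_h:.2f} mmol/h ({cmd.mode})")

# --- chemostat bookkeeping ---------------------------------------------------
d = sg.dilution_rate(medium_flow_ml_h=40.0, working_volume_l=2.0)
acetate = sg.combined_feed_acetate_mm(medium_flow_ml_h=40.0, stock_feed_g_h=0.2)
print(f"\nD = {d:.3f} 1/h; combined feed acetate = {acetate:.1f} mM")
print(f"inoculation: OD {sg.inoculation_od(3.33, 12.0, 500.0):.3f} after 12 ml stock into 500 ml")

# --- two-level gas alarm state machine ---------------------------------------
print("\nalarm sequence (CO ppm, H2 vol%):")
state = AlarmState()
for co, h2, events in [(50, 0.1, ()), (120, 0.2, ()), (155, 0.2, ()), (0, 0.0, ())]:
    state = sg.alarm_step(state, co, h2, events=events)
    print(f"  CO {co:5.0f}, H2 {h2:4.1f} -> {state.level:8s} valves {state.valves}")
state = sg.alarm_reset(state, 0.0, 0.0)
print(f"  operator reset      -> {state.level:8s} valves {state.valves}")
# Note the second-to-last row: readings recovered but the shutdown stays
# latched until the explicit operator reset.
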