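"""Characterize an insert's mixing behavior from a step-tracer experiment.

Simulates the dual-photometer recording of a step-tracer run through the
HC3 honeycomb insert (ground-truth Bodenstein number 20, mean residence
time 30 s, 0.5% detector noise), writes it in the serial-log format, reads
it back, and runs the full RTD pipeline: F-curve normalization, exit-age
differentiation, inlet-corrected moments and the open-open dispersion model.
"""

import io

from flowbed import ETHANOL, analyze_rtd, builtin_inserts, io_formats, simulate

insert = builtin_inserts()["HC3"]
step = simulate.simulate_tracer_step(bo=20.0, t_mean=30.0, noise_rel=0.005, seed=1)

# round-trip through the on-disk tracer-log dialect
log = io.StringIO()
io_formats.write_tracer_log(step.to_records(), log)
records = io_formats.read_tracer_log(io.StringIO(log.getvalue()))
time, inlet, outlet = io_formats.tracer_arrays(records)

result = analyze_rtd(time, inlet, outlet, insert, ETHANOL, flowrate=1.0)

print(f"insert                : {insert.name} ({insert.family})")
print(f"corrected t_mean      : {result.mean_residence_time:8.2f} s")
print(f"corrected variance    : {result.variance:8.2f} s^2")
print(f"Bodenstein number     : {result.bodenstein:8.2f}   (ground truth 20)")
print(f"axial dispersion D_ax : {result.axial_dispersion:8.3e} m^2/s")
print(f"Reynolds number       : {result.reynolds:8.3f}")
print()
print("Bo << 100 means the insert behaves closer to a stirred tank than to")
print("plug flow at this flowrate; D_ax quantifies the axial backmixing the")
print("inlet-capillary correction has isolated to the column itself.")
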