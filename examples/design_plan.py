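"""Plan the two-iteration fractional CCD over the default design space.

Prints the 11 first-iteration operating points (flowrate, temperature,
dilution ratio), then completes the second iteration around a hypothetical
best run and shows that the full campaign totals 21 runs while reaching 98%
of every factor range.
"""

import io

from flowbed import doe, io_formats

space = doe.DesignSpace.default()
first = doe.subregion_first(space, 0.7)
points = doe.generate_ccd(first, include_center=True, iteration=1)

print(f"factors        : {space.names}")
print(f"alpha          : {doe.alpha(space.k):.7f}")
print(f"iteration 1    : {len(points)} runs")
for p in points:
    fr, te, di = p.real
    print(f"  run {p.run_index:2d} {p.role:9s} FR={fr:5.3f} mL/min  T={te:5.2f} C  D={di:5.2f}")

# pretend the low-dilution axial point won the first round
best = next(p for p in points if p.role == "axial" and p.value("dilution") < 10)
plan = doe.CampaignPlan(
    space=space, first_fraction=0.7, second_fraction=0.4,
    subregion_1=first, points=list(points),
)
plan.complete_second(best)
print(f"iteration 2    : {len(plan.iteration2)} runs around run {best.run_index}")
print(f"total          : {len(plan.points)} runs")
print(f"coverage       : {100 * doe.coverage_fraction(0.7, 0.4):.0f}% of each axis")

table = io.StringIO()
io_formats.write_design_table(plan.points, table)
print(f"design table   : {len(table.getvalue().splitlines()) - 1} CSV rows")
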