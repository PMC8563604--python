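"""Run the full 21-experiment self-optimization against the virtual reactor.

A virtual HC3 insert with known kinetics (temperature optimum 30 C,
Michaelis-Menten saturation, 8-tank backmixing, 1% measurement noise) is
screened by the two-iteration fractional CCD; the campaign's best operating
point is then compared with the brute-force grid optimum it can reach.
"""

import tempfile

from flowbed import (
    CampaignConfig,
    DesignSpace,
    KineticParams,
    SimulatorProvider,
    VirtualReactor,
    builtin_inserts,
    report,
    run_campaign,
    simulate,
)

insert = builtin_inserts()["HC3"]
kinetics = KineticParams(vmax_ref=0.02, t_opt=30.0, t_width=6.0, km=0.5,
                         n_tanks=8, noise_rel=0.01, seed=42)
reactor = VirtualReactor(geometry=insert, kinetics=kinetics)
config = CampaignConfig(
    design_space=DesignSpace.default(), stock_concentration=10.0,
    insert=insert, seed=42,
)

result = run_campaign(SimulatorProvider(reactor), config)

b1, bf = result.best_iteration1, result.best_final
print(f"runs executed : {len(result.results)} (failures: {len(result.failures)})")
print(
    f"iteration 1   : best run {b1.point.run_index:2d} "
    f"FR={b1.point.value('flowrate'):.3f} T={b1.point.value('temperature'):.2f} "
    f"D={b1.point.value('dilution'):.2f}  STY={b1.sty:.2f} g/(L*h)"
)
print(
    f"final best    : run {bf.point.run_index:2d} "
    f"FR={bf.point.value('flowrate'):.3f} T={bf.point.value('temperature'):.2f} "
    f"D={bf.point.value('dilution'):.2f}  STY={bf.sty:.2f} g/(L*h) "
    f"(yield {100 * bf.yield_frac:.1f}%, tau {bf.residence_time_s:.1f} s)"
)

best_grid, sty_grid = simulate.true_optimum(reactor, config.design_space, grid_n=25)
print(f"grid oracle   : STY={sty_grid:.2f} g/(L*h) at {best_grid}")
print(f"campaign/oracle STY ratio: {bf.sty / sty_grid:.3f}")

with tempfile.TemporaryDirectory() as out:
    paths = report(result, out)
    print("report files  :", ", ".join(p.name for p in paths.values()))

print("\nThe campaign reaches the oracle's neighborhood with 21 experiments")
print("instead of a 15625-point grid; the gap reflects the zoomed design's")
print("finite resolution and the greedy single-optimum zoom.")
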