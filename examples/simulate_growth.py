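"""FBA, FVA and robustness on a minimal uptake-limited pathway.

The toy chain takes up nutrient A (at most 10 flux units), transports
it into the cytosol, converts it to biomass precursor B and drains it
through the biomass reaction.  Throughput is therefore limited by
uptake: the optimal growth flux equals 10, every reaction's flux is
uniquely determined, and the robustness curve is linear in the uptake.
"""

from gemkit import fba, fva, make_fixture, robustness

model = make_fixture("chain")

solution = fba(model)
print(f"FBA objective ({solution.objective_reaction}): "
      f"{solution.objective_value:g}")
for rid, flux in solution.fluxes.items():
    print(f"  {rid:6s} {flux:8.3f}  {model.reactions[rid].equation}")

intervals = fva(model, optimum_fraction=1.0)
print("\nFVA at the optimum (point intervals = unique fluxes):")
for rid, (low, high) in intervals.items():
    print(f"  {rid:6s} [{low:g}, {high:g}]")

curve = robustness(model, "EX_A", steps=5)
print("\nGrowth as a function of the fixed uptake flux:")
for fixed, objective in curve.points:
    print(f"  uptake {fixed:8.2f} -> growth {objective:g}")
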