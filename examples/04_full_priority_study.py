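"""Run the full priority-setting study and print the headline tables.

The study evaluates four potato research options (late blight
resistance, virus resistance, bacterial wilt resistance, improved seed
systems) against a static counterfactual and three foresight
(SSP-RCP-style) scenarios, under both all-countries and target-only
welfare aggregation, and ranks them by net-benefit NPV.
"""

from cropforesight import StudyConfig, compare_aggregations, run_study

result = run_study(StudyConfig(seed=2019))

print("net-benefit NPV ranking per scenario x aggregation:")
print(result.ranking("npv").to_string(index=False))

frame = result.reports_frame()
cols = ["technology", "scenario", "aggregation", "producer_surplus_npv",
        "consumer_surplus_npv", "cost_npv", "net_benefits_npv", "irr"]
static_all = frame[(frame.scenario == "static") & (frame.aggregation == "all")]
print("\nstatic scenario, all countries (million US$):")
print(static_all[cols].round(1).to_string(index=False))

print("\ntarget-only vs all-countries net benefits:")
comp = compare_aggregations(result.reports)
print(comp[comp.scenario == "static"]
      .round(3).to_string(index=False))

f = result.world.focus_index
print("\nend-of-horizon world potato price, static scenario (US$/t):")
wp0 = result.baselines["static"].world_price[-1, f]
print(f"  baseline: {wp0:.2f}")
for tech in result.manifest["technologies"]:
    wp1 = result.shocked[("static", tech)].world_price[-1, f]
    print(f"  {tech}: {wp1:.2f} ({100 * (wp1 - wp0) / wp0:+.2f}%)")
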