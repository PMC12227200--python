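"""Compare two simulated genotypes: rank-sum tests and negbin regression.

Simulates a control group and a knockout-like group with doubled small-
event rate (the direction seen when galanin signalling is removed),
then runs the full activity analysis: per-larva tier summaries, AUC
normalised to control, Mann-Whitney tests on continuous measures and a
negative-binomial GLM on event counts.
"""

from calseize import PipelineConfig, SimulationConfig, run_activity_analysis
from calseize.simulate import GroupEffect, simulate_cohort

sim = SimulationConfig(
    rng_seed=0,
    duration_s=900.0,  # shortened recordings keep the demo quick
    group_effects={"gal_ko": GroupEffect(small_rate=2.0, small_amp=0.8)},
)
cohort = simulate_cohort(sim, {"control": 10, "gal_ko": 10}, seed=0)
result = run_activity_analysis(cohort, PipelineConfig(), control_group="control")

print(result["summaries"][["larva_id", "group", "count_5pct", "auc_normalized"]]
      .groupby("group").agg({"count_5pct": "mean", "auc_normalized": "mean"}))
print()
for comp in result["comparisons"]:
    kind = "rate ratio" if comp.test == "negbin_glm" else "median diff"
    print(f"{comp.measure_name:45s} {comp.test:10s} "
          f"{kind}={comp.effect:7.3f}  p={comp.p_value:.3g} [{comp.significance_label}]")
# The knockout group fires small events twice as often but 0.8x as large,
# so part of its amplitude distribution drops below the 5% threshold: the
# count_5pct rate ratio lands between 1 and 2, the count_10pct ratio falls
# below 1, and the amplitude medians shift down - the frequency-up /
# amplitude-down signature of removing an inhibitory neuropeptide.
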