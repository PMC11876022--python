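"""Full screening workflow: univariate screens, MVMR, mediation.

Simulates an exposure -> mediator -> outcome study in which the entire
exposure effect flows through the mediator (a = 0.1, b = 0.07, no direct
effect), then runs the staged screen and prints the mediation verdict.
"""

from mrmediate import PipelineConfig, run_mediation_workflow, simulate_triple

tri = simulate_triple(seed=11)  # defaults: 200 instruments/trait, n = 300k
print(f"truth: a = {tri.truth['a']}, b = {tri.truth['b']}, "
      f"direct = {tri.truth['c_direct']}, indirect = {tri.truth['indirect_effect']}")

cfg = PipelineConfig(methods=("ivw",), sensitivity_parts=("heterogeneity", "steiger"))
res = run_mediation_workflow(
    [tri.exposure], [tri.mediator], tri.outcome, tri.ld, cfg
)

eo = res.screen_exposure_outcome.pairs[0]
print(f"exposure -> outcome: beta = {eo.primary.beta:+.5f} "
      f"(p = {eo.primary.pval:.2g}, passed = {eo.passed})")

for mv in res.mvmr_results:
    print(f"{mv.model_id} MVMR on {mv.nsnp} instruments:")
    for row in mv.estimates.itertuples(index=False):
        print(f"  {row.exposure:14s} direct beta = {row.beta:+.5f} "
              f"se = {row.se:.5f}  p = {row.pval:.3g}")

m = res.mediation_results[0]
print(f"indirect effect beta_M = {m.beta_m:+.5f}  SE_M = {m.se_m:.5f}")
print(f"Sobel z = {m.sobel_z:.2f} (p = {m.sobel_pval:.3g})")
print(f"classification: {m.classification}")
# complete mediation: the exposure's effect on the outcome disappears once
# the mediator's direct effect is accounted for in the multivariable model.
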