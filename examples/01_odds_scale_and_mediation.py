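"""Odds-scale reporting and product-of-coefficients mediation.

Takes published per-row coefficients (log-odds beta and SE) as inputs,
converts them to odds ratios with 95% confidence intervals, then composes
a mediation effect from its two components and tests it with the Sobel z.
"""

from mrmediate import mediation_effect, sobel_test, to_odds_scale

# a log-odds effect of a metabolite exposure on a binary outcome
odds = to_odds_scale(beta=0.068207, se=0.021287)
print(f"OR = {odds['or_']:.6f}  95% CI ({odds['ci_low']:.6f}, {odds['ci_high']:.6f})"
      f"  p = {odds['pval']:.6f}")
# OR > 1: each effect-allele copy multiplies the outcome odds by ~1.07.

# exposure -> mediator effect (univariate MR) and mediator -> outcome
# direct effect (from multivariable MR), each with its standard error
eff = mediation_effect(beta_a=0.103511, se_a=0.033395,
                       beta_b=0.072537, se_b=0.028385)
sob = sobel_test(eff["beta_m"], eff["se_m"])
print(f"indirect effect beta_M = {eff['beta_m']:.6f}  SE_M = {eff['se_m']:.6f}")
print(f"Sobel z = {sob['z']:.3f}  p = {sob['pval']:.4f}")
# beta_M = beta_A * beta_B is the effect transmitted through the mediator;
# Sobel p < 0.05 means the mediated path is statistically significant.
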