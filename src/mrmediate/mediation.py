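"""Product-of-coefficients mediation with Sobel test and classification.

For an exposure -> mediator -> outcome chain the indirect (mediated)
effect is

    beta_M = beta_A * beta_B
    SE_M   = sqrt((beta_A * SE_B)^2 + (beta_B * SE_A)^2)

with beta_A the univariate MR effect of exposure on mediator and beta_B
the mediator's direct effect on the outcome from multivariable MR.  The
causal-stepwise decision tree then classifies the model:

1. the indirect effect is significant if both beta_A and beta_B are
   significant at alpha; if either is not, a Sobel test on
   z = beta_M / SE_M decides;
2. given a significant indirect effect: a non-significant direct effect
   (exposure on outcome in MVMR, beta_C') means complete mediation; a
   significant direct effect with the opposite sign to beta_M is a
   covering (suppression) effect with ratio |beta_M / beta_C'| * 100%;
   with the same sign it is partial mediation with proportion
   beta_M / beta_C * 100%, beta_C being the univariate total effect;
3. otherwise: no mediation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError

CLASSIFICATIONS = (
    "complete-mediation",
    "partial-mediation",
    "covering-effect",
    "no-mediation",
)


def mediation_effect(beta_a: float, se_a: float, beta_b: float, se_b: float) -> dict:
    """Indirect effect and its delta-method standard error."""
    if se_a <= 0 or se_b <= 0:
        raise InputError("component standard errors must be positive")
    beta_m = beta_a * beta_b
    se_m = float(np.sqrt((beta_a * se_b) ** 2 + (beta_b * se_a) ** 2))
    return {"beta_m": beta_m, "se_m": se_m}


def sobel_test(beta_m: float, se_m: float) -> dict:
    """Sobel z-test of the indirect effect against zero."""
    if se_m < 0:
        raise InputError("se_m must be non-negative")
    if se_m == 0:
        if beta_m == 0:
            return {"z": 0.0, "pval": 1.0, "degenerate": False}
        return {"z": np.inf if beta_m > 0 else -np.inf, "pval": 0.0, "degenerate": True}
    z = beta_m / se_m
    return {"z": float(z), "pval": float(2.0 * stats.norm.sf(abs(z))), "degenerate": False}


def classify_mediation(
    beta_a: float,
    pval_a: float,
    beta_b: float,
    pval_b: float,
    beta_m: float,
    sobel_pval: float,
    beta_c_total: float,
    beta_c_direct: float,
    pval_c_direct: float,
    alpha: float = 0.05,
) -> dict:
    """Apply the causal-stepwise decision tree; see the module docstring."""
    for name, v in (("pval_a", pval_a), ("pval_b", pval_b),
                    ("sobel_pval", sobel_pval), ("pval_c_direct", pval_c_direct)):
        if v is None or not np.isfinite(v):
            raise InputError(f"missing component for classification: {name}")
    both_sig = pval_a < alpha and pval_b < alpha
    indirect_sig = both_sig or sobel_pval < alpha
    if not indirect_sig:
        return {"classification": "no-mediation", "proportion": None,
                "indirect_significant": False}
    if pval_c_direct >= alpha:
        return {"classification": "complete-mediation", "proportion": None,
                "indirect_significant": True}
    if np.sign(beta_m) != np.sign(beta_c_direct):
        proportion = abs(beta_m / beta_c_direct) * 100.0
        return {"classification": "covering-effect", "proportion": proportion,
                "indirect_significant": True}
    proportion = beta_m / beta_c_total * 100.0
    return {"classification": "partial-mediation", "proportion": proportion,
            "indirect_significant": True}


@dataclass
class MediationResult:
    """All components of one exposure -> mediator -> outcome model."""

    model_id: str
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_a: float
    se_a: float
    pval_a: float
    beta_b: float
    se_b: float
    pval_b: float
    beta_m: float = np.nan
    se_m: float = np.nan
    sobel_z: float = np.nan
    sobel_pval: float = np.nan
    beta_c_total: float = np.nan
    se_c_total: float = np.nan
    pval_c_total: float = np.nan
    beta_c_direct: float = np.nan
    se_c_direct: float = np.nan
    pval_c_direct: float = np.nan
    classification: str = ""
    proportion: float | None = None

    def ci(self, which: str, z: float = 1.96) -> tuple[float, float]:
        beta = getattr(self, f"beta_{which}")
        se = getattr(self, f"se_{which}")
        return (beta - z * se, beta + z * se)


def mediate(
    model_id: str,
    exposure_id: str,
    mediator_id: str,
    outcome_id: str,
    beta_a: float,
    se_a: float,
    pval_a: float,
    beta_b: float,
    se_b: float,
    pval_b: float,
    beta_c_total: float,
    se_c_total: float,
    pval_c_total: float,
    beta_c_direct: float,
    se_c_direct: float,
    pval_c_direct: float,
    alpha: float = 0.05,
) -> MediationResult:
    """Compose indirect effect, Sobel test and classification from the
    univariate and multivariable MR components."""
    eff = mediation_effect(beta_a, se_a, beta_b, se_b)
    sob = sobel_test(eff["beta_m"], eff["se_m"])
    cls = classify_mediation(
        beta_a, pval_a, beta_b, pval_b, eff["beta_m"], sob["pval"],
        beta_c_total, beta_c_direct, pval_c_direct, alpha=alpha,
    )
    return MediationResult(
        model_id=model_id,
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta_a=beta_a, se_a=se_a, pval_a=pval_a,
        beta_b=beta_b, se_b=se_b, pval_b=pval_b,
        beta_m=eff["beta_m"], se_m=eff["se_m"],
        sobel_z=sob["z"], sobel_pval=sob["pval"],
        beta_c_total=beta_c_total, se_c_total=se_c_total, pval_c_total=pval_c_total,
        beta_c_direct=beta_c_direct, se_c_direct=se_c_direct,
        pval_c_direct=pval_c_direct,
        classification=cls["classification"],
        proportion=cls["proportion"],
    )
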