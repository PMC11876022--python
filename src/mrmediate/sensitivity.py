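"""Sensitivity battery: heterogeneity, pleiotropy, leave-one-out, Steiger.

* Cochran Q with I^2 = max(0, (Q - df) / Q), labelled none / mild (0-25%) /
  moderate (25-50%) / high (>50%);
* MR-Egger intercept test for directional horizontal pleiotropy
  (significant intercept at alpha = 0.05);
* leave-one-out IVW refits to spot single influential instruments;
* Steiger directionality: the instruments should explain more variance in
  the exposure than in the outcome when the assumed causal direction is
  right; the p-value compares the two correlations via Fisher's z;
* funnel-plot data (per-SNP ratio vs precision), exported not rendered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, InsufficientDataError
from .estimators import _effects, cochran_q_stat, ivw, mr_egger, run_estimators
from .instruments import variance_explained
from .sumstats import HarmonizedSet


def heterogeneity_label(i2: float) -> str:
    if i2 <= 0:
        return "none"
    if i2 < 0.25:
        return "mild"
    if i2 < 0.50:
        return "moderate"
    return "high"


def cochran_q(h: HarmonizedSet, slope: float | None = None) -> dict:
    """Cochran Q around the IVW slope (df = nsnp - 1) with Higgins I^2."""
    bx, _, by, sy = _effects(h)
    n = len(bx)
    if n < 2:
        raise InsufficientDataError("Cochran Q requires at least 2 SNPs")
    if slope is None:
        slope = ivw(h, "fixed").beta
    q = cochran_q_stat(bx, by, sy, slope)
    df = n - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return {
        "q": q,
        "q_df": df,
        "q_pval": float(stats.chi2.sf(q, df)),
        "i2": i2,
        "label": heterogeneity_label(i2),
    }


def egger_intercept_test(h: HarmonizedSet, alpha: float = 0.05) -> dict:
    """Directional-pleiotropy test from the MR-Egger intercept."""
    est = mr_egger(h)
    return {
        "intercept": est.intercept,
        "se": est.intercept_se,
        "pval": est.intercept_pval,
        "pleiotropic": bool(est.intercept_pval < alpha),
    }


def leave_one_out(
    h: HarmonizedSet, flag_se_multiple: float = 2.0, heterogeneity_alpha: float = 0.05
) -> pd.DataFrame:
    """IVW refit dropping each SNP in turn (same effects-model rule).

    The ``influential`` flag marks SNPs whose removal shifts the estimate
    by more than ``flag_se_multiple`` times the refit's standard error.
    """
    d = h.estimation_data.reset_index(drop=True)
    if len(d) < 3:
        raise InsufficientDataError("leave-one-out requires at least 3 SNPs")
    full = run_estimators(h, methods=("ivw",), heterogeneity_alpha=heterogeneity_alpha)[0]
    rows = []
    for i in range(len(d)):
        sub = HarmonizedSet(h.exposure_id, h.outcome_id, d.drop(index=i))
        est = run_estimators(sub, methods=("ivw",), heterogeneity_alpha=heterogeneity_alpha)[0]
        rows.append(
            {
                "snp": d.loc[i, "snp"],
                "beta_without": est.beta,
                "se_without": est.se,
                "pval_without": est.pval,
                "influential": bool(
                    abs(est.beta - full.beta) > flag_se_multiple * est.se
                ),
            }
        )
    return pd.DataFrame(rows)


def steiger_test(
    h: HarmonizedSet, n_exp: int | None = None, n_out: int | None = None
) -> dict:
    """Directionality check: variance explained in exposure vs outcome.

    R^2 on each side sums per-SNP 2 * beta^2 * MAF * (1 - MAF) over the
    estimation rows (clipped to [0, 1]); the p-value compares the implied
    correlations sqrt(R^2) through Fisher's z with n - 3 normalization.
    """
    d = h.estimation_data
    if len(d) == 0:
        raise InsufficientDataError("Steiger test requires at least 1 SNP")
    if d["eaf_exp"].isna().any() or d["eaf_out"].isna().any():
        raise InputError("Steiger test requires effect-allele frequencies on both sides")
    n_exp = int(n_exp if n_exp is not None else d["n_exp"].max())
    n_out = int(n_out if n_out is not None else d["n_out"].max())
    r2_exp = float(
        np.clip(
            variance_explained(d["beta_exp"].to_numpy(), d["eaf_exp"].to_numpy()).sum(),
            0.0,
            1.0,
        )
    )
    r2_out = float(
        np.clip(
            variance_explained(d["beta_out"].to_numpy(), d["eaf_out"].to_numpy()).sum(),
            0.0,
            1.0,
        )
    )
    # clip below 1 so atanh stays finite on synthetic data with huge totals
    r_exp = np.sqrt(min(r2_exp, 1.0 - 1e-10))
    r_out = np.sqrt(min(r2_out, 1.0 - 1e-10))
    if n_exp <= 3 or n_out <= 3:
        raise InputError("Steiger test requires sample sizes above 3")
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    return {
        "r2_exposure": r2_exp,
        "r2_outcome": r2_out,
        "direction_correct": bool(r2_exp > r2_out),
        "steiger_pval": float(2.0 * stats.norm.sf(abs(z))),
    }


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio and precision (1/SE) for funnel plots."""
    d = h.estimation_data
    ratio = d["beta_out"].to_numpy() / d["beta_exp"].to_numpy()
    precision = np.abs(d["beta_exp"].to_numpy()) / d["se_out"].to_numpy()
    return pd.DataFrame({"snp": d["snp"], "ratio": ratio, "precision": precision})


@dataclass
class SensitivityReport:
    """Aggregated sensitivity results for one exposure/outcome pair."""

    exposure_id: str
    outcome_id: str
    nsnp: int
    heterogeneity: dict | None = None
    pleiotropy: dict | None = None
    steiger: dict | None = None
    loo: pd.DataFrame | None = None
    funnel: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "nsnp": self.nsnp,
            "heterogeneity": self.heterogeneity,
            "pleiotropy": self.pleiotropy,
            "steiger": self.steiger,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def sensitivity_report(
    h: HarmonizedSet,
    parts=("heterogeneity", "pleiotropy", "loo", "steiger", "funnel"),
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run the requested sensitivity analyses, noting those not computable
    (pleiotropy and leave-one-out need at least 3 instruments)."""
    rep = SensitivityReport(h.exposure_id, h.outcome_id, h.nsnp)
    for part in parts:
        try:
            if part == "heterogeneity":
                rep.heterogeneity = cochran_q(h)
            elif part == "pleiotropy":
                rep.pleiotropy = egger_intercept_test(h, alpha=alpha)
            elif part == "loo":
                rep.loo = leave_one_out(h)
            elif part == "steiger":
                rep.steiger = steiger_test(h)
            elif part == "funnel":
                rep.funnel = funnel_data(h)
            else:
                raise InputError(f"unknown sensitivity part: {part}")
        except InsufficientDataError as exc:
            rep.notes.append(f"{part}: not computed ({exc})")
    return rep
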