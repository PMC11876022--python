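"""Causal-effect estimators for two-sample MR.

Given harmonized per-SNP effects (beta_exp, se_exp, beta_out, se_out), the
estimators are:

* Wald ratio — single-SNP base case, beta_out / beta_exp;
* IVW — zero-intercept weighted regression of outcome on exposure betas
  with weights 1/se_out^2 (equivalently an inverse-variance meta-analysis
  of Wald ratios); fixed-effects SE fixes the residual variance at 1,
  random-effects multiplies it by max(1, sqrt(Q / (nsnp - 1)));
* MR-Egger — the same regression with a free intercept; a non-zero
  intercept indicates directional pleiotropy and the slope remains a
  consistent causal estimate under the InSIDE assumption;
* weighted median — consistent when >50% of the weight is on valid
  instruments;
* simple/weighted mode — kernel-density mode of the per-SNP ratios,
  consistent when the largest group of instruments is valid.

All p-values are two-sided normal; odds ratios and 95% CIs use
exp(beta +/- 1.96 * se), matching log-odds outcome effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import InputError, InsufficientDataError
from .sumstats import HarmonizedSet

Z95 = 1.96


def _two_sided_p(z):
    return 2.0 * stats.norm.sf(np.abs(z))


def to_odds_scale(beta: float, se: float) -> dict:
    """Odds ratio, 95% CI and two-sided normal p from a log-odds effect."""
    if se <= 0:
        raise InputError("se must be positive")
    with np.errstate(over="ignore"):  # inf bounds are honest for huge SEs
        return {
            "or_": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - Z95 * se)),
            "ci_high": float(np.exp(beta + Z95 * se)),
            "pval": float(_two_sided_p(beta / se)),
        }


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def __post_init__(self):
        if self.se > 0 and np.isnan(self.or_):
            odds = to_odds_scale(self.beta, self.se)
            self.or_ = odds["or_"]
            self.ci_low = odds["ci_low"]
            self.ci_high = odds["ci_high"]
        elif np.isnan(self.or_):
            self.or_ = float(np.exp(self.beta))
            self.ci_low = self.ci_high = self.or_


def _effects(h: HarmonizedSet | np.ndarray):
    d = h.estimation_data
    return (
        d["beta_exp"].to_numpy(float),
        d["se_exp"].to_numpy(float),
        d["beta_out"].to_numpy(float),
        d["se_out"].to_numpy(float),
    )


def wald_ratio(row) -> MREstimate:
    """Single-SNP causal estimate: beta_out / beta_exp, first-order delta SE."""
    bx, by, sy = float(row["beta_exp"]), float(row["beta_out"]), float(row["se_out"])
    if bx == 0:
        raise InputError("Wald ratio undefined for beta_exp = 0")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate("wald_ratio", beta, se, float(_two_sided_p(beta / se)), 1)


def cochran_q_stat(bx, by, sy, slope):
    """Weighted residual sum of squares around a zero-intercept slope."""
    w = 1.0 / sy**2
    return float(np.sum(w * (by - slope * bx) ** 2))


def ivw(h: HarmonizedSet, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept WLS)."""
    if effects_model not in ("fixed", "random"):
        raise InputError(f"unknown effects model: {effects_model}")
    bx, sx, by, sy = _effects(h)
    n = len(bx)
    if n < 1:
        raise InsufficientDataError("IVW requires at least one SNP")
    if n == 1:
        est = wald_ratio(h.estimation_data.iloc[0])
        return MREstimate(f"ivw_{effects_model}", est.beta, est.se, est.pval, 1)
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    if effects_model == "random":
        q = cochran_q_stat(bx, by, sy, beta)
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return MREstimate(
        f"ivw_{effects_model}", beta, se, float(_two_sided_p(beta / se)), n
    )


def mr_egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit with intercept, exposure betas
    oriented non-negative; slope SE uses the multiplier
    max(1, sqrt(Q_egger / (nsnp - 2)))."""
    bx, sx, by, sy = _effects(h)
    n = len(bx)
    if n < 3:
        raise InsufficientDataError("MR-Egger requires at least 3 SNPs")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    q = fit.ssr  # weighted residual sum of squares
    mult = max(1.0, np.sqrt(q / (n - 2)))
    base_se = fit.bse / np.sqrt(fit.scale)  # unit residual variance
    icpt_se, slope_se = float(base_se[0] * mult), float(base_se[1] * mult)
    icpt, slope = float(fit.params[0]), float(fit.params[1])
    return MREstimate(
        "mr_egger",
        slope,
        slope_se,
        float(_two_sided_p(slope / slope_se)),
        n,
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_pval=float(_two_sided_p(icpt / icpt_se)),
    )


def _ratios_and_weights(bx, by, sy):
    ratio = by / bx
    se_ratio = sy / np.abs(bx)
    return ratio, 1.0 / se_ratio**2


def _weighted_median(ratio, weight):
    order = np.argsort(ratio, kind="stable")
    r, w = ratio[order], weight[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 5000, seed: int = 0
) -> MREstimate:
    """Weighted median of Wald ratios, SE by seeded parametric bootstrap."""
    bx, sx, by, sy = _effects(h)
    n = len(bx)
    if n < 3:
        raise InsufficientDataError("weighted median requires at least 3 SNPs")
    ratio, weight = _ratios_and_weights(bx, by, sy)
    beta = _weighted_median(ratio, weight)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, n))
    bys = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r, w = _ratios_and_weights(bxs[i], bys[i], sy)
        boots[i] = _weighted_median(r, w)
    se = float(np.std(boots, ddof=1))
    pval = float(_two_sided_p(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate("weighted_median", beta, se, pval, n)


def _mode_bandwidth(ratio, factor):
    # modified Silverman rule on the ratio spread
    sd = np.std(ratio, ddof=1)
    mad = stats.median_abs_deviation(ratio, scale="normal")
    spread = min(sd, mad) if mad > 0 else sd
    return factor * 0.9 * spread * len(ratio) ** (-1 / 5)


def _kde_argmax(ratio, weight, h, refine=True, gridsize=2048):
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, gridsize)
    dens = weight @ np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2)
    i = int(np.argmax(dens))
    if not refine:
        return float(grid[i])
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]

    def neg_density(x):
        return -np.sum(weight * np.exp(-0.5 * ((x - ratio) / h) ** 2))

    res = optimize.minimize_scalar(
        neg_density, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def mode_estimate(
    h: HarmonizedSet,
    variant: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the smoothed density of Wald ratios (simple or
    inverse-variance weighted), SE by seeded parametric bootstrap."""
    if variant not in ("simple", "weighted"):
        raise InputError(f"unknown mode variant: {variant}")
    bx, sx, by, sy = _effects(h)
    n = len(bx)
    if n < 3:
        raise InsufficientDataError("mode estimators require at least 3 SNPs")
    ratio, ivw_weight = _ratios_and_weights(bx, by, sy)
    weight = ivw_weight if variant == "weighted" else np.ones(n)
    weight = weight / weight.sum()

    method = f"{variant}_mode"
    if np.ptp(ratio) == 0:
        beta = float(ratio[0])
        return MREstimate(method, beta, 0.0, 1.0 if beta == 0 else 0.0, n)
    bw = _mode_bandwidth(ratio, bandwidth_factor)
    beta = _kde_argmax(ratio, weight, bw)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        r, w = _ratios_and_weights(bxs, bys, sy)
        w = w if variant == "weighted" else np.ones(n)
        w = w / w.sum()
        if np.ptp(r) == 0:
            boots[i] = r[0]
            continue
        bwi = _mode_bandwidth(r, bandwidth_factor)
        boots[i] = _kde_argmax(r, w, bwi, refine=False, gridsize=512)
    se = float(np.std(boots, ddof=1))
    pval = float(_two_sided_p(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(method, beta, se, pval, n)


METHODS = ("ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode")


def run_estimators(
    h: HarmonizedSet,
    methods=METHODS,
    n_boot: int = 5000,
    seed: int = 0,
    heterogeneity_alpha: float = 0.05,
) -> list[MREstimate]:
    """Run the requested estimators, skipping those with too few SNPs.

    ``ivw`` yields the effects-model variant selected by the heterogeneity
    rule (random effects when the Cochran Q p-value is below
    ``heterogeneity_alpha``); both variants can be requested explicitly as
    ``ivw_fixed`` / ``ivw_random``.
    """
    out = []
    for m in methods:
        try:
            if m == "ivw":
                fixed = ivw(h, "fixed")
                if fixed.nsnp >= 2:
                    bx, _, by, sy = _effects(h)
                    q = cochran_q_stat(bx, by, sy, fixed.beta)
                    q_p = stats.chi2.sf(q, fixed.nsnp - 1)
                    est = ivw(h, "random") if q_p < heterogeneity_alpha else fixed
                else:
                    est = fixed
            elif m == "ivw_fixed":
                est = ivw(h, "fixed")
            elif m == "ivw_random":
                est = ivw(h, "random")
            elif m == "mr_egger":
                est = mr_egger(h)
            elif m == "weighted_median":
                est = weighted_median(h, n_boot=n_boot, seed=seed)
            elif m == "simple_mode":
                est = mode_estimate(h, "simple", n_boot=n_boot, seed=seed)
            elif m == "weighted_mode":
                est = mode_estimate(h, "weighted", n_boot=n_boot, seed=seed)
            else:
                raise InputError(f"unknown method: {m}")
        except InsufficientDataError:
            continue
        out.append(est)
    return out
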