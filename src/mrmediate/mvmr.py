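"""Multivariable MR: joint direct effects of several exposures on one outcome.

Instruments are the union of each exposure's genome-wide-significant SNPs,
jointly re-clumped ranking by the minimum p across exposures.  The
estimator is IVW-style multivariable weighted regression: outcome betas on
the matrix of exposure betas, no intercept, weights 1/se_out^2; standard
errors carry the max(1, sqrt(Q / (nsnp - n_exposures))) multiplier.  A
heuristic conditional instrument-strength F is reported per exposure
(never used for filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearityError, InsufficientDataError
from .instruments import GENOME_WIDE_P, InstrumentConfig, LDMatrix, clump
from .sumstats import HarmonizedSet, SummaryStats, harmonize


def select_mvmr_instruments(
    exposures: list[SummaryStats],
    ld: LDMatrix,
    config: InstrumentConfig | None = None,
) -> list:
    """Union of per-exposure significant SNPs, jointly re-clumped.

    Ranking within the greedy clump uses each SNP's minimum p-value across
    exposures; single-exposure input reduces to the univariate clump.
    """
    cfg = config or InstrumentConfig()
    if len(exposures) == 0:
        raise InsufficientDataError("MVMR requires at least one exposure")
    min_p: dict = {}
    for exp in exposures:
        sig = exp.data[exp.data["pval"] < cfg.p_thresh]
        for snp, p in zip(sig["snp"], sig["pval"]):
            if snp not in min_p or p < min_p[snp]:
                min_p[snp] = p
    if not min_p:
        raise InsufficientDataError("no SNP reaches the significance threshold in any exposure")
    pooled = pd.DataFrame(
        {"snp": list(min_p), "pval": list(min_p.values())}
    )
    # reuse the greedy clump via a minimal single-trait table
    template = exposures[0].data.set_index("snp")
    fallback = {c: template[c].iloc[0] for c in ("effect_allele", "other_allele")}
    rows = []
    for snp, p in zip(pooled["snp"], pooled["pval"]):
        chrom, pos = ld.locus(snp)
        rows.append(
            {
                "snp": snp, "chr": chrom, "pos": pos,
                "effect_allele": fallback["effect_allele"],
                "other_allele": fallback["other_allele"],
                "eaf": 0.5, "beta": 0.0, "se": 1.0, "pval": p, "n": 1000,
            }
        )
    pooled_stats = SummaryStats("mvmr-union", pd.DataFrame(rows))
    return clump(pooled_stats, ld, p_thresh=1.0, r2_thresh=cfg.r2_thresh,
                 window_kb=cfg.window_kb)


@dataclass
class MVMRData:
    """Per-SNP exposure and outcome effects aligned to a shared effect allele."""

    exposure_ids: list
    outcome_id: str
    data: pd.DataFrame  # snp, beta_<id>, se_<id>..., beta_out, se_out


def harmonize_mvmr(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    snps: list,
    palindrome_policy: str = "drop-ambiguous",
) -> MVMRData:
    """Align every exposure and the outcome to the first exposure's effect
    allele at the selected SNPs; SNPs missing or unresolvable anywhere are
    dropped."""
    ref = exposures[0]
    ref_data = ref.data[ref.data["snp"].isin(snps)].reset_index(drop=True)
    ref_sub = SummaryStats(ref.trait_id, ref_data)
    merged = ref_data[["snp", "beta", "se"]].rename(
        columns={"beta": f"beta_{ref.trait_id}", "se": f"se_{ref.trait_id}"}
    )
    for other in list(exposures[1:]) + [outcome]:
        hz = harmonize(ref_sub, other, palindrome_policy=palindrome_policy)
        keep = hz.estimation_data
        label = "out" if other is outcome else other.trait_id
        cols = keep[["snp", "beta_out", "se_out"]].rename(
            columns={"beta_out": f"beta_{label}", "se_out": f"se_{label}"}
        )
        merged = merged.merge(cols, on="snp", how="inner")
    return MVMRData(
        exposure_ids=[e.trait_id for e in exposures],
        outcome_id=outcome.trait_id,
        data=merged.reset_index(drop=True),
    )


@dataclass
class MVMRResult:
    """Direct effects of each exposure from one multivariable fit."""

    model_id: str
    exposures: list
    estimates: pd.DataFrame  # exposure, beta, se, pval, conditional_f
    nsnp: int
    q: float = np.nan
    q_pval: float = np.nan

    def estimate_for(self, exposure_id: str) -> dict:
        row = self.estimates.set_index("exposure").loc[exposure_id]
        return {k: row[k] for k in ("beta", "se", "pval", "conditional_f")}


def _conditional_f(X, se_x, w, j):
    """Instrument strength of exposure j after partialling out the others:
    mean weighted squared residual association scaled by its own SE."""
    others = np.delete(X, j, axis=1)
    if others.shape[1] == 0:
        resid = X[:, j]
    else:
        fit = sm.WLS(X[:, j], others, weights=w).fit()
        resid = X[:, j] - others @ fit.params
    return float(np.mean(resid**2 / se_x[:, j] ** 2))


def mvmr_ivw(mv: MVMRData, model_id: str = "mvmr") -> MVMRResult:
    """IVW-style multivariable weighted regression of outcome on exposures."""
    ids = mv.exposure_ids
    p = len(ids)
    d = mv.data
    n = len(d)
    if n < p + 1:
        raise InsufficientDataError(
            f"MVMR with {p} exposures needs at least {p + 1} instruments, got {n}"
        )
    X = np.column_stack([d[f"beta_{i}"].to_numpy(float) for i in ids])
    se_x = np.column_stack([d[f"se_{i}"].to_numpy(float) for i in ids])
    y = d["beta_out"].to_numpy(float)
    w = 1.0 / d["se_out"].to_numpy(float) ** 2

    # an exposure with no signal at these instruments (all betas zero) is a
    # nuisance-free column: it gets a zero direct effect rather than making
    # the whole design rank-deficient
    zero_cols = [j for j in range(p) if np.all(X[:, j] == 0.0)]
    live = [j for j in range(p) if j not in zero_cols]
    if not live:
        raise InsufficientDataError("all exposure columns are zero")

    Xw = X[:, live] * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < len(live):
        p_live = len(live)
        # name exposures involved in near-exact linear dependence
        corr = np.corrcoef(X[:, live], rowvar=False)
        corr = np.atleast_2d(corr)
        guilty = set()
        for a in range(p_live):
            for b in range(a + 1, p_live):
                if abs(corr[a, b]) > 1 - 1e-8:
                    guilty.update((ids[live[a]], ids[live[b]]))
        guilty = sorted(guilty) or [ids[j] for j in live]
        raise CollinearityError(
            f"rank-deficient exposure matrix (rank {rank} < {p_live}); "
            f"collinear exposures: {guilty}",
            exposures=guilty,
        )

    fit = sm.WLS(y, X[:, live], weights=w).fit()
    q = float(fit.ssr)
    mult = max(1.0, np.sqrt(q / (n - len(live))))
    base_se = fit.bse / np.sqrt(fit.scale)
    se_live = base_se * mult
    beta = np.zeros(p)
    se = np.full(p, np.inf)
    beta[live] = fit.params
    se[live] = se_live
    pval = np.ones(p)
    pval[live] = 2.0 * stats.norm.sf(np.abs(fit.params / se_live))
    est = pd.DataFrame(
        {
            "exposure": ids,
            "beta": beta,
            "se": se,
            "pval": pval,
            "conditional_f": [_conditional_f(X, se_x, w, j) for j in range(p)],
        }
    )
    return MVMRResult(
        model_id=model_id,
        exposures=list(ids),
        estimates=est,
        nsnp=n,
        q=q,
        q_pval=float(stats.chi2.sf(q, n - len(live))),
    )
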