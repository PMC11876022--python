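"""End-to-end screening workflow.

The screening logic mirrors a staged epidemiological MR study:

1. univariate screen of every candidate exposure (and mediator) against
   the outcome — instruments, harmonization, the estimator battery,
   sensitivity checks; a pair passes when the primary IVW estimate is
   significant (raw p < 0.05 by default, no multiple-testing correction
   unless requested) and the Steiger test supports the assumed direction;
2. univariate MR of each surviving exposure on each surviving mediator,
   keeping significant, direction-consistent pairs;
3. a two-exposure MVMR of each surviving (exposure, mediator) pair on the
   outcome, giving the mediator's direct effect beta_B and the exposure's
   direct effect beta_C';
4. product-of-coefficients mediation with Sobel test and classification.

The primary IVW estimate uses fixed effects, switching to random effects
when the Cochran Q p-value falls below 0.05.  Pairs with fewer than three
instruments stay in the causal screen but skip the pleiotropy and
leave-one-out checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, InsufficientDataError
from .estimators import METHODS, MREstimate, run_estimators
from .instruments import InstrumentConfig, InstrumentSet, LDMatrix, select_instruments
from .mediation import MediationResult, mediate
from .mvmr import MVMRResult, harmonize_mvmr, mvmr_ivw, select_mvmr_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import HarmonizedSet, SummaryStats, harmonize


@dataclass
class PipelineConfig:
    """Knobs of the screening workflow (defaults mirror the staged design)."""

    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    methods: tuple = METHODS
    n_boot: int = 5000
    seed: int = 0
    alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    palindrome_policy: str = "drop-ambiguous"
    steiger_required: bool = True
    sensitivity_parts: tuple = ("heterogeneity", "pleiotropy", "loo", "steiger", "funnel")
    multiple_testing: str | None = None  # None (raw p, the default) | "bonferroni" | "fdr"


def _adjust_pvals(pvals: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return pvals
    from statsmodels.stats.multitest import multipletests

    kind = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}[method]
    return multipletests(pvals, method=kind)[1]


@dataclass
class PairResult:
    """Everything computed for one exposure/outcome pair."""

    exposure_id: str
    outcome_id: str
    instruments: InstrumentSet
    harmonized: HarmonizedSet
    estimates: list
    sensitivity: SensitivityReport
    primary: MREstimate
    passed: bool
    pval_screen: float


@dataclass
class ScreenResult:
    """One screening stage: per-pair records plus a flat summary table."""

    stage: str
    pairs: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            for est in p.estimates:
                rows.append(
                    {
                        "exposure": p.exposure_id,
                        "id": p.outcome_id,
                        "nsnp": est.nsnp,
                        "beta": est.beta,
                        "se": est.se,
                        "or_95ci": f"{est.or_:.6f} ({est.ci_low:.6f}, {est.ci_high:.6f})",
                        "pval": est.pval,
                        "method": est.method,
                        "primary": est is p.primary,
                        "passed": p.passed,
                    }
                )
        return pd.DataFrame(rows)

    def passing(self) -> list:
        return [p for p in self.pairs if p.passed]


def _screen_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    cfg: PipelineConfig,
) -> PairResult | None:
    inst = select_instruments(exposure, ld, cfg.instruments)
    if inst.k < 1:
        return None
    sub = SummaryStats(
        exposure.trait_id,
        exposure.data[exposure.data["snp"].isin(inst.snps)].reset_index(drop=True),
    )
    h = harmonize(sub, outcome, palindrome_policy=cfg.palindrome_policy)
    if h.nsnp < 1:
        return None
    parts = cfg.sensitivity_parts
    if h.nsnp < 3:
        parts = tuple(p for p in parts if p not in ("pleiotropy", "loo"))
    ests = run_estimators(
        h, methods=cfg.methods, n_boot=cfg.n_boot, seed=cfg.seed,
        heterogeneity_alpha=cfg.heterogeneity_alpha,
    )
    if not ests:
        return None
    primary = next((e for e in ests if e.method.startswith("ivw")), ests[0])
    sens = sensitivity_report(h, parts=parts, alpha=cfg.alpha)
    steiger_ok = True
    if cfg.steiger_required and sens.steiger is not None:
        steiger_ok = (
            sens.steiger["direction_correct"]
            and sens.steiger["steiger_pval"] < cfg.alpha
        )
    return PairResult(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        instruments=inst,
        harmonized=h,
        estimates=ests,
        sensitivity=sens,
        primary=primary,
        passed=bool(primary.pval < cfg.alpha and steiger_ok),
        pval_screen=primary.pval,
    )


def run_univariate_screen(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: LDMatrix,
    config: PipelineConfig | None = None,
    stage: str = "exposure-outcome",
) -> ScreenResult:
    """Screen each exposure against the outcome; see the module docstring."""
    cfg = config or PipelineConfig()
    res = ScreenResult(stage=stage)
    for exposure in exposures:
        try:
            pair = _screen_pair(exposure, outcome, ld, cfg)
        except InsufficientDataError as exc:
            res.skipped.append((exposure.trait_id, str(exc)))
            continue
        if pair is None:
            res.skipped.append((exposure.trait_id, "no surviving instrument"))
            continue
        res.pairs.append(pair)
    if cfg.multiple_testing and res.pairs:
        adj = _adjust_pvals(
            np.array([p.pval_screen for p in res.pairs]), cfg.multiple_testing
        )
        for p, q in zip(res.pairs, adj):
            steiger_ok = True
            if cfg.steiger_required and p.sensitivity.steiger is not None:
                steiger_ok = (
                    p.sensitivity.steiger["direction_correct"]
                    and p.sensitivity.steiger["steiger_pval"] < cfg.alpha
                )
            p.pval_screen = float(q)
            p.passed = bool(q < cfg.alpha and steiger_ok)
    return res


@dataclass
class MediationWorkflowResult:
    """All stages of the mediation screening workflow."""

    screen_exposure_outcome: ScreenResult
    screen_mediator_outcome: ScreenResult
    screen_exposure_mediator: ScreenResult
    mvmr_results: list = field(default_factory=list)
    mediation_results: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    @property
    def mediation_table(self) -> pd.DataFrame:
        rows = []
        for r in self.mediation_results:
            lo_a, hi_a = r.ci("a")
            lo_b, hi_b = r.ci("b")
            lo_m, hi_m = r.ci("m")
            rows.append(
                {
                    "model": r.model_id,
                    "exposure": r.exposure_id,
                    "mediator": r.mediator_id,
                    "direct_effect_em": f"{r.beta_a:.6f} ({lo_a:.6f}, {hi_a:.6f})",
                    "direct_effect_mo": f"{r.beta_b:.6f} ({lo_b:.6f}, {hi_b:.6f})",
                    "mediation_effect": f"{r.beta_m:.6f} ({lo_m:.6f}, {hi_m:.6f})",
                    "direct_effect_eo": r.beta_c_direct,
                    "total_effect_eo": r.beta_c_total,
                    "sobel_z": r.sobel_z,
                    "sobel_pval": r.sobel_pval,
                    "classification": r.classification,
                    "proportion_pct": r.proportion,
                }
            )
        return pd.DataFrame(rows)

    @property
    def mvmr_table(self) -> pd.DataFrame:
        rows = []
        for res in self.mvmr_results:
            for rec in res.estimates.itertuples(index=False):
                rows.append(
                    {
                        "model": res.model_id,
                        "exposure": rec.exposure,
                        "beta": rec.beta,
                        "se": rec.se,
                        "pval": rec.pval,
                        "conditional_f": rec.conditional_f,
                        "nsnp": res.nsnp,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.screen_exposure_outcome.table.to_csv(
            out / "univariate_exposure_outcome.tsv", sep="\t", index=False
        )
        self.screen_mediator_outcome.table.to_csv(
            out / "univariate_mediator_outcome.tsv", sep="\t", index=False
        )
        self.screen_exposure_mediator.table.to_csv(
            out / "exposure_mediator.tsv", sep="\t", index=False
        )
        self.mvmr_table.to_csv(out / "mvmr.tsv", sep="\t", index=False)
        self.mediation_table.to_csv(out / "mediation.tsv", sep="\t", index=False)
        for stage in (
            self.screen_exposure_outcome,
            self.screen_mediator_outcome,
            self.screen_exposure_mediator,
        ):
            for pair in stage.pairs:
                tag = re.sub(
                    r"[^A-Za-z0-9._-]", "-",
                    f"{stage.stage}_{pair.exposure_id}_{pair.outcome_id}",
                )
                pair.sensitivity.to_json(out / f"sensitivity_{tag}.json")
                if pair.sensitivity.loo is not None:
                    pair.sensitivity.loo.to_csv(
                        out / f"loo_{tag}.tsv", sep="\t", index=False
                    )
                if pair.sensitivity.funnel is not None:
                    pair.sensitivity.funnel.to_csv(
                        out / f"funnel_{tag}.tsv", sep="\t", index=False
                    )


def run_mediation_workflow(
    exposures: list[SummaryStats],
    mediators: list[SummaryStats],
    outcome: SummaryStats,
    ld: LDMatrix,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> MediationWorkflowResult:
    """Staged mediation screen; see the module docstring for the gates."""
    cfg = config or PipelineConfig()

    screen_eo = run_univariate_screen(exposures, outcome, ld, cfg, "exposure-outcome")
    screen_mo = run_univariate_screen(mediators, outcome, ld, cfg, "mediator-outcome")
    surviving_exp = {p.exposure_id for p in screen_eo.passing()}
    surviving_med = {p.exposure_id for p in screen_mo.passing()}

    exp_by_id = {e.trait_id: e for e in exposures}
    med_by_id = {m.trait_id: m for m in mediators}

    screen_em = ScreenResult(stage="exposure-mediator")
    for eid in sorted(surviving_exp):
        for mid in sorted(surviving_med):
            sub = run_univariate_screen(
                [exp_by_id[eid]], med_by_id[mid], ld, cfg, "exposure-mediator"
            )
            screen_em.pairs.extend(sub.pairs)
            screen_em.skipped.extend(sub.skipped)

    result = MediationWorkflowResult(screen_eo, screen_mo, screen_em)
    model_no = 0
    eo_pairs = {p.exposure_id: p for p in screen_eo.pairs}
    mo_pairs = {p.exposure_id: p for p in screen_mo.pairs}
    for pair in screen_em.pairs:
        if not pair.passed:
            continue
        eid, mid = pair.exposure_id, pair.outcome_id
        model_no += 1
        model_id = f"Model {model_no}"
        try:
            snps = select_mvmr_instruments(
                [exp_by_id[eid], med_by_id[mid]], ld, cfg.instruments
            )
            mv = harmonize_mvmr(
                [exp_by_id[eid], med_by_id[mid]],
                outcome,
                snps,
                palindrome_policy=cfg.palindrome_policy,
            )
            mv_res = mvmr_ivw(mv, model_id=model_id)
        except (CollinearityError, InsufficientDataError) as exc:
            result.failures.append((model_id, eid, mid, str(exc)))
            continue
        result.mvmr_results.append(mv_res)

        a_est = pair.primary
        b_est = mv_res.estimate_for(mid)
        c_direct = mv_res.estimate_for(eid)
        total = eo_pairs[eid].primary
        med_res = mediate(
            model_id=model_id,
            exposure_id=eid,
            mediator_id=mid,
            outcome_id=outcome.trait_id,
            beta_a=a_est.beta, se_a=a_est.se, pval_a=a_est.pval,
            beta_b=float(b_est["beta"]), se_b=float(b_est["se"]),
            pval_b=float(b_est["pval"]),
            beta_c_total=total.beta, se_c_total=total.se, pval_c_total=total.pval,
            beta_c_direct=float(c_direct["beta"]), se_c_direct=float(c_direct["se"]),
            pval_c_direct=float(c_direct["pval"]),
            alpha=cfg.alpha,
        )
        result.mediation_results.append(med_res)

    if out_dir is not None:
        result.write(out_dir)
    return result
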