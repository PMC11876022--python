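"""Synthetic GWAS summary statistics under a known causal structure.

The generator emulates the summary-level inputs of a two-sample MR study:
three traits (exposure, mediator, outcome) measured in large cohorts, an
exposure -> mediator -> outcome causal chain with effects

    beta_med = a * beta_exp            (+ SNP-specific noise)
    beta_out = c_direct * beta_exp + b * beta_med
               + pleiotropy_intercept  (+ SNP-specific noise)

per instrument SNP, a near-identity LD matrix with optional correlated
blocks, and observed betas equal to the true effects plus sampling noise
with the analytic standard error 1 / sqrt(2 * N * MAF * (1 - MAF)) of a
standardized (or log-odds) per-allele effect.  The exposure and the
mediator each carry their own set of genome-wide-significant instruments
(true effects truncated so |beta| exceeds the significance threshold at
the trait's sample size), mirroring how multivariable MR instrument sets
are built from the union of per-trait instruments; null SNPs have zero
effects everywhere.  A configurable fraction of SNPs is emitted as
palindromic or with swapped allele coding in the mediator/outcome tables
to exercise harmonization.  All randomness flows from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .instruments import GENOME_WIDE_P, LDMatrix
from .sumstats import SummaryStats

_NONPALINDROMIC = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """True causal parameters and sampling design of one simulated study.

    Defaults encode the conditions the package is exercised under: 200
    instruments per heritable trait at biobank-scale samples (300k), MAF
    uniform on (0.05, 0.5), instrument effects of magnitude ~0.2 on the
    standardized scale (strong enough that the per-SNP F-statistic with
    the set-level k clears the F >= 10 gate at these sample sizes), a
    modest mediated effect a*b and no direct effect, pleiotropy or excess
    heterogeneity unless requested.
    """

    n_snps_instrument: int = 200
    n_snps_mediator: int | None = None  # defaults to n_snps_instrument
    n_snps_null: int = 50
    n_exp: int = 300_000
    n_med: int = 300_000
    n_out: int = 300_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_gx_scale: float = 0.2
    a: float = 0.1
    b: float = 0.07
    c_direct: float = 0.0
    pleiotropy_intercept: float = 0.0
    heterogeneity_sd: float = 0.0
    palindromic_fraction: float = 0.05
    allele_flip_fraction: float = 0.2
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    snp_prefix: str = "rs"  # lets several studies coexist with disjoint SNP ids
    seed: int = 0

    def __post_init__(self):
        if self.n_snps_mediator is None:
            self.n_snps_mediator = self.n_snps_instrument
        for name in ("palindromic_fraction", "allele_flip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.maf_range[0] < self.maf_range[1] < 1.0):
            raise ConfigError(f"invalid maf_range: {self.maf_range}")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.beta_gx_scale <= 0:
            raise ConfigError("beta_gx_scale must be positive")
        if self.heterogeneity_sd < 0:
            raise ConfigError("heterogeneity_sd must be non-negative")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_block_r2 < 1.0:
            raise ConfigError("ld_block_r2 must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SimulatedTriple:
    """Output of one simulation: three trait tables, LD and ground truth."""

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix
    truth: dict
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, tab in (
            ("exposure", self.exposure),
            ("mediator", self.mediator),
            ("outcome", self.outcome),
        ):
            tab.data.to_csv(outdir / f"{label}.tsv", sep="\t", index=False)
        self.ld.write(outdir / "ld_matrix.tsv", outdir / "ld_positions.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        self.config.to_yaml(outdir / "sim_config.yaml")


def _truncated_instrument_effects(rng, scale, thresholds):
    """beta ~ half-normal(scale) conditioned on beta > threshold.

    Effects are positive: each trait's instrument effect alleles are coded
    trait-increasing (the convention summary-data MR tools standardize to),
    which also makes a directional pleiotropy intercept meaningful under
    MR-Egger's non-negative-exposure orientation.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    lo = stats.norm.cdf(thresholds / scale)  # one-sided, magnitude
    tail = 1.0 - lo
    if np.any(tail < 1e-12):
        raise ConfigError(
            "beta_gx_scale too small for genome-wide significance at this "
            "sample size: raise beta_gx_scale, the sample size, or the MAF range"
        )
    u = rng.uniform(size=thresholds.shape)
    return scale * stats.norm.ppf(lo + u * tail)


def _analytic_se(n, maf):
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def simulate_triple(config: SimConfig | None = None, **overrides) -> SimulatedTriple:
    """Simulate exposure, mediator and outcome summary statistics.

    Keyword overrides build a fresh :class:`SimConfig`, e.g.
    ``simulate_triple(seed=3, a=0.0)``.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        d = asdict(config)
        d.update(overrides)
        config = SimConfig(**d)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    kx, km, k0 = cfg.n_snps_instrument, cfg.n_snps_mediator, cfg.n_snps_null
    total = kx + km + k0
    z_gw = stats.norm.isf(GENOME_WIDE_P / 2.0)

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=total)
    se_exp = _analytic_se(cfg.n_exp, maf)
    se_med = _analytic_se(cfg.n_med, maf)
    se_out = _analytic_se(cfg.n_out, maf)

    is_x = np.zeros(total, dtype=bool)
    is_m = np.zeros(total, dtype=bool)
    is_x[:kx] = True
    is_m[kx : kx + km] = True
    is_instrument = is_x | is_m

    beta_exp = np.zeros(total)
    beta_med = np.zeros(total)
    if kx:
        beta_exp[is_x] = _truncated_instrument_effects(
            rng, cfg.beta_gx_scale, z_gw * se_exp[is_x]
        )
    if km:
        beta_med[is_m] = _truncated_instrument_effects(
            rng, cfg.beta_gx_scale, z_gw * se_med[is_m]
        )
    het_med = (
        rng.normal(0.0, cfg.heterogeneity_sd, size=total)
        if cfg.heterogeneity_sd > 0
        else np.zeros(total)
    )
    het_out = (
        rng.normal(0.0, cfg.heterogeneity_sd, size=total)
        if cfg.heterogeneity_sd > 0
        else np.zeros(total)
    )
    beta_med = beta_med + cfg.a * beta_exp + np.where(is_x, het_med, 0.0)
    beta_out = (
        cfg.c_direct * beta_exp
        + cfg.b * beta_med
        + np.where(is_instrument, cfg.pleiotropy_intercept + het_out, 0.0)
    )

    obs_exp = beta_exp + rng.normal(0.0, se_exp)
    obs_med = beta_med + rng.normal(0.0, se_med)
    obs_out = beta_out + rng.normal(0.0, se_out)

    # genomic layout: LD blocks share a locus, everything else is spread
    # far beyond the clumping window
    snp = np.array([f"{cfg.snp_prefix}{i + 1:06d}" for i in range(total)])
    chrom = np.empty(total, dtype=object)
    pos = np.empty(total, dtype=np.int64)
    r2 = np.eye(total)
    bs = cfg.ld_block_size
    for start in range(0, total, bs):
        stop = min(start + bs, total)
        block = start // bs
        c = str(block % 22 + 1)
        base = 1_000_000 + (block // 22) * 30_000_000
        for j, i in enumerate(range(start, stop)):
            chrom[i] = c
            pos[i] = base + j * 1000
        if stop - start > 1 and cfg.ld_block_r2 > 0:
            r2[start:stop, start:stop] = cfg.ld_block_r2
            np.fill_diagonal(r2[start:stop, start:stop], 1.0)

    # allele coding; a fraction palindromic, a fraction strand/effect-swapped
    # in the mediator and outcome tables
    pal = rng.uniform(size=total) < cfg.palindromic_fraction
    pair_idx = rng.integers(0, 8, size=total)
    pal_idx = rng.integers(0, 4, size=total)
    ea = np.array(
        [
            (_PALINDROMIC[pal_idx[i]] if pal[i] else _NONPALINDROMIC[pair_idx[i]])[0]
            for i in range(total)
        ]
    )
    oa = np.array(
        [
            (_PALINDROMIC[pal_idx[i]] if pal[i] else _NONPALINDROMIC[pair_idx[i]])[1]
            for i in range(total)
        ]
    )

    def table(trait_id, beta_obs, se, n):
        z = beta_obs / se
        return pd.DataFrame(
            {
                "snp": snp,
                "chr": chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta_obs,
                "se": se,
                "pval": np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300),
                "n": np.full(total, n, dtype=np.int64),
            }
        )

    t_exp = table(f"sim-exp-{cfg.seed}", obs_exp, se_exp, cfg.n_exp)
    t_med = table(f"sim-med-{cfg.seed}", obs_med, se_med, cfg.n_med)
    t_out = table(f"sim-out-{cfg.seed}", obs_out, se_out, cfg.n_out)

    flip_med = rng.uniform(size=total) < cfg.allele_flip_fraction
    flip_out = rng.uniform(size=total) < cfg.allele_flip_fraction
    for tab, flip in ((t_med, flip_med), (t_out, flip_out)):
        tab.loc[flip, ["effect_allele", "other_allele"]] = tab.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
        tab.loc[flip, "beta"] = -tab.loc[flip, "beta"]
        tab.loc[flip, "eaf"] = 1.0 - tab.loc[flip, "eaf"]

    ld = LDMatrix(
        snp_ids=list(snp),
        r2=r2,
        positions=pd.DataFrame({"snp": snp, "chr": chrom, "pos": pos}),
    )
    truth = {
        "a": cfg.a,
        "b": cfg.b,
        "c_direct": cfg.c_direct,
        "total_effect": cfg.c_direct + cfg.a * cfg.b,
        "indirect_effect": cfg.a * cfg.b,
        "pleiotropy_intercept": cfg.pleiotropy_intercept,
        "heterogeneity_sd": cfg.heterogeneity_sd,
    }
    return SimulatedTriple(
        exposure=SummaryStats(f"sim-exp-{cfg.seed}", t_exp),
        mediator=SummaryStats(f"sim-med-{cfg.seed}", t_med),
        outcome=SummaryStats(f"sim-out-{cfg.seed}", t_out),
        ld=ld,
        truth=truth,
        config=cfg,
    )
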