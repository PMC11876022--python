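"""Instrument selection: genome-wide significance, LD clumping, strength filters.

Instruments for an exposure are SNPs passing a p-value threshold
(default 5e-8), pruned to pairwise LD independence (r^2 < 0.001 within a
10,000 kb window) by greedy clumping against a supplied LD matrix, and
strong by the F-statistic rule F >= 10 with

    F = (N - k - 1) / k * R^2 / (1 - R^2)

where N is the exposure sample size, k the number of clumped instruments
and R^2 the variance in the exposure explained,

    R^2 = 2 * beta^2 * MAF * (1 - MAF).

F is evaluated per SNP from its own R^2 with the set-level k (single pass;
an iterative variant that re-derives k after each removal is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError
from .sumstats import SummaryStats

GENOME_WIDE_P = 5e-8


@dataclass
class LDMatrix:
    """Pairwise r^2 between SNPs plus their genomic positions.

    Stands in for a reference panel: symmetric, unit diagonal, values in
    [0, 1].  ``positions`` maps snp -> (chrom, pos).
    """

    snp_ids: list
    r2: np.ndarray
    positions: pd.DataFrame  # columns: snp, chr, pos

    def __post_init__(self):
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise InputError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise InputError("LD r^2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self._pos = self.positions.set_index("snp")[["chr", "pos"]]

    def pairwise(self, snp_a: str, snp_b: str) -> float:
        return float(self.r2[self._index[snp_a], self._index[snp_b]])

    def locus(self, snp: str) -> tuple[str, int]:
        row = self._pos.loc[snp]
        return str(row["chr"]), int(row["pos"])

    def __contains__(self, snp):
        return snp in self._index

    def write(self, matrix_path, positions_path) -> None:
        pd.DataFrame(self.r2, columns=self.snp_ids).to_csv(
            matrix_path, sep="\t", index=False
        )
        self.positions.to_csv(positions_path, sep="\t", index=False)


def read_ld_matrix(matrix_path, positions_path) -> LDMatrix:
    mat = pd.read_csv(matrix_path, sep="\t")
    pos = pd.read_csv(positions_path, sep="\t", dtype={"snp": str, "chr": str})
    return LDMatrix(
        snp_ids=list(mat.columns), r2=mat.to_numpy(dtype=float), positions=pos
    )


def variance_explained(beta, eaf, formula: str = "standard"):
    """Variance in the exposure explained by one SNP.

    ``standard``: 2 * beta^2 * MAF * (1 - MAF) with MAF = min(eaf, 1 - eaf).
    ``as-printed``: 2 * (1 - MAF) * MAF * 2 * beta, an audit mode retaining
    a linear-in-beta variant sometimes quoted in print; it is dimensionally
    inconsistent with a variance fraction and not used by default.
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any(eaf <= 0) or np.any(eaf >= 1):
        raise InputError("eaf must lie strictly inside (0, 1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    if formula == "standard":
        r2 = 2.0 * beta**2 * maf * (1.0 - maf)
    elif formula == "as-printed":
        r2 = 2.0 * (1.0 - maf) * maf * 2.0 * beta
    else:
        raise ConfigError(f"unknown r2 formula: {formula}")
    return r2 if r2.ndim else float(r2)


def f_statistic(n, k, r2):
    """Instrument-strength F-statistic; the F >= 10 rule is applied by callers."""
    n = np.asarray(n, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 0) or np.any(r2 >= 1):
        raise InputError("r2 must lie in [0, 1)")
    if k < 1 or np.any(n <= k + 1):
        raise InputError("requires n > k + 1 and k >= 1")
    f = (n - k - 1) / k * r2 / (1.0 - r2)
    return f if f.ndim else float(f)


def clump(
    stats: SummaryStats,
    ld: LDMatrix,
    p_thresh: float = GENOME_WIDE_P,
    r2_thresh: float = 0.001,
    window_kb: int = 10_000,
) -> list:
    """Greedy LD clumping; returns selected snp ids.

    SNPs below ``p_thresh`` are ranked by ascending p (ties broken by snp
    id, so the result is invariant to input row order); a SNP is accepted
    iff its r^2 with every already-accepted SNP on the same chromosome
    within ``window_kb`` is below ``r2_thresh``.
    """
    cand = stats.data[stats.data["pval"] < p_thresh]
    if len(cand) == 0:
        return []
    missing = [s for s in cand["snp"] if s not in ld]
    if missing:
        raise ConfigError(f"SNPs absent from LD matrix: {missing[:5]}...")
    cand = cand.sort_values(["pval", "snp"], kind="mergesort")

    window = window_kb * 1000
    accepted: list = []
    loci = {}
    for snp in cand["snp"]:
        chrom, pos = ld.locus(snp)
        ok = True
        for other in accepted:
            o_chrom, o_pos = loci[other]
            if o_chrom == chrom and abs(o_pos - pos) <= window:
                if ld.pairwise(snp, other) >= r2_thresh:
                    ok = False
                    break
        if ok:
            accepted.append(snp)
            loci[snp] = (chrom, pos)
    return accepted


@dataclass
class InstrumentConfig:
    p_thresh: float = GENOME_WIDE_P
    r2_thresh: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0
    r2_formula: str = "standard"
    iterative_f: bool = False


@dataclass
class InstrumentSet:
    """Instruments surviving the p-value, clumping and F filters.

    ``table`` records per-SNP beta/se/eaf/pval/n plus the intermediate
    r2 and f_stat; ``report`` the per-stage counts.
    """

    exposure_id: str
    table: pd.DataFrame
    k: int
    n: int
    report: dict = field(default_factory=dict)

    @property
    def snps(self) -> list:
        return list(self.table["snp"])


def select_instruments(
    stats: SummaryStats, ld: LDMatrix, config: InstrumentConfig | None = None
) -> InstrumentSet:
    """p-filter -> clump -> per-SNP R^2 -> per-SNP F with set-level k -> F filter."""
    cfg = config or InstrumentConfig()
    kept = clump(stats, ld, cfg.p_thresh, cfg.r2_thresh, cfg.window_kb)
    tab = stats.data[stats.data["snp"].isin(kept)].copy()
    tab = tab.set_index("snp").loc[kept].reset_index()  # clump order
    n_sig = int((stats.data["pval"] < cfg.p_thresh).sum())
    k_clumped = len(tab)
    report = {
        "n_input": len(stats.data),
        "n_significant": n_sig,
        "n_clumped": k_clumped,
    }
    if k_clumped == 0:
        report["n_final"] = 0
        return InstrumentSet(stats.trait_id, tab, 0, 0, report)

    def apply_f(tab, k):
        r2 = np.clip(
            variance_explained(
                tab["beta"].to_numpy(), tab["eaf"].to_numpy(), cfg.r2_formula
            ),
            0.0,
            1.0 - 1e-12,
        )
        f = f_statistic(tab["n"].to_numpy(), k, r2)
        tab = tab.assign(r2=r2, f_stat=f)
        return tab[tab["f_stat"] >= cfg.f_min], tab

    strong, annotated = apply_f(tab, k_clumped)
    if cfg.iterative_f:
        while len(strong) not in (0, len(annotated)):
            strong, annotated = apply_f(
                strong.drop(columns=["r2", "f_stat"]), len(strong)
            )
    report["n_final"] = len(strong)
    n_exp = int(stats.data["n"].max()) if len(stats.data) else 0
    return InstrumentSet(
        exposure_id=stats.trait_id,
        table=strong.reset_index(drop=True),
        k=len(strong),
        n=n_exp,
        report=report,
    )
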