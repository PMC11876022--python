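"""GWAS summary-statistics tables and exposure/outcome harmonization.

A summary-statistics table holds one trait's per-SNP association results
(effect/other allele, effect-allele frequency, beta, SE, p, N).  For binary
traits betas are on the log-odds scale.  Harmonization aligns an exposure
and an outcome table onto the exposure's effect allele, negating outcome
betas and complementing frequencies where the outcome reports the other
allele, resolving strand flips by complementing, and handling palindromic
(A/T, C/G) variants according to a configurable policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError

#: Canonical column names of the TSV dialect read and written by this module.
CANONICAL_COLUMNS = (
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)

#: Harmonization outcomes recorded per row.
ACTIONS = (
    "kept",
    "flipped",
    "dropped-palindromic",
    "dropped-missing",
    "dropped-incompatible",
)


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait_id
        Dataset label, e.g. an OpenGWAS-style id such as ``"ieu-a-69"``.
    data
        Validated table with the canonical columns; ``snp`` unique.
    rejections
        Per-row reasons for rows dropped during validation.
    """

    trait_id: str
    data: pd.DataFrame
    rejections: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigError(f"summary statistics missing columns: {missing}")

    def __len__(self):
        return len(self.data)

    @property
    def n_rejected(self):
        return len(self.rejections)


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop rows violating the table invariants; return (clean, reasons).

    Invariants: ACGT alleles, effect != other allele, 0 < eaf < 1, se > 0,
    0 < pval <= 1, n > 0, pos >= 0, snp ids unique (first occurrence kept).
    """
    reasons = []
    keep = np.ones(len(df), dtype=bool)

    def reject(mask, reason):
        for snp in df.loc[mask & keep, "snp"]:
            reasons.append((str(snp), reason))
        keep[np.asarray(mask)] = False

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    reject(~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES), "non-ACGT allele")
    reject((ea == oa).to_numpy(), "effect allele equals other allele")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    reject((~((eaf > 0) & (eaf < 1))).to_numpy(), "eaf outside (0,1)")
    se = pd.to_numeric(df["se"], errors="coerce")
    reject((~(se > 0)).to_numpy(), "se not positive")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    reject((~((pval > 0) & (pval <= 1))).to_numpy(), "pval outside (0,1]")
    n = pd.to_numeric(df["n"], errors="coerce")
    reject((~(n > 0)).to_numpy(), "n not positive")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    reject((~(pos >= 0)).to_numpy(), "negative position")
    reject(df["snp"].duplicated(keep="first").to_numpy(), "duplicate snp id")

    clean = df.loc[keep].copy()
    clean["effect_allele"] = ea[keep]
    clean["other_allele"] = oa[keep]
    for col, typ in (
        ("pos", np.int64),
        ("eaf", float),
        ("beta", float),
        ("se", float),
        ("pval", float),
        ("n", np.int64),
    ):
        clean[col] = clean[col].astype(typ)
    clean["snp"] = clean["snp"].astype(str)
    clean["chr"] = clean["chr"].astype(str)
    return clean.reset_index(drop=True), reasons


def read_summary_stats(
    path, trait_id: str | None = None, dialect: dict | None = None
) -> SummaryStats:
    """Read a tab-separated summary-statistics table.

    ``dialect`` maps file column names onto canonical names, e.g.
    ``{"BETA": "beta", "A1": "effect_allele"}``.  Rows violating the table
    invariants are rejected with per-row reasons (``result.rejections``);
    row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"required columns missing from {path}: {missing} "
            f"(use a dialect mapping if headers differ)"
        )
    if len(df) == 0:
        raise InputError(f"empty summary-statistics table: {path}")
    clean, reasons = validate_rows(df[list(CANONICAL_COLUMNS)])
    if trait_id is None:
        from pathlib import Path

        trait_id = Path(path).stem
    return SummaryStats(trait_id=trait_id, data=clean, rejections=reasons)


def write_summary_stats(stats: SummaryStats, path) -> None:
    stats.data.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    ``data`` keeps every exposure SNP with an ``action_taken`` column;
    ``estimation_data`` restricts to rows usable for estimation
    (action ``kept`` or ``flipped``).
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame

    @property
    def estimation_data(self) -> pd.DataFrame:
        return self.data[self.data["action_taken"].isin(("kept", "flipped"))]

    @property
    def nsnp(self) -> int:
        return len(self.estimation_data)

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _is_palindromic(ea, oa):
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "drop-ambiguous",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Alignment rules, applied in order at each shared SNP:

    * identical allele coding -> ``kept``;
    * effect/other alleles swapped -> beta negated, eaf complemented,
      ``flipped``;
    * strand-complemented coding (possibly swapped) -> resolved by
      complementing the outcome alleles first;
    * palindromic SNPs (complement == swap, so alleles alone cannot resolve
      the strand): policy ``drop-all`` drops them; ``drop-ambiguous`` drops
      those with exposure eaf inside ``eaf_window`` and aligns the rest by
      allele frequency concordance; ``keep`` aligns all by frequency;
    * anything else -> ``dropped-incompatible`` (never silently kept).

    Exposure SNPs absent from the outcome are recorded ``dropped-missing``.
    """
    if palindrome_policy not in ("drop-all", "drop-ambiguous", "keep"):
        raise ConfigError(f"unknown palindrome policy: {palindrome_policy}")
    lo, hi = eaf_window

    exp = exposure.data
    out = outcome.data.set_index("snp")

    rows = []
    for rec in exp.itertuples(index=False):
        row = {
            "snp": rec.snp,
            "effect_allele": rec.effect_allele,
            "other_allele": rec.other_allele,
            "beta_exp": rec.beta,
            "se_exp": rec.se,
            "eaf_exp": rec.eaf,
            "pval_exp": rec.pval,
            "n_exp": rec.n,
            "beta_out": np.nan,
            "se_out": np.nan,
            "eaf_out": np.nan,
            "pval_out": np.nan,
            "n_out": 0,
        }
        if rec.snp not in out.index:
            row["action_taken"] = "dropped-missing"
            rows.append(row)
            continue
        o = out.loc[rec.snp]
        ea, oa = rec.effect_allele, rec.other_allele
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        beta_o, eaf_o = float(o["beta"]), float(o["eaf"])

        palindromic = _is_palindromic(ea, oa)
        action = None
        if palindromic:
            if palindrome_policy == "drop-all":
                action = "dropped-palindromic"
            elif {o_ea, o_oa} != {ea, oa}:
                action = "dropped-incompatible"
            elif palindrome_policy == "drop-ambiguous" and lo <= rec.eaf <= hi:
                action = "dropped-palindromic"
            else:
                # alleles alone cannot fix the strand; align by whether the
                # reported frequencies sit on the same side of 0.5
                if o_ea != ea:
                    beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                    action = "flipped"
                else:
                    action = "kept"
                if (rec.eaf - 0.5) * (eaf_o - 0.5) < 0:
                    beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                    action = "flipped" if action == "kept" else "kept"
        else:
            if (o_ea, o_oa) == (ea, oa):
                action = "kept"
            elif (o_ea, o_oa) == (oa, ea):
                beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                action = "flipped"
            else:
                c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
                if (c_ea, c_oa) == (ea, oa):
                    action = "kept"
                elif (c_ea, c_oa) == (oa, ea):
                    beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                    action = "flipped"
                else:
                    action = "dropped-incompatible"

        if action in ("kept", "flipped"):
            row.update(
                beta_out=beta_o,
                se_out=float(o["se"]),
                eaf_out=eaf_o,
                pval_out=float(o["pval"]),
                n_out=int(o["n"]),
            )
        row["action_taken"] = action
        rows.append(row)

    data = pd.DataFrame(rows)
    if len(data) == 0:
        data = pd.DataFrame(
            columns=[
                "snp", "effect_allele", "other_allele", "beta_exp", "se_exp",
                "eaf_exp", "pval_exp", "n_exp", "beta_out", "se_out",
                "eaf_out", "pval_out", "n_out", "action_taken",
            ]
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id, data=data
    )
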