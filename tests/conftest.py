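import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag

from mrmediate import HarmonizedSet, LDMatrix, SummaryStats


def make_sumstats(trait_id, rows):
    """Build a SummaryStats table from per-SNP dicts, filling defaults."""
    defaults = {
        "chr": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "se": 0.01,
        "pval": 1e-10,
        "n": 100_000,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = {"snp": f"rs{i + 1}", "beta": 0.1, **defaults, **row}
        recs.append(rec)
    return SummaryStats(trait_id, pd.DataFrame(recs))


def make_harmonized(bx, by, sy, sx=None, eaf=None, n_exp=100_000, n_out=100_000):
    """Harmonized set straight from effect arrays (all rows kept)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    eaf = np.full_like(bx, 0.3) if eaf is None else np.asarray(eaf, float)
    df = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(len(bx))],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": bx,
            "se_exp": sx,
            "eaf_exp": eaf,
            "pval_exp": 1e-10,
            "n_exp": n_exp,
            "beta_out": by,
            "se_out": sy,
            "eaf_out": eaf,
            "pval_out": 0.5,
            "n_out": n_out,
            "action_taken": "kept",
        }
    )
    return HarmonizedSet("exp", "out", df)


def merge_studies(triples, outcome_n=None):
    """Combine simulated studies into one panel sharing a single outcome.

    Outcome tables are concatenated (each study's SNPs keep their own
    zero/true effects) and the LD matrices stacked block-diagonally.
    SNP ids must be disjoint across studies.
    """
    out = pd.concat([t.outcome.data for t in triples], ignore_index=True)
    assert out["snp"].is_unique
    ld = LDMatrix(
        snp_ids=[s for t in triples for s in t.ld.snp_ids],
        r2=block_diag(*[t.ld.r2 for t in triples]),
        positions=pd.concat([t.ld.positions for t in triples], ignore_index=True),
    )
    return SummaryStats("panel-outcome", out), ld


@pytest.fixture
def harmonized_three():
    return make_harmonized(
        bx=[0.1, 0.15, 0.2], by=[0.02, 0.04, 0.03], sy=[0.01, 0.015, 0.02]
    )
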