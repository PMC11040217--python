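import numpy as np
import pandas as pd
import pytest

from mrmediate.summary_stats import COLUMNS, HarmonizedSet, SummaryStats


def make_hset(bx, by, sy, sx=None, exposure_names=None, outcome_name="Y"):
    """Build a HarmonizedSet directly from effect arrays (test fixture)."""
    bx = np.atleast_2d(np.asarray(bx, dtype=float))
    if bx.shape[0] == 1 and bx.shape[1] != len(by):
        bx = bx.T
    if bx.shape[0] != len(by):
        bx = bx.T
    L, K = bx.shape
    if sx is None:
        sx = np.full((L, K), 1e-6)
    else:
        sx = np.broadcast_to(np.asarray(sx, dtype=float).reshape(-1, K), (L, K)).copy()
    names = list(exposure_names) if exposure_names else [f"X{k}" for k in range(K)]
    return HarmonizedSet(
        exposure_names=names,
        outcome_name=outcome_name,
        variant_id=np.array([f"rs{i}" for i in range(L)], dtype=object),
        beta_x=bx,
        se_x=sx,
        beta_y=np.asarray(by, dtype=float),
        se_y=np.asarray(sy, dtype=float),
        eaf_exposure=np.full(L, 0.4),
        eaf_outcome=np.full(L, 0.4),
        actions=np.full(L, "kept", dtype=object),
    )


def make_stats(
    name="trait",
    trait_type="quantitative",
    variant_id=("rs1", "rs2", "rs3"),
    beta=(0.1, 0.2, 0.3),
    se=(0.01, 0.01, 0.01),
    pval=(1e-10, 1e-10, 1e-10),
    eaf=(0.2, 0.3, 0.4),
    effect_allele=("A", "C", "G"),
    other_allele=("G", "T", "A"),
    chrom=None,
    pos=None,
    n=100_000,
):
    m = len(variant_id)
    df = pd.DataFrame(
        {
            "variant_id": list(variant_id),
            "chrom": list(chrom) if chrom is not None else ["1"] * m,
            "pos": list(pos) if pos is not None else [1_000_000 + 10_000 * i for i in range(m)],
            "effect_allele": list(effect_allele),
            "other_allele": list(other_allele),
            "eaf": list(eaf),
            "beta": list(beta),
            "se": list(se),
            "pval": list(pval),
            "n": n,
        }
    )
    return SummaryStats(name, trait_type, df[list(COLUMNS)])


@pytest.fixture
def two_snp_hset():
    """The hand-checkable 2-instrument fixture: Wald ratios 0.6 and 0.4 with
    equal outcome SEs, giving IVW slope 0.44 and Q = 3.2."""
    return make_hset(bx=[0.1, 0.2], by=[0.06, 0.08], sy=[0.01, 0.01])
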