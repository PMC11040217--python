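"""Multivariable MR: direct effects of several exposures on one outcome,
with conditional instrument-strength and heterogeneity diagnostics.

The estimator is the standard summary-data MVMR regression: outcome effects
regressed on the K exposure-effect columns without intercept, weighted by the
inverse outcome variance.  The conditional F-statistic measures how much
independent signal one exposure's instruments carry after projecting out the
other exposures; the modified Cochran's Q (Q_A) measures residual
heterogeneity allowing for uncertainty in the exposure effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .summary_stats import HarmonizedSet
from .uvmr import MREstimate


class MVMRError(ValueError):
    pass


@dataclass
class MVMRResult:
    exposure_names: list[str]
    outcome_name: str
    estimates: list[MREstimate]  # one direct effect per exposure
    conditional_f: np.ndarray  # per exposure
    q_a: float
    q_a_df: int
    q_a_pval: float
    n_snp: int


def _design(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = h.beta_x
    L, K = X.shape
    if L <= K:
        raise MVMRError(f"under-identified: {L} instruments for {K} exposures")
    rank = np.linalg.matrix_rank(X)
    if rank < K:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (h.exposure_names[i], h.exposure_names[j])
            for i in range(K)
            for j in range(i + 1, K)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise MVMRError(f"rank-deficient exposure matrix; collinear exposures: {pairs}")
    w = 1.0 / h.se_y**2
    return X, w, h.beta_y


def mvmr_ivw(h: HarmonizedSet) -> tuple[list[MREstimate], np.ndarray]:
    """Direct-effect estimates (one per exposure) and the coefficient vector.

    Zero-intercept weighted regression of beta_Y on the exposure-effect
    columns with weights 1/se_Y²; per-coefficient SEs carry multiplicative
    random-effects scaling sqrt(Q_resid / (L - K)) floored at 1; two-sided
    normal p-values.
    """
    X, w, y = _design(h)
    L, K = X.shape
    xtwx = X.T @ (w[:, None] * X)
    cov_unscaled = np.linalg.inv(xtwx)
    theta = cov_unscaled @ (X.T @ (w * y))
    resid = y - X @ theta
    q_resid = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_resid / (L - K)))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    ests = [
        MREstimate.from_beta_se("mvmr_ivw", theta[k], se[k], L) for k in range(K)
    ]
    return ests, theta


def conditional_f(h: HarmonizedSet, exposure_index: int) -> float:
    """Conditional F-statistic for one exposure given the others.

    The target exposure's instrument effects are regressed (weights
    1/se_X_target², no intercept) on the other exposures' effects; the
    weighted residual sum of squares Q_x divided by the instrument count L is
    the conditional F.  With K = 1 this reduces to the mean per-instrument F,
    mean((beta_X/se_X)²).  Values below ~10 indicate conditionally weak
    instruments.
    """
    X = h.beta_x
    L, K = X.shape
    if not 0 <= exposure_index < K:
        raise IndexError("exposure_index out of range")
    t = X[:, exposure_index]
    st = h.se_x[:, exposure_index]
    w = 1.0 / st**2
    others = np.delete(X, exposure_index, axis=1)
    if others.shape[1] == 0:
        pred = np.zeros(L)
    else:
        xtwx = others.T @ (w[:, None] * others)
        coef = np.linalg.pinv(xtwx) @ (others.T @ (w * t))
        pred = others @ coef
    q_x = float(np.sum(w * (t - pred) ** 2))
    return q_x / L


def modified_q(h: HarmonizedSet, estimates: np.ndarray) -> tuple[float, int, float]:
    """Modified Cochran's Q (Q_A) for MVMR heterogeneity.

    Q_A = sum_i (beta_Y_i - sum_k theta_k beta_Xk_i)² /
          (se_Y_i² + sum_k theta_k² se_Xk_i²), chi-square with L - K df.
    Unlike the fitting weights, the denominator propagates exposure-side
    uncertainty through the fitted coefficients.
    """
    theta = np.asarray(estimates, dtype=float)
    X, y = h.beta_x, h.beta_y
    L, K = X.shape
    if theta.shape != (K,):
        raise ValueError("one coefficient per exposure required")
    num = (y - X @ theta) ** 2
    den = h.se_y**2 + (h.se_x**2) @ (theta**2)
    q_a = float(np.sum(num / den))
    df = L - K
    p = float(sps.chi2.sf(q_a, df)) if df > 0 else float("nan")
    return q_a, df, p


def mvmr_from_harmonized(h: HarmonizedSet) -> MVMRResult:
    ests, theta = mvmr_ivw(h)
    q_a, df, p = modified_q(h, theta)
    f = np.array([conditional_f(h, k) for k in range(h.n_exposures)])
    return MVMRResult(
        exposure_names=list(h.exposure_names),
        outcome_name=h.outcome_name,
        estimates=ests,
        conditional_f=f,
        q_a=q_a,
        q_a_df=df,
        q_a_pval=p,
        n_snp=h.n_snps,
    )


def run_mvmr(exposures, outcome, ld, params=None) -> MVMRResult:
    """Full multivariable chain for a list of exposure datasets.

    The instrument set is the union of each exposure's clumped genome-wide
    significant variants, re-clumped jointly on the per-variant minimum
    p-value across exposures, restricted to variants present in every
    dataset, then harmonized against the outcome.
    """
    from .summary_stats import SummaryStats, harmonize, ld_clump, select_instruments
    from .uvmr import MRParams

    params = params or MRParams()
    per_exp = []
    for ex in exposures:
        inst = select_instruments(ex, params.p_threshold)
        per_exp.append(ld_clump(inst, ld, params.r2_threshold, params.window_kb))

    rows = {}
    for sel, ex in zip(per_exp, exposures):
        for row in sel.df.itertuples(index=False):
            cur = rows.get(row.variant_id)
            if cur is None or row.pval < cur.pval:
                rows[row.variant_id] = row
    if not rows:
        raise MVMRError("no instruments for any exposure")
    import pandas as pd

    union = SummaryStats(
        "union", "quantitative", pd.DataFrame(list(rows.values()))
    )
    union = ld_clump(union, ld, params.r2_threshold, params.window_kb)
    ids = list(union.df["variant_id"])

    subsets = []
    for ex in exposures:
        present = set(ex.df["variant_id"])
        ids = [v for v in ids if v in present]
    ids = [v for v in ids if v in set(outcome.df["variant_id"])]
    for ex in exposures:
        subsets.append(ex.subset(ids))
    h = harmonize(subsets, outcome, params.palindrome_maf)
    return mvmr_from_harmonized(h)
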