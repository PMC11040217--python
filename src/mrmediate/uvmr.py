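"""Univariable two-sample MR estimators and their diagnostics.

All estimators consume a single-exposure :class:`~mrmediate.summary_stats.HarmonizedSet`
and treat each instrument's Wald ratio (outcome effect over exposure effect)
as an estimate of the same causal effect.  The inverse-variance-weighted (IVW)
estimator is their precision-weighted mean, fitted as a zero-intercept weighted
regression of outcome effects on exposure effects; MR-Egger adds an intercept
that absorbs average directional pleiotropy; the weighted median is consistent
when at least half of the instrument weight is valid.  Standard errors for IVW
and Egger use multiplicative random effects — the fixed-effect SE scaled by
sqrt(Q / df), floored at 1 — so between-instrument heterogeneity widens, and
never narrows, the intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .summary_stats import HarmonizedSet

Z975 = float(sps.norm.ppf(0.975))


@dataclass
class MREstimate:
    method: str  # ivw | egger | weighted_median | wald | mvmr_ivw | ...
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     df: int | None = None) -> "MREstimate":
        """Build from a point estimate and SE; normal reference distribution
        unless ``df`` is given (then Student t, as for MR-Egger)."""
        beta, se = float(beta), float(se)
        if df is None:
            crit = Z975
            p = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = float(sps.t.ppf(0.975, df))
            p = 2.0 * sps.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        return cls(method, beta, se, beta - crit * se, beta + crit * se, p, int(n_snp))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class MRUnavailable:
    """Marker for an estimator that cannot run on the data it was given
    (typically too few instruments).  Carried as data, not an exception, so
    sweeps over many traits never abort."""

    method: str
    reason: str


@dataclass
class UVMRDiagnostics:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    i2_gx: float
    i2_gx_flag: bool  # true when I²GX < 0.9 (Egger dilution-bias caution)


def _check_single(h: HarmonizedSet) -> None:
    if h.n_exposures != 1:
        raise ValueError("univariable estimator requires a single-exposure set")


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument causal-effect ratios beta_Y/beta_X with first-order
    SEs se_Y/|beta_X|.  Instruments with beta_X = 0 are excluded."""
    _check_single(h)
    bx, by, sy = h.bx, h.beta_y, h.se_y
    ok = bx != 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} instrument(s) with zero exposure effect")
    return by[ok] / bx[ok], sy[ok] / np.abs(bx[ok])


def ivw(h: HarmonizedSet) -> tuple[MREstimate, float]:
    """Random-effects IVW estimate and its Cochran's Q.

    With one instrument, falls back to the Wald ratio (method 'wald', Q = 0).
    """
    _check_single(h)
    L = h.n_snps
    if L < 1:
        raise ValueError("IVW requires at least one instrument")
    bx, by, sy = h.bx, h.beta_y, h.se_y
    if L == 1:
        est = MREstimate.from_beta_se("wald", by[0] / bx[0], sy[0] / abs(bx[0]), 1)
        return est, 0.0
    w = 1.0 / sy**2
    theta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    q = float(np.sum(w * (by - theta * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (L - 1)))
    est = MREstimate.from_beta_se("ivw", theta, se_fixed * scale, L)
    return est, q


def _orient(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flip instrument signs so exposure effects are non-negative."""
    s = np.where(h.bx < 0, -1.0, 1.0)
    return s * h.bx, h.sx, s * h.beta_y, h.se_y


def mr_egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate] | MRUnavailable:
    """MR-Egger regression: weighted regression of outcome effects on
    (sign-oriented) exposure effects with an intercept.

    Returns (slope estimate, intercept estimate); the intercept is the average
    directional pleiotropy per instrument.  Both use multiplicative
    random-effects scaling (floored at 1) and t reference with L - 2 df.
    Needs at least 3 instruments.
    """
    _check_single(h)
    L = h.n_snps
    if L < 3:
        return MRUnavailable("egger", f"requires >= 3 instruments, have {L}")
    x, _, y, sy = _orient(h)
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ xtwy
    resid = y - X @ coef
    q_egger = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_egger / (L - 2)))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    slope = MREstimate.from_beta_se("egger", coef[1], se[1], L, df=L - 2)
    intercept = MREstimate.from_beta_se("egger_intercept", coef[0], se[0], L, df=L - 2)
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] < 0.5:
        return float(v[-1])
    k = int(np.searchsorted(cum, 0.5))  # cum[k-1] < 0.5 <= cum[k]
    frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(v[k - 1] + frac * (v[k] - v[k - 1]))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate | MRUnavailable:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Wald ratios are ordered; with inverse-variance weights normalised to sum
    one, the estimate is the ratio value where the midpoint cumulative weight
    crosses 0.5 (linear interpolation between adjacent ratios).  The SE is the
    standard deviation of the weighted median over ``n_boot`` parametric
    resamples ratio_j ~ Normal(ratio_j, se_j²).  Needs >= 3 instruments.
    """
    _check_single(h)
    if h.n_snps < 3:
        return MRUnavailable("weighted_median", f"requires >= 3 instruments, have {h.n_snps}")
    r, s = wald_ratios(h)
    w = 1.0 / s**2
    point = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(r, s, size=(n_boot, len(r)))
    order = np.argsort(draws, axis=1, kind="mergesort")
    v = np.take_along_axis(draws, order, axis=1)
    wmat = (w / w.sum())[None, :] * np.ones((n_boot, 1))
    wmat = np.take_along_axis(wmat, order, axis=1)
    cum = np.cumsum(wmat, axis=1) - 0.5 * wmat
    boots = np.empty(n_boot)
    for i in range(n_boot):  # small per-row interpolation
        ci, vi = cum[i], v[i]
        if ci[0] >= 0.5:
            boots[i] = vi[0]
        elif ci[-1] < 0.5:
            boots[i] = vi[-1]
        else:
            k = int(np.searchsorted(ci, 0.5))
            boots[i] = vi[k - 1] + (0.5 - ci[k - 1]) / (ci[k] - ci[k - 1]) * (vi[k] - vi[k - 1])
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", point, se, h.n_snps)


def i2_gx(h: HarmonizedSet) -> float:
    """I²GX statistic for the MR-Egger no-measurement-error (NOME) assumption.

    With weights 1/se_X², Q_GX is the weighted dispersion of the (oriented)
    exposure effects around their weighted mean; I²GX = (Q_GX - (L-1))/Q_GX,
    floored at 0.  Values below 0.9 indicate regression-dilution bias in the
    Egger slope.
    """
    _check_single(h)
    if h.n_snps < 2:
        raise ValueError("I2_GX requires at least 2 instruments")
    x, sx, _, _ = _orient(h)
    w = 1.0 / sx**2
    mean = np.sum(w * x) / np.sum(w)
    q_gx = float(np.sum(w * (x - mean) ** 2))
    if q_gx == 0.0:
        return 0.0
    return max(0.0, (q_gx - (h.n_snps - 1)) / q_gx)


@dataclass
class MRParams:
    """Thresholds and knobs shared by the pipeline stages (defaults follow the
    usual two-sample MR conventions: genome-wide significance 5e-8, clumping
    r² 0.001 within 10,000 kb, proxy r² 0.8, palindromic-MAF cutoff 0.3)."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    proxy_r2_min: float = 0.8
    palindrome_maf: float = 0.3
    n_boot: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median")


@dataclass
class UVMRResult:
    exposure: str
    outcome: str
    estimates: dict = field(default_factory=dict)  # method -> MREstimate | MRUnavailable
    diagnostics: UVMRDiagnostics | None = None
    harmonized: HarmonizedSet | None = None
    analyzable: bool = True
    reason: str = ""

    @property
    def ivw_estimate(self) -> MREstimate | None:
        est = self.estimates.get("ivw") or self.estimates.get("wald")
        return est if isinstance(est, MREstimate) else None


def uvmr_from_harmonized(h: HarmonizedSet, params: MRParams | None = None) -> UVMRResult:
    params = params or MRParams()
    res = UVMRResult(exposure=h.exposure_names[0], outcome=h.outcome_name, harmonized=h)
    est, q = ivw(h)
    res.estimates[est.method] = est
    L = h.n_snps
    eg = mr_egger(h) if "egger" in params.methods else None
    intercept = None
    if isinstance(eg, tuple):
        res.estimates["egger"], intercept = eg
    elif isinstance(eg, MRUnavailable):
        res.estimates["egger"] = eg
    if "weighted_median" in params.methods:
        res.estimates["weighted_median"] = weighted_median(
            h, n_boot=params.n_boot, seed=params.seed
        )
    i2 = i2_gx(h) if L >= 2 else 0.0
    res.diagnostics = UVMRDiagnostics(
        q_stat=q,
        q_df=max(L - 1, 0),
        q_pval=float(sps.chi2.sf(q, L - 1)) if L > 1 else 1.0,
        egger_intercept=intercept.beta if intercept else None,
        egger_intercept_se=intercept.se if intercept else None,
        egger_intercept_pval=intercept.pval if intercept else None,
        i2_gx=i2,
        i2_gx_flag=i2 < 0.9,
    )
    return res


def run_uvmr(exposure, outcome, ld, params: MRParams | None = None,
             proxy_table=None) -> UVMRResult:
    """Full univariable chain: select instruments → LD clump → (proxy
    substitution for instruments absent from the outcome data) → harmonize →
    estimate.  A trait with no usable instruments is returned as
    not-analyzable rather than raising."""
    from .summary_stats import (
        HarmonizationError, apply_proxies, harmonize, ld_clump,
        select_instruments, substitute_proxies,
    )

    params = params or MRParams()
    inst = select_instruments(exposure, params.p_threshold)
    if inst.n_variants == 0:
        return UVMRResult(exposure.trait_name, outcome.trait_name,
                          analyzable=False, reason="no genome-wide-significant instruments")
    inst = ld_clump(inst, ld, params.r2_threshold, params.window_kb)
    if proxy_table is not None:
        outcome_ids = set(outcome.df["variant_id"])
        missing = [v for v in inst.df["variant_id"] if v not in outcome_ids]
        if missing:
            mapping, _dropped = substitute_proxies(
                missing, proxy_table, outcome_ids, params.proxy_r2_min
            )
            inst = apply_proxies(inst, mapping, proxy_table)
    try:
        h = harmonize([inst], outcome, params.palindrome_maf)
    except HarmonizationError as exc:
        return UVMRResult(exposure.trait_name, outcome.trait_name,
                          analyzable=False, reason=str(exc))
    return uvmr_from_harmonized(h, params)
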