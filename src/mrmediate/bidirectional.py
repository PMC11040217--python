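"""Bidirectional MR screening: is a trait a cause, a consequence, or both,
of the mediator?

Instruments are selected independently per direction (the trait's own
genome-wide-significant loci for trait → mediator, the mediator's loci for
mediator → trait).  The IVW estimate is the classifying statistic; the two
FDR-adjusted p-values against the significance threshold determine the
class.  Traits classified 'forward_only' are causes but not consequences of
the mediator and thus remain eligible for mediation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fdr import bh_fdr
from .summary_stats import LDTable, SummaryStats
from .uvmr import MRParams, UVMRResult, run_uvmr


@dataclass
class DirectionResult:
    trait: str
    forward: UVMRResult | None
    reverse: UVMRResult | None
    p_forward_adj: float
    p_reverse_adj: float
    classification: str  # forward_only | reverse_only | bidirectional | none
    forward_assessable: bool = True
    reverse_assessable: bool = True


def classify_from_adjusted(
    p_forward_adj: float,
    p_reverse_adj: float,
    alpha: float = 0.05,
    forward_assessable: bool = True,
    reverse_assessable: bool = True,
) -> str:
    """Pure classification rule: significance in each adjusted direction.
    A non-assessable direction counts as non-significant (the trait carries
    an assessability flag so callers can treat it cautiously)."""
    fwd = forward_assessable and p_forward_adj < alpha
    rev = reverse_assessable and p_reverse_adj < alpha
    if fwd and rev:
        return "bidirectional"
    if fwd:
        return "forward_only"
    if rev:
        return "reverse_only"
    return "none"


def _adjusted(p: float, family) -> float:
    """Adjust ``p`` within its family of sibling raw p-values (BH)."""
    if family is None or len(family) == 0:
        return p
    fam = np.concatenate([[p], np.asarray(family, dtype=float)])
    return float(bh_fdr(fam)[0])


def classify_direction(
    trait: SummaryStats,
    mediator: SummaryStats,
    ld: LDTable,
    params: MRParams | None = None,
    alpha_fdr: float = 0.05,
    forward_family=None,
    reverse_family=None,
) -> DirectionResult:
    """Run MR in both directions between a trait and the mediator and
    classify the causal direction.

    ``forward_family``/``reverse_family`` optionally supply the sibling raw
    p-values of the multiple-testing family each direction belongs to (e.g.
    the other screened traits); adjustment is BH within that family.
    """
    params = params or MRParams()
    fwd = run_uvmr(trait, mediator, ld, params)
    rev = run_uvmr(mediator, trait, ld, params)
    f_ok = fwd.analyzable and fwd.ivw_estimate is not None
    r_ok = rev.analyzable and rev.ivw_estimate is not None
    p_f = _adjusted(fwd.ivw_estimate.pval, forward_family) if f_ok else float("nan")
    p_r = _adjusted(rev.ivw_estimate.pval, reverse_family) if r_ok else float("nan")
    cls = classify_from_adjusted(p_f, p_r, alpha_fdr, f_ok, r_ok)
    return DirectionResult(
        trait=trait.trait_name,
        forward=fwd,
        reverse=rev,
        p_forward_adj=p_f,
        p_reverse_adj=p_r,
        classification=cls,
        forward_assessable=f_ok,
        reverse_assessable=r_ok,
    )
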