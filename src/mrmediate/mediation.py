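"""Two-step MR mediation: indirect effects and proportion mediated.

The causal chain is trait → mediator → outcome.  Step 1 estimates the
trait→mediator effect `a` by univariable MR; step 2 estimates the
trait-adjusted mediator→outcome effect `b` from MVMR of (trait, mediator) on
the outcome.  The indirect effect is the product a·b, the total effect `c`
comes from univariable trait→outcome MR, and the proportion mediated is
a·b / c.  Standard errors use the first-order delta method with zero
cross-covariance, which the two-sample design (independent GWAS cohorts for
each leg) justifies.  The proportion mediated is reported unclamped: values
outside [0, 1] or with sign opposite to the total effect are flagged rather
than hidden, since they are diagnostically meaningful (e.g. a direct effect
opposing the indirect pathway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .uvmr import MREstimate, MRParams, Z975, run_uvmr
from .mvmr import MVMRError, MVMRResult, run_mvmr


def indirect_effect(a: MREstimate, b: MREstimate) -> MREstimate:
    """Product-of-coefficients indirect effect a·b.

    Delta-method SE: sqrt(a² · se_b² + b² · se_a²) (first order, zero
    cross-covariance between the two legs).
    """
    beta = a.beta * b.beta
    se = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
    return MREstimate.from_beta_se("indirect", beta, se, min(a.n_snp, b.n_snp))


@dataclass
class ProportionMediated:
    pm: float
    se: float
    ci_low: float
    ci_high: float
    sign_inconsistent: bool
    out_of_unit_interval: bool
    undefined: bool = False


def proportion_mediated(indirect: MREstimate, total: MREstimate) -> ProportionMediated:
    """PM = indirect/total with delta-method SE for the ratio.

    se(PM) = |PM| · sqrt((se_ind/ind)² + (se_tot/tot)²), zero cross-covariance.
    A zero total effect yields an undefined-result marker, never a division
    error.
    """
    if total.beta == 0:
        return ProportionMediated(float("nan"), float("nan"), float("nan"),
                                  float("nan"), False, False, undefined=True)
    pm = indirect.beta / total.beta
    if indirect.beta == 0:
        se = abs(indirect.se / total.beta)
    else:
        se = abs(pm) * float(
            np.sqrt((indirect.se / indirect.beta) ** 2 + (total.se / total.beta) ** 2)
        )
    return ProportionMediated(
        pm=float(pm),
        se=se,
        ci_low=pm - Z975 * se,
        ci_high=pm + Z975 * se,
        sign_inconsistent=bool(np.sign(indirect.beta) != np.sign(total.beta)
                               and indirect.beta != 0),
        out_of_unit_interval=not (0.0 <= pm <= 1.0),
    )


@dataclass
class MediationResult:
    trait: str
    outcome: str
    total: MREstimate | None = None  # c, UVMR trait -> outcome
    direct: MREstimate | None = None  # c', MVMR trait coefficient
    a: MREstimate | None = None  # UVMR trait -> mediator
    b: MREstimate | None = None  # MVMR mediator coefficient
    indirect: MREstimate | None = None  # a*b
    pm: ProportionMediated | None = None
    mvmr: MVMRResult | None = None
    withheld: bool = False
    reason: str = ""
    # diagnostics carried for reporting
    extras: dict = field(default_factory=dict)


def run_mediation(trait, mediator, outcome, ld, params: MRParams | None = None) -> MediationResult:
    """Full 2-step MR for one (trait, outcome) pair.

    total: UVMR trait→outcome; a: UVMR trait→mediator; (c', b): MVMR of
    (trait, mediator) on the outcome.  Any leg that cannot be analyzed
    withholds the result with the reason recorded.
    """
    params = params or MRParams()
    res = MediationResult(trait=trait.trait_name, outcome=outcome.trait_name)

    total_run = run_uvmr(trait, outcome, ld, params)
    if not total_run.analyzable or total_run.ivw_estimate is None:
        res.withheld, res.reason = True, f"total effect leg: {total_run.reason or 'no estimate'}"
        return res
    a_run = run_uvmr(trait, mediator, ld, params)
    if not a_run.analyzable or a_run.ivw_estimate is None:
        res.withheld, res.reason = True, f"trait->mediator leg: {a_run.reason or 'no estimate'}"
        return res
    try:
        mv = run_mvmr([trait, mediator], outcome, ld, params)
    except (MVMRError, ValueError) as exc:
        res.withheld, res.reason = True, f"MVMR leg: {exc}"
        return res

    res.total = total_run.ivw_estimate
    res.a = a_run.ivw_estimate
    res.direct, res.b = mv.estimates[0], mv.estimates[1]
    res.mvmr = mv
    res.indirect = indirect_effect(res.a, res.b)
    res.pm = proportion_mediated(res.indirect, res.total)
    res.extras = {
        "total_diagnostics": total_run.diagnostics,
        "a_diagnostics": a_run.diagnostics,
    }
    return res
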