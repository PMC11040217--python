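"""Study orchestration: screen a trait panel against the mediator and the
stroke outcomes, control the FDR, apply the eligibility rules, and run
mediation for every eligible (trait, outcome) pair.

The eligibility rules mirror the study funnel: a trait enters mediation
analysis iff it (1) has an FDR-significant effect on the mediator, (2) has no
bidirectional relationship with the mediator, and (3) is putatively causal
for at least one outcome.  Mediation is then run per (trait, outcome) pair
restricted to outcomes that are themselves causally affected by the mediator
and for which the trait is FDR-significant.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._fdr import bh_fdr  # noqa: F401  (re-exported: FDR control lives here)
from .bidirectional import DirectionResult, classify_from_adjusted
from .mediation import MediationResult, run_mediation
from .summary_stats import LDTable, SummaryStats, read_gwas
from .uvmr import MREstimate, MRParams, run_uvmr

__all__ = [
    "bh_fdr",
    "StudyConfig",
    "EligibilityRecord",
    "StudyReport",
    "determine_mediator_outcomes",
    "select_eligible",
    "run_study",
    "run_pipeline",
]


@dataclass
class StudyConfig:
    """File-based configuration of a full pipeline run."""

    trait_files: list[str]
    mediator_file: str
    outcome_files: list[str]
    ld_file: str
    out_dir: str
    proxy_file: str | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    proxy_r2: float = 0.8
    palindrome_maf: float = 0.3
    alpha_fdr: float = 0.05
    fdr_family: str = "per_outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in [*self.trait_files, self.mediator_file, *self.outcome_files, self.ld_file]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        if self.proxy_file is not None and not os.path.exists(self.proxy_file):
            raise FileNotFoundError(self.proxy_file)
        for name, val, lo, hi in [
            ("p_instrument", self.p_instrument, 0, 1),
            ("clump_r2", self.clump_r2, 0, 1),
            ("proxy_r2", self.proxy_r2, 0, 1),
            ("palindrome_maf", self.palindrome_maf, 0, 0.5),
            ("alpha_fdr", self.alpha_fdr, 0, 1),
        ]:
            if not lo <= val <= hi:
                raise ValueError(f"{name} = {val} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def params(self) -> MRParams:
        return MRParams(
            p_threshold=self.p_instrument,
            r2_threshold=self.clump_r2,
            window_kb=self.clump_window_kb,
            proxy_r2_min=self.proxy_r2,
            palindrome_maf=self.palindrome_maf,
            seed=self.seed,
        )


@dataclass
class EligibilityRecord:
    trait: str
    rule1_effect_on_mediator: bool
    rule2_not_bidirectional: bool
    rule3_causal_for_any_outcome: bool
    eligible_outcomes: list[str] = field(default_factory=list)
    trace: list[str] = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return (
            self.rule1_effect_on_mediator
            and self.rule2_not_bidirectional
            and self.rule3_causal_for_any_outcome
        )


def determine_mediator_outcomes(
    mediator_pfdr: Mapping[str, float], alpha: float = 0.05
) -> list[str]:
    """Outcomes the mediator itself causally affects (FDR-significant)."""
    return [o for o, p in mediator_pfdr.items() if np.isfinite(p) and p < alpha]


def select_eligible(
    trait_names,
    trait_mediator_pfdr: Mapping[str, float],
    directions: Mapping[str, DirectionResult],
    trait_outcome_pfdr: Mapping[tuple[str, str], float],
    mediator_outcomes,
    alpha: float = 0.05,
) -> list[EligibilityRecord]:
    """Apply the three eligibility rules and record the evidence trail."""
    records = []
    for t in trait_names:
        p1 = trait_mediator_pfdr.get(t, float("nan"))
        rule1 = np.isfinite(p1) and p1 < alpha
        d = directions.get(t)
        rule2 = d is not None and d.classification == "forward_only"
        sig_outcomes = [
            o for (tt, o), p in trait_outcome_pfdr.items()
            if tt == t and np.isfinite(p) and p < alpha
        ]
        rule3 = len(sig_outcomes) > 0
        rec = EligibilityRecord(
            trait=t,
            rule1_effect_on_mediator=bool(rule1),
            rule2_not_bidirectional=bool(rule2),
            rule3_causal_for_any_outcome=bool(rule3),
            trace=[
                f"rule1: p_FDR(trait->mediator) = {p1:.3g}",
                f"rule2: direction = {d.classification if d else 'not assessed'}",
                f"rule3: significant outcomes = {sorted(sig_outcomes)}",
            ],
        )
        if rec.eligible:
            rec.eligible_outcomes = sorted(set(sig_outcomes) & set(mediator_outcomes))
        records.append(rec)
    return records


@dataclass
class StudyReport:
    screen: pd.DataFrame
    diagnostics: pd.DataFrame
    directions: pd.DataFrame
    eligibility: pd.DataFrame
    mvmr: pd.DataFrame
    mediation: pd.DataFrame
    funnel: dict
    mediator_outcomes: list[str]
    mediation_results: list[MediationResult] = field(default_factory=list)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name in ("screen", "diagnostics", "directions", "eligibility", "mvmr", "mediation"):
            getattr(self, name).to_csv(os.path.join(out_dir, f"{name}.tsv"),
                                       sep="\t", index=False)
        with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
            json.dump(
                {"funnel": self.funnel, "mediator_outcomes": sorted(self.mediator_outcomes)},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def _estimate_row(exposure, outcome, method, est) -> dict:
    if isinstance(est, MREstimate):
        return {
            "exposure": exposure, "outcome": outcome, "method": method,
            "beta": est.beta, "se": est.se, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "pval": est.pval,
            "odds_ratio": est.odds_ratio, "n_snp": est.n_snp, "note": "",
        }
    note = getattr(est, "reason", "unavailable")
    return {
        "exposure": exposure, "outcome": outcome, "method": method,
        "beta": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "pval": np.nan, "odds_ratio": np.nan, "n_snp": 0, "note": note,
    }


def run_study(
    traits: Mapping[str, SummaryStats],
    mediator: SummaryStats,
    outcomes: Mapping[str, SummaryStats],
    ld: LDTable,
    params: MRParams | None = None,
    alpha_fdr: float = 0.05,
    proxy_table: pd.DataFrame | None = None,
) -> StudyReport:
    """Execute the full study flow on in-memory datasets.

    FDR families: the screen adjusts within each outcome across exposures
    (the mediator included); each bidirectional direction adjusts across
    traits.  Per-trait failures are quarantined as not-analyzable rows, never
    aborting the run.
    """
    params = params or MRParams()
    trait_names = list(traits)
    outcome_names = list(outcomes)

    # --- UVMR screen: every exposure (traits + mediator) x every outcome
    screen_rows, diag_rows = [], []
    ivw_p: dict[tuple[str, str], float] = {}
    for oname in outcome_names:
        for ename in [*trait_names, mediator.trait_name]:
            exp = traits[ename] if ename in traits else mediator
            res = run_uvmr(exp, outcomes[oname], ld, params, proxy_table=proxy_table)
            if not res.analyzable:
                screen_rows.append(_estimate_row(ename, oname, "ivw", res))
                continue
            for method, est in res.estimates.items():
                screen_rows.append(_estimate_row(ename, oname, method, est))
            d = res.diagnostics
            diag_rows.append({
                "exposure": ename, "outcome": oname, "q_stat": d.q_stat,
                "q_df": d.q_df, "q_pval": d.q_pval,
                "egger_intercept": d.egger_intercept,
                "egger_intercept_pval": d.egger_intercept_pval,
                "i2_gx": d.i2_gx, "i2_gx_flag": d.i2_gx_flag,
            })
            if res.ivw_estimate is not None:
                ivw_p[(ename, oname)] = res.ivw_estimate.pval

    # FDR within each outcome family
    screen_pfdr: dict[tuple[str, str], float] = {}
    for oname in outcome_names:
        keys = [k for k in ivw_p if k[1] == oname]
        if keys:
            adj = bh_fdr([ivw_p[k] for k in keys])
            screen_pfdr.update(dict(zip(keys, adj)))

    # --- bidirectional stage (traits vs mediator), FDR across traits per direction
    fwd_runs, rev_runs = {}, {}
    for t in trait_names:
        fwd_runs[t] = run_uvmr(traits[t], mediator, ld, params, proxy_table=proxy_table)
        rev_runs[t] = run_uvmr(mediator, traits[t], ld, params, proxy_table=proxy_table)
    fwd_ok = {t: fwd_runs[t].ivw_estimate is not None for t in trait_names}
    rev_ok = {t: rev_runs[t].ivw_estimate is not None for t in trait_names}
    fwd_keys = [t for t in trait_names if fwd_ok[t]]
    rev_keys = [t for t in trait_names if rev_ok[t]]
    fwd_adj = dict(zip(fwd_keys, bh_fdr([fwd_runs[t].ivw_estimate.pval for t in fwd_keys]))) if fwd_keys else {}
    rev_adj = dict(zip(rev_keys, bh_fdr([rev_runs[t].ivw_estimate.pval for t in rev_keys]))) if rev_keys else {}

    directions: dict[str, DirectionResult] = {}
    dir_rows = []
    for t in trait_names:
        p_f = fwd_adj.get(t, float("nan"))
        p_r = rev_adj.get(t, float("nan"))
        cls = classify_from_adjusted(p_f, p_r, alpha_fdr, fwd_ok[t], rev_ok[t])
        directions[t] = DirectionResult(
            trait=t, forward=fwd_runs[t], reverse=rev_runs[t],
            p_forward_adj=p_f, p_reverse_adj=p_r, classification=cls,
            forward_assessable=fwd_ok[t], reverse_assessable=rev_ok[t],
        )
        fe, re_ = fwd_runs[t].ivw_estimate, rev_runs[t].ivw_estimate
        dir_rows.append({
            "trait": t,
            "beta_forward": fe.beta if fe else np.nan,
            "p_forward_adj": p_f,
            "beta_reverse": re_.beta if re_ else np.nan,
            "p_reverse_adj": p_r,
            "classification": cls,
            "forward_assessable": fwd_ok[t],
            "reverse_assessable": rev_ok[t],
        })

    # --- eligibility
    mediator_pfdr = {o: screen_pfdr.get((mediator.trait_name, o), float("nan"))
                     for o in outcome_names}
    mediator_outcomes = determine_mediator_outcomes(mediator_pfdr, alpha_fdr)
    trait_outcome_pfdr = {k: v for k, v in screen_pfdr.items() if k[0] != mediator.trait_name}
    records = select_eligible(
        trait_names, fwd_adj, directions, trait_outcome_pfdr, mediator_outcomes, alpha_fdr
    )
    elig_rows = [{
        "trait": r.trait,
        "rule1_effect_on_mediator": r.rule1_effect_on_mediator,
        "rule2_not_bidirectional": r.rule2_not_bidirectional,
        "rule3_causal_for_any_outcome": r.rule3_causal_for_any_outcome,
        "eligible": r.eligible,
        "eligible_outcomes": ",".join(r.eligible_outcomes),
        "trace": " | ".join(r.trace),
    } for r in records]

    # --- mediation per eligible (trait, outcome) task
    med_rows, mvmr_rows, med_results = [], [], []
    tasks = [(r.trait, o) for r in records if r.eligible for o in r.eligible_outcomes]
    for tname, oname in tasks:
        m = run_mediation(traits[tname], mediator, outcomes[oname], ld, params)
        med_results.append(m)
        if m.withheld:
            med_rows.append({"trait": tname, "outcome": oname, "withheld": True,
                             "reason": m.reason})
            continue
        med_rows.append({
            "trait": tname, "outcome": oname, "withheld": False, "reason": "",
            "total_beta": m.total.beta, "total_se": m.total.se,
            "direct_beta": m.direct.beta, "direct_se": m.direct.se,
            "a_beta": m.a.beta, "a_se": m.a.se,
            "b_beta": m.b.beta, "b_se": m.b.se,
            "indirect_beta": m.indirect.beta, "indirect_se": m.indirect.se,
            "proportion_mediated_pct": 100.0 * m.pm.pm,
            "pm_se_pct": 100.0 * m.pm.se,
            "pm_ci_low_pct": 100.0 * m.pm.ci_low,
            "pm_ci_high_pct": 100.0 * m.pm.ci_high,
            "sign_inconsistent": m.pm.sign_inconsistent,
            "out_of_unit_interval": m.pm.out_of_unit_interval,
        })
        mv = m.mvmr
        for k, ename in enumerate(mv.exposure_names):
            est = mv.estimates[k]
            mvmr_rows.append({
                "trait": tname, "outcome": oname, "exposure": ename,
                "direct_beta": est.beta, "direct_se": est.se, "direct_pval": est.pval,
                "conditional_f": mv.conditional_f[k],
                "q_a": mv.q_a, "q_a_df": mv.q_a_df, "q_a_pval": mv.q_a_pval,
                "n_snp": mv.n_snp,
            })

    n_rule3 = sum(r.rule3_causal_for_any_outcome for r in records)
    n_rule13 = sum(r.rule3_causal_for_any_outcome and r.rule1_effect_on_mediator
                   for r in records)
    funnel = {
        "traits_screened": len(trait_names),
        "causal_for_any_outcome": n_rule3,
        "and_affect_mediator": n_rule13,
        "eligible_not_bidirectional": sum(r.eligible for r in records),
        "mediation_tasks": len(tasks),
        "mediation_completed": sum(not m.withheld for m in med_results),
    }

    empty = lambda cols: pd.DataFrame(columns=cols)  # noqa: E731
    return StudyReport(
        screen=pd.DataFrame(screen_rows),
        diagnostics=pd.DataFrame(diag_rows),
        directions=pd.DataFrame(dir_rows),
        eligibility=pd.DataFrame(elig_rows),
        mvmr=pd.DataFrame(mvmr_rows) if mvmr_rows else empty(
            ["trait", "outcome", "exposure", "direct_beta", "direct_se",
             "direct_pval", "conditional_f", "q_a", "q_a_df", "q_a_pval", "n_snp"]),
        mediation=pd.DataFrame(med_rows) if med_rows else empty(
            ["trait", "outcome", "withheld", "reason"]),
        funnel=funnel,
        mediator_outcomes=mediator_outcomes,
        mediation_results=med_results,
    )


def run_pipeline(config: StudyConfig) -> StudyReport:
    """File-based entry point: read all datasets, run the study, write the
    report bundle (TSV tables plus a machine-readable run log) to
    ``config.out_dir``.  Reruns with the same config and seed are
    byte-identical."""
    traits = {}
    for p in config.trait_files:
        s = read_gwas(p, trait_name=os.path.splitext(os.path.basename(p))[0])
        traits[s.trait_name] = s
    mediator = read_gwas(
        config.mediator_file, trait_type="binary",
        trait_name=os.path.splitext(os.path.basename(config.mediator_file))[0],
    )
    outcomes = {}
    for p in config.outcome_files:
        s = read_gwas(p, trait_type="binary",
                      trait_name=os.path.splitext(os.path.basename(p))[0])
        outcomes[s.trait_name] = s
    ld = LDTable.read(config.ld_file)
    proxy = pd.read_csv(config.proxy_file, sep="\t") if config.proxy_file else None
    report = run_study(traits, mediator, outcomes, ld, config.params(),
                       config.alpha_fdr, proxy_table=proxy)
    report.write(config.out_dir)
    return report
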