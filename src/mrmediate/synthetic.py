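"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the data a trait → atrial-fibrillation → stroke
mediation study consumes: three (or more) independent GWAS cohorts whose
per-variant effects follow a linear structural model,

    exposure SNPs:  direct effect gamma_j ~ N(0, effect_sd²) on the exposure
    mediator SNPs:  direct effect delta_m ~ N(0, mediator_effect_sd²) on the
                    mediator (the mediator's own susceptibility loci)
    mediator      = a · exposure (+ per-SNP pleiotropy on invalid instruments)
    outcome       = c' · exposure + b · mediator
    reverse path  : mediator → exposure with coefficient `reverse_effect`

Summary statistics are simulated directly on the marginal-effect scale:
observed beta = LD-marginalised true effect + normal noise whose SE follows
the usual GWAS formula (binary traits, log-odds scale:
se = 1/sqrt(n · cf(1-cf) · 2 · eaf(1-eaf)); quantitative traits, SD units:
se = 1/sqrt(n · 2 · eaf(1-eaf))).  LD comes as equicorrelated blocks with
within-block r² = ld_rho; marginal effects and estimation noise are both
correlated with sqrt(ld_rho) inside a block.  Each cohort uses independent
noise, so the two-sample (no overlap) assumption holds exactly.

Directional pleiotropy is defined relative to the exposure-increasing allele
of the instrument as observed (the marginal effect): invalid instruments
receive an extra marginal mediator effect sign(marginal gamma_j) · alpha_j
with alpha_j ~ N(pleiotropy_mean, pleiotropy_sd²) ('directional') or
N(0, pleiotropy_sd²) ('balanced').  The InSIDE assumption holds, so a
directional mean biases IVW while MR-Egger's intercept absorbs it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .summary_stats import LDTable, SummaryStats, ValidationError

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one trait → mediator → outcome system.

    Defaults emulate the scale of the real study's ingredients: a large meta-analysis
    quantitative exposure (n = 1M), a large binary-mediator GWAS
    (n ≈ 1.03M, ~5.9% cases, the 2018 AF meta-analysis scale) and a binary
    stroke outcome (n ≈ 447k, ~9% cases, MEGASTROKE scale); ~200 exposure
    loci (the scale of a well-powered polygenic trait) with per-SNP effects
    of SD 0.02 phenotype-SD units and ~80 mediator loci of SD 0.05 log-odds,
    about a third of the exposure loci sitting in 3-SNP LD blocks of
    r² = 0.9.
    """

    n_snps_exposure: int = 200
    n_snps_mediator: int = 80
    ld_block_sizes: tuple[int, ...] = (3,) * 20
    ld_rho: float = 0.9
    effect_sd: float = 0.02
    mediator_effect_sd: float = 0.05
    a_true: float = 0.4
    b_true: float = 0.8
    c_prime_true: float = 0.1
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.03
    invalid_fraction: float = 0.0
    reverse_effect: float = 0.0
    n_exposure: int = 1_000_000
    n_mediator: int = 1_030_836
    n_outcome: int = 446_696
    case_fraction_mediator: float = 0.059
    case_fraction_outcome: float = 0.09
    exposure_trait_type: str = "quantitative"
    allele_flip_fraction: float = 0.3
    seed: int = 0
    noise_seed: int | None = None  # re-draw sampling noise only (fixed truth)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ValidationError(f"ld_rho must be in [0, 1], got {self.ld_rho}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValidationError("invalid_fraction must be in [0, 1]")
        if sum(self.ld_block_sizes) > self.n_snps_exposure:
            raise ValidationError("ld_block_sizes sum exceeds n_snps_exposure")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n <= 0:
                raise ValidationError("cohort sizes must be positive")
        for cf in (self.case_fraction_mediator, self.case_fraction_outcome):
            if not 0.0 < cf < 1.0:
                raise ValidationError("case fractions must be in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.effect_sd == 0.0:
            warnings.warn("effect_sd = 0: no instrument will reach significance")


@dataclass
class SimulationTruth:
    """Ground truth accompanying one simulated system."""

    variant_id: np.ndarray
    snp_effect_exposure: np.ndarray  # marginal true effects on the exposure
    snp_effect_mediator: np.ndarray
    snp_effect_outcome: np.ndarray
    a_true: float
    b_true: float
    c_prime_true: float
    total_true: float
    proportion_mediated_true: float


def _make_layout(n_exposure: int, block_sizes: Sequence[int], n_mediator: int,
                 prefix: str = "rs") -> pd.DataFrame:
    """Variant ids, positions and LD-block labels.  Each block (and each
    singleton) occupies its own locus, 20 Mb apart so loci never share a
    clumping window; block members sit 10 kb apart."""
    rows = []
    sizes = list(block_sizes)
    n_in_blocks = sum(sizes)
    sizes += [1] * (n_exposure - n_in_blocks)
    sizes += [1] * n_mediator
    idx = 0
    for locus, size in enumerate(sizes):
        chrom = str(locus % 22 + 1)
        base = 1_000_000 + (locus // 22) * 20_000_000
        for k in range(size):
            rows.append((f"{prefix}{100001 + idx}", chrom, base + k * 10_000, locus))
            idx += 1
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "block"])


def simulate_ld_table(config: SimulationConfig) -> LDTable:
    """Block-diagonal LD: within-block pairs at r² = ld_rho, 0 elsewhere."""
    layout = _make_layout(config.n_snps_exposure, config.ld_block_sizes,
                          config.n_snps_mediator)
    return _ld_from_layout(layout, config.ld_rho)


def _ld_from_layout(layout: pd.DataFrame, rho: float) -> LDTable:
    tab = LDTable()
    if rho == 0.0:
        return tab
    for _, grp in layout.groupby("block"):
        ids = list(grp["variant_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                tab.add(ids[i], ids[j], rho)
    return tab


def _block_chol(layout: pd.DataFrame, rho: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-block (index array, Cholesky factor of the correlation matrix)."""
    r = np.sqrt(rho)
    out = []
    for _, grp in layout.groupby("block", sort=False):
        idx = grp.index.to_numpy()
        m = len(idx)
        corr = np.full((m, m), r)
        np.fill_diagonal(corr, 1.0)
        out.append((idx, np.linalg.cholesky(corr)))
    return out


def _marginalise(effects: np.ndarray, blocks) -> np.ndarray:
    """Marginal effect of each SNP: correlation-weighted sum of the joint
    effects of its LD block."""
    out = effects.copy()
    for idx, chol in blocks:
        corr = chol @ chol.T
        out[idx] = corr @ effects[idx]
    return out


def _correlated_noise(rng: np.random.Generator, blocks, n: int) -> np.ndarray:
    z = rng.standard_normal(n)
    out = z.copy()
    for idx, chol in blocks:
        out[idx] = chol @ z[idx]
    return out


def _se_vector(n: int, eaf: np.ndarray, case_fraction: float | None) -> np.ndarray:
    var_g = 2.0 * eaf * (1.0 - eaf)
    if case_fraction is None:  # quantitative, unit phenotype variance
        return 1.0 / np.sqrt(n * var_g)
    return 1.0 / np.sqrt(n * case_fraction * (1.0 - case_fraction) * var_g)


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ea_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    oa_idx = (ea_idx + shift) % 4
    return _BASES[ea_idx], _BASES[oa_idx]


def _cohort_stats(
    name: str,
    trait_type: str,
    layout: pd.DataFrame,
    true_marginal: np.ndarray,
    eaf: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
    n: int,
    case_fraction: float | None,
    blocks,
    rng: np.random.Generator,
    flip_fraction: float,
) -> SummaryStats:
    m = len(layout)
    se = _se_vector(n, eaf, case_fraction)
    beta = true_marginal + se * _correlated_noise(rng, blocks, m)
    pval = np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    flip = rng.random(m) < flip_fraction
    df = pd.DataFrame(
        {
            "variant_id": layout["variant_id"],
            "chrom": layout["chrom"],
            "pos": layout["pos"],
            "effect_allele": np.where(flip, oa, ea),
            "other_allele": np.where(flip, ea, oa),
            "eaf": np.where(flip, 1.0 - eaf, eaf),
            "beta": np.where(flip, -beta, beta),
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    return SummaryStats(name, trait_type, df)


def simulate_mediation_gwas(
    config: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, LDTable, SimulationTruth]:
    """Simulate the (exposure, mediator, outcome) GWAS triple plus LD table
    and ground truth.  The same seed always yields identical output; the
    three cohorts use independent child seeds of the root seed."""
    cfg = config
    layout = _make_layout(cfg.n_snps_exposure, cfg.ld_block_sizes, cfg.n_snps_mediator)
    m = len(layout)
    n_exp = cfg.n_snps_exposure
    blocks = _block_chol(layout, cfg.ld_rho)

    ss = np.random.SeedSequence(cfg.seed)
    (s_eff, s_shared, s_x, s_m, s_y) = [np.random.default_rng(c) for c in ss.spawn(5)]
    if cfg.noise_seed is not None:
        s_x, s_m, s_y = [np.random.default_rng(c)
                         for c in np.random.SeedSequence(cfg.noise_seed).spawn(3)]

    gamma = np.zeros(m)
    gamma[:n_exp] = s_eff.normal(0.0, cfg.effect_sd, n_exp)
    delta = np.zeros(m)
    delta[n_exp:] = s_eff.normal(0.0, cfg.mediator_effect_sd, cfg.n_snps_mediator)

    # structural solve with the mediator->exposure feedback loop
    a, r = cfg.a_true, cfg.reverse_effect
    denom = 1.0 - a * r
    d_x, d_m = gamma, delta
    g_x = _marginalise((d_x + r * d_m) / denom, blocks)
    g_m = _marginalise((d_m + a * d_x) / denom, blocks)

    # pleiotropy is attached on the marginal scale, aligned with the marginal
    # exposure effect of the invalid instrument — directional pleiotropy means
    # a consistent extra mediator effect per exposure-increasing allele, and
    # must stay sign-coherent for the instrument an estimator actually uses
    if cfg.pleiotropy_mode != "none" and cfg.invalid_fraction > 0:
        n_invalid = int(round(cfg.invalid_fraction * n_exp))
        which = s_eff.choice(n_exp, size=n_invalid, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        draw = s_eff.normal(mean, cfg.pleiotropy_sd, n_invalid)
        pleio = np.zeros(m)
        pleio[which] = np.where(g_x[which] < 0, -1.0, 1.0) * draw
        g_m = g_m + pleio

    g_y = cfg.c_prime_true * g_x + cfg.b_true * g_m

    eaf = s_shared.uniform(0.05, 0.95, m)
    ea, oa = _alleles(s_shared, m)

    exposure = _cohort_stats(
        "exposure", cfg.exposure_trait_type, layout, g_x, eaf, ea, oa,
        cfg.n_exposure,
        None if cfg.exposure_trait_type == "quantitative" else 0.5,
        blocks, s_x, 0.0,
    )
    mediator = _cohort_stats(
        "mediator", "binary", layout, g_m, eaf, ea, oa,
        cfg.n_mediator, cfg.case_fraction_mediator, blocks, s_m,
        cfg.allele_flip_fraction,
    )
    outcome = _cohort_stats(
        "outcome", "binary", layout, g_y, eaf, ea, oa,
        cfg.n_outcome, cfg.case_fraction_outcome, blocks, s_y,
        cfg.allele_flip_fraction,
    )
    total = cfg.c_prime_true + cfg.a_true * cfg.b_true
    truth = SimulationTruth(
        variant_id=layout["variant_id"].to_numpy(),
        snp_effect_exposure=g_x,
        snp_effect_mediator=g_m,
        snp_effect_outcome=g_y,
        a_true=cfg.a_true,
        b_true=cfg.b_true,
        c_prime_true=cfg.c_prime_true,
        total_true=total,
        proportion_mediated_true=(cfg.a_true * cfg.b_true / total) if total != 0 else float("nan"),
    )
    return exposure, mediator, outcome, _ld_from_layout(layout, cfg.ld_rho), truth


@dataclass
class PanelTrait:
    """One trait in a multi-trait panel: its causal coordinates in the DAG.

    ``c_prime`` may be a single direct effect applied to every outcome or a
    per-outcome mapping (e.g. to engineer a trait whose total effect cancels
    for every outcome)."""

    name: str
    a: float = 0.4
    c_prime: float | Mapping[str, float] = 0.1
    reverse_effect: float = 0.0
    n_snps: int = 40

    def c_prime_for(self, outcome: str) -> float:
        if isinstance(self.c_prime, Mapping):
            return float(self.c_prime.get(outcome, 0.0))
        return float(self.c_prime)


@dataclass
class PanelData:
    traits: dict[str, SummaryStats]
    mediator: SummaryStats
    outcomes: dict[str, SummaryStats]
    ld: LDTable
    truth: pd.DataFrame  # one row per (trait, outcome) with a/b/c'/total/pm


def simulate_panel(
    traits: Sequence[PanelTrait],
    outcome_b: Mapping[str, float],
    config: SimulationConfig | None = None,
) -> PanelData:
    """Simulate a whole screening panel sharing one mediator and several
    outcomes.  Every GWAS covers every panel variant (as a real genome-wide
    scan would), so reverse-direction MR can select the mediator's own loci
    from any trait's dataset.  Reverse causation uses a first-order
    linearisation (adequate for the small |a·reverse| this panel uses)."""
    cfg = config or SimulationConfig()
    n_trait_snps = sum(t.n_snps for t in traits)
    # give each trait two 3-SNP LD blocks (when it has room) so clumping has
    # real work to do in panel runs
    block_sizes: list[int] = []
    for t in traits:
        if t.n_snps >= 6:
            block_sizes += [3, 3] + [1] * (t.n_snps - 6)
        else:
            block_sizes += [1] * t.n_snps
    layout = _make_layout(n_trait_snps, tuple(block_sizes), cfg.n_snps_mediator)
    m = len(layout)
    blocks = _block_chol(layout, cfg.ld_rho)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(3 + len(traits) + 1 + len(outcome_b))
    s_eff = np.random.default_rng(children[0])
    s_shared = np.random.default_rng(children[1])

    # direct effects: each trait owns a disjoint SNP set; mediator loci last
    own = {}
    offset = 0
    gamma = np.zeros((len(traits), m))
    for k, t in enumerate(traits):
        own[t.name] = slice(offset, offset + t.n_snps)
        gamma[k, own[t.name]] = s_eff.normal(0.0, cfg.effect_sd, t.n_snps)
        offset += t.n_snps
    delta = np.zeros(m)
    delta[n_trait_snps:] = s_eff.normal(0.0, cfg.mediator_effect_sd, cfg.n_snps_mediator)

    g_m = delta + sum(t.a * gamma[k] for k, t in enumerate(traits))

    eaf = s_shared.uniform(0.05, 0.95, m)
    ea, oa = _alleles(s_shared, m)

    trait_stats: dict[str, SummaryStats] = {}
    for k, t in enumerate(traits):
        g_x = gamma[k].copy()
        if t.reverse_effect:
            mask = np.ones(m, dtype=bool)
            mask[own[t.name]] = False
            g_x[mask] += t.reverse_effect * g_m[mask]
        trait_stats[t.name] = _cohort_stats(
            t.name, "quantitative", layout, _marginalise(g_x, blocks), eaf, ea, oa,
            cfg.n_exposure, None, blocks,
            np.random.default_rng(children[3 + k]), cfg.allele_flip_fraction if k else 0.0,
        )

    mediator = _cohort_stats(
        "AF", "binary", layout, _marginalise(g_m, blocks), eaf, ea, oa,
        cfg.n_mediator, cfg.case_fraction_mediator, blocks,
        np.random.default_rng(children[3 + len(traits)]), cfg.allele_flip_fraction,
    )

    outcome_stats: dict[str, SummaryStats] = {}
    truth_rows = []
    for j, (oname, b) in enumerate(outcome_b.items()):
        g_y = b * g_m
        for k, t in enumerate(traits):
            g_y = g_y + t.c_prime_for(oname) * gamma[k]
        outcome_stats[oname] = _cohort_stats(
            oname, "binary", layout, _marginalise(g_y, blocks), eaf, ea, oa,
            cfg.n_outcome, cfg.case_fraction_outcome, blocks,
            np.random.default_rng(children[4 + len(traits) + j]),
            cfg.allele_flip_fraction,
        )
        for t in traits:
            total = t.c_prime_for(oname) + t.a * b
            truth_rows.append(
                (t.name, oname, t.a, b, t.c_prime_for(oname), total,
                 (t.a * b / total) if total != 0 else float("nan"))
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["trait", "outcome", "a_true", "b_true", "c_prime_true",
                 "total_true", "proportion_mediated_true"],
    )
    return PanelData(trait_stats, mediator, outcome_stats, _ld_from_layout(layout, cfg.ld_rho), truth)


def write_simulation(path_prefix: str, sim) -> None:
    """Write a simulated triple to standard summary-stat TSVs plus truth."""
    exposure, mediator, outcome, ld, truth = sim
    from .summary_stats import write_gwas

    write_gwas(exposure, f"{path_prefix}.exposure.tsv")
    write_gwas(mediator, f"{path_prefix}.mediator.tsv")
    write_gwas(outcome, f"{path_prefix}.outcome.tsv")
    ld.write(f"{path_prefix}.ld.tsv")
    pd.DataFrame(
        {
            "variant_id": truth.variant_id,
            "effect_exposure": truth.snp_effect_exposure,
            "effect_mediator": truth.snp_effect_mediator,
            "effect_outcome": truth.snp_effect_outcome,
        }
    ).to_csv(f"{path_prefix}.truth.tsv", sep="\t", index=False)


def eligibility_demo_panel(seed: int = 0, config: SimulationConfig | None = None) -> PanelData:
    """A 12-trait screening panel engineered so exactly four traits satisfy
    all three mediation-eligibility rules.

    Traits T01-T04 cause the mediator, have no reverse path, and directly
    affect the outcomes (eligible).  T05-T07 affect the outcomes but not the
    mediator (rule 1 fails).  T08-T10 are bidirectional with the mediator
    (rule 2 fails).  T11-T12 affect the mediator but their direct outcome
    effects exactly cancel the mediated path, so they are causal for no
    outcome (rule 3 fails).  Outcomes AS/AIS/CES are mediator-affected;
    LAS/SVS are not.
    """
    outcome_b = {"AS": 0.25, "AIS": 0.3, "CES": 0.7, "LAS": 0.0, "SVS": 0.0}
    traits = (
        [PanelTrait(f"T{i:02d}", a=0.4, c_prime=0.1) for i in range(1, 5)]
        + [PanelTrait(f"T{i:02d}", a=0.0, c_prime=0.3) for i in range(5, 8)]
        + [PanelTrait(f"T{i:02d}", a=0.4, c_prime=0.1, reverse_effect=0.2)
           for i in range(8, 11)]
        + [PanelTrait(f"T{i:02d}", a=0.4,
                      c_prime={o: -0.4 * b for o, b in outcome_b.items()})
           for i in range(11, 13)]
    )
    cfg = config or SimulationConfig()
    cfg = replace(cfg, seed=seed)
    return simulate_panel(traits, outcome_b, cfg)
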