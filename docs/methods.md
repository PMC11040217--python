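# Methods

## Estimation model

All estimators operate on harmonized per-instrument summary statistics: the
exposure effect β̂_Xj with SE σ_Xj, and the outcome effect β̂_Yj with SE
σ_Yj, from non-overlapping cohorts. Binary traits are on the log-odds
scale; quantitative traits in phenotype-SD units.

**IVW.** θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj² with w_j = 1/σ_Yj², identically
the (β_Xj/σ_Yj)²-weighted mean of the Wald ratios. Heterogeneity is
Cochran's Q = Σ w_j (β_Yj − θ̂ β_Xj)². The SE uses *multiplicative* random
effects: the fixed-effect SE times max(1, √(Q/(L−1))). The floor at 1 means
under-dispersion never shrinks intervals; this is the dominant two-sample
convention, and the alternative (additive random effects) is deliberately
not offered. p-values are two-sided normal. With a single instrument the
estimate degrades to the Wald ratio, labelled as such.

**MR-Egger.** Instruments are first oriented so β_Xj ≥ 0 (signs of β_X and
β_Y flipped together; the orientation leaves IVW and the weighted median
unchanged and is applied only where it matters, Egger and I²GX). A weighted
regression with intercept is then fitted by the closed-form 2×2 normal
equations; both coefficient SEs are scaled by max(1, √(Q_E/(L−2))) and
referred to t with L−2 df. The intercept estimates average directional
pleiotropy per instrument. Fewer than 3 instruments returns an
unavailability marker (data, not an exception, so multi-trait sweeps never
abort). I²GX = max(0, (Q_GX − (L−1))/Q_GX), where Q_GX is the
1/σ_X²-weighted dispersion of the oriented exposure effects, quantifies the
no-measurement-error assumption; the conventional caution threshold 0.9 is
attached as a flag.

**Weighted median.** Wald ratios are sorted; with inverse-variance ratio
weights normalised to sum 1, the estimate is the value where the midpoint
cumulative weight (cumulative sum minus half the current weight) crosses
0.5, linearly interpolated. The SE is a parametric bootstrap: ratio_j
resampled from N(ratio_j, se_j²) with a fixed seed (default 1,000 draws,
configurable). Equal weights and odd L reproduce the plain median exactly.

**MVMR.** Direct effects are the zero-intercept weighted regression of β_Y
on the K exposure columns, weights 1/σ_Y². Coefficient SEs carry the same
multiplicative scaling, max(1, √(Q_resid/(L−K))) with the weighted residual
sum of squares — this (rather than the modified Q below) keeps the K = 1
case *exactly* equal to univariable IVW, an identity the test suite
enforces. Exposure-side uncertainty is ignored in estimation (standard
weighted-regression MVMR, not the Q-minimisation estimator) but enters two
diagnostics:

- modified Cochran's Q: Q_A = Σ (β_Yi − Σ_k θ̂_k β_Xki)² /
  (σ_Yi² + Σ_k θ̂_k² σ_Xki²), χ² with L−K df;
- conditional F: the target exposure's effects are regressed (weights
  1/σ_X,target², no intercept) on the other exposures' effects; the
  weighted residual sum of squares divided by L is the conditional F. The
  normalisation by L was chosen so that with no conditioning exposures the
  statistic reduces to the familiar mean per-instrument F,
  mean((β_X/σ_X)²); conventions differ across software and this one is a
  deliberate choice.

The MVMR instrument set is the union of each exposure's clumped
genome-wide-significant variants, re-clumped jointly on the per-variant
minimum p across exposures, restricted to variants present in all datasets.

**Mediation (2-step MR).** indirect = a·b with delta SE
√(a²·se_b² + b²·se_a²); PM = indirect/total with delta SE
|PM|·√((se_ind/ind)² + (se_tot/tot)²). Cross-covariances are set to zero:
the legs come from independent GWAS cohorts, and the shared-instrument
correlation that remains is small and (for the PM ratio) conservative,
since the indirect and total effects co-move through the outcome noise. PM
is reported *unclamped*, with flags when it leaves [0, 1] or when the
indirect and total effects disagree in sign — real analyses produce such
values (e.g. negative direct effects overshooting positive totals) and
clamping would hide them. A zero total effect returns an undefined-result
marker rather than dividing.

## Instrument processing

Selection is strict: p < 5×10⁻⁸ (the boundary value is excluded, matching
the usual "p < 5×10⁻⁸" notation). Clumping is greedy: repeatedly keep the
lowest-p remaining variant and drop same-chromosome variants within
10,000 kb at r² ≥ 0.001; p ties break lexicographically by variant id for
determinism. LD arrives as an explicit r² table (absent pair ⇒ 0, with the
synthetic module or an external tool as the source); genotype reference
panels are out of scope. Instruments missing from an outcome dataset can be
replaced from a proxy table (highest r², requiring r² ≥ 0.8, allele map
applied verbatim) before harmonization.

Harmonization aligns every dataset to the first exposure's allele
orientation: identical allele pairs are kept, swapped pairs flip the beta
sign and replace EAF by 1−EAF, strand-complement pairs likewise; anything
else is dropped as incompatible. Palindromic variants (A/T, C/G) carry no
allele information, so they are resolved by frequency concordance: dropped
when exposure MAF > 0.3, when either EAF is within ±0.01 of 0.5, or when
EAF is missing; otherwise aligned so both datasets sit on the same side of
0.5. The frequency-concordance rule below MAF 0.3 is this package's choice
(the conservative alternative — dropping all palindromic variants — can be
emulated by setting the threshold to 0). Every per-variant decision is
recorded in an action column.

## Multiple testing and eligibility

Benjamini–Hochberg adjustment (statsmodels' step-up implementation) is
applied within explicit families: for the screen, within each outcome
across exposures (the mediator included); for bidirectional MR, within each
direction across traits. Direction classes are a pure function of the two
adjusted p-values at α = 0.05: forward_only / reverse_only / bidirectional
/ none, with a non-assessable direction (no instruments) counted as
non-significant and flagged. "Bidirectional" requires FDR significance in
*both* directions. A trait enters mediation iff it (1) affects the mediator,
(2) is forward_only, and (3) is FDR-significant for at least one outcome;
tasks are then formed per (trait, outcome) for outcomes that are both
mediator-affected and trait-significant. Funnel counts are nested
intersections, so monotonicity holds by construction.

## Synthetic data generator

The generator simulates summary statistics directly on the marginal-effect
scale rather than via individual-level genotypes: observed β̂ = true
marginal effect + normal noise with the analytic GWAS SE
(binary: 1/√(n·cf(1−cf)·2·eaf(1−eaf)); quantitative:
1/√(n·2·eaf(1−eaf))), EAF ~ U(0.05, 0.95) shared across cohorts, and
independent noise per cohort (the two-sample assumption holds exactly).
This preserves everything the estimators consume at desk-scale cost.

The structural model: exposure loci carry direct effects γ_j ~ N(0,
effect_sd²); mediator loci carry δ_m ~ N(0, mediator_effect_sd²); the
exposure→mediator effect is `a`, the direct exposure→outcome effect `c′`,
the mediator→outcome effect `b`, and an optional mediator→exposure path
`r` closes a feedback loop solved exactly as
g_X = (d_X + r·d_M)/(1−a·r), g_M = (d_M + a·d_X)/(1−a·r),
g_Y = c′·g_X + b·g_M. LD is equicorrelated blocks with within-block
r² = ld_rho; true effects and sampling noise are both mixed with
correlation √ld_rho inside blocks. Pleiotropy for the invalid fraction of
exposure loci is attached *after* LD marginalisation, aligned with the sign
of the instrument's marginal exposure effect: α_j ~ N(pleiotropy_mean,
pleiotropy_sd²) (directional) or N(0, pleiotropy_sd²) (balanced). Attaching
it per-causal-variant instead would let oppositely-signed block members
cancel the directional component after marginalisation, turning nominally
directional pleiotropy into approximately balanced pleiotropy at the
instrument level — an artifact, since directional pleiotropy means a
consistent effect per exposure-increasing allele of the variant actually
used. Alleles are drawn per variant; a configurable fraction of variants is
presented with swapped allele order (beta negated, EAF complemented) in the
non-reference cohorts, and palindromic pairs arise naturally, so
harmonization is genuinely exercised.

Default study conditions (chosen once as a realistic emulation of the
ingredients of a large two-sample mediation study, and used as-is by the
validation suite):

| parameter | default | rationale |
|---|---|---|
| n_snps_exposure | 200 | a well-powered polygenic trait's genome-wide-significant loci |
| effect_sd | 0.02 SD/allele | typical lead-SNP effects of anthropometric/biomarker traits |
| n_exposure | 1,000,000 | modern meta-analysis scale; keeps winner's-curse attenuation of selected instruments small |
| n_snps_mediator / mediator_effect_sd | 80 / 0.05 log-odds | AF susceptibility loci; about half reach genome-wide significance in the mediator GWAS |
| n_mediator, case fraction | 1,030,836 / 0.059 | the scale of the 2018 AF meta-analysis (60,620 cases, 970,216 controls) |
| n_outcome, case fraction | 446,696 / 0.09 | the scale of the European any-stroke GWAS (40,585 cases, 406,111 controls) |
| ld_block_sizes, ld_rho | twenty 3-SNP blocks, r² 0.9 | ~30 % of exposure loci need pruning |
| pleiotropy_mean, pleiotropy_sd | 0.03, 0.01 | invalid instruments act like moderate mediator loci with a consistent sign |
| a, b, c′ | 0.4, 0.8, 0.1 | a strong mediated pathway with a modest direct effect (PM ≈ 76 %) |
| allele_flip_fraction | 0.3 | cross-cohort allele-order discordance |

`reverse_effect` defaults to 0; bidirectional scenarios in the validation
suite use 0.2, large enough that a reverse path is unambiguous at these
cohort sizes. A `noise_seed` override redraws sampling noise while holding
the causal truth fixed, which is what unbiasedness checks need.

The panel generator composes many traits (disjoint locus sets, shared
mediator and outcomes, per-trait `a`, `c′`, `reverse_effect` and per-outcome
`b`), computing trait GWAS effects to first order in the reverse path. The
bundled 12-trait demonstration panel engineers exactly four eligible traits
by construction: three traits fail rule 1 (a = 0), three fail rule 2
(reverse path present), and two fail rule 3 (per-outcome direct effects set
to −a·b so every total effect cancels exactly).

### What the generator does not emulate

No individual-level genotypes, population structure, relatedness, sample
overlap between cohorts, or winner's-curse correction; binary-trait effects
are generated directly on the log-odds scale, so the non-collapsibility of
odds ratios is not represented; LD is block-equicorrelated rather than
empirically shaped. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated model, not robustness to
overlapping samples or realistic LD; the known ~few-percent regression
dilution of MVMR coefficients under measurement error and selection is
visible in the simulations and documented rather than hidden.

## Numerical and degenerate-case choices

p-values are clipped into (0, 1] (floor 1e-300). Q = 0 gives an I²GX of 0
with the dilution flag set. Under-identified MVMR (L ≤ K) and
rank-deficient exposure matrices raise errors naming the collinear
exposures; estimator unavailability from too few instruments is data.
Zero-instrument traits are marked not-analyzable and quarantined by the
pipeline rather than failing the run. All randomness in a pipeline run
descends from a single seed via spawned child streams; reruns are
byte-identical, and output tables contain no timestamps.

## Validation problem sizes

The statistical validation suite uses 1,000 replicates for test
calibration (50-instrument null systems), 200 replicates for pleiotropy
robustness and mediation-recovery checks, 100 per direction-classification
scenario, and the 12-trait panel for the end-to-end funnel — sizes at which
every Monte-Carlo margin used in an assertion is several times its
simulation SE.
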