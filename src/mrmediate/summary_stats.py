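"""GWAS summary statistics: reading, instrument selection, LD clumping,
proxy substitution and allele harmonization.

Summary statistics are the per-variant marginal association estimates a GWAS
releases: the effect size per copy of the effect allele (log-odds for binary
traits, SD units for quantitative ones), its standard error, the effect-allele
frequency (EAF) and the association p-value. Two-sample MR joins such tables
from independent cohorts, which requires aligning the effect alleles of every
instrument between the exposure and outcome datasets; palindromic variants
(A/T or C/G) cannot be aligned from alleles alone and are resolved, when
possible, from allele-frequency concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary-statistic table
COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


class FormatError(ValueError):
    """A summary-statistic file does not have the expected layout."""


class ValidationError(ValueError):
    """A record violates a per-variant invariant."""


class HarmonizationError(ValueError):
    """No instrument survives harmonization."""


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``df`` holds one row per variant with the columns in :data:`COLUMNS`,
    unique by ``variant_id``. ``trait_type`` ('binary' or 'quantitative')
    records the scale of ``beta`` (log-odds vs SD units).
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValidationError(
                f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}"
            )
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"summary statistics missing columns: {missing}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)
        validate_records(self.df)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        """Rows for ``variant_ids``, preserving this table's order."""
        wanted = set(variant_ids)
        sub = self.df[self.df["variant_id"].isin(wanted)].reset_index(drop=True)
        return SummaryStats(self.trait_name, self.trait_type, sub)

    def lookup(self, variant_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reindexed to exactly ``variant_ids`` (must all be present)."""
        idx = self.df.set_index("variant_id")
        missing = [v for v in variant_ids if v not in idx.index]
        if missing:
            raise KeyError(f"variants absent from {self.trait_name}: {missing[:5]}")
        out = idx.loc[list(variant_ids)].reset_index()
        return out


def validate_records(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` naming the first offending row."""
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate variant_id: {dup.iloc[0]!r}")
    for i, row in enumerate(df.itertuples(index=False)):
        if row.effect_allele not in VALID_ALLELES or row.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"row {i} ({row.variant_id}): alleles must be one of A/C/G/T, "
                f"got {row.effect_allele}/{row.other_allele}"
            )
        if row.effect_allele == row.other_allele:
            raise ValidationError(
                f"row {i} ({row.variant_id}): effect and other allele identical"
            )
        if not row.se > 0:
            raise ValidationError(f"row {i} ({row.variant_id}): se must be > 0, got {row.se}")
        if not np.isnan(row.eaf) and not 0.0 <= row.eaf <= 1.0:
            raise ValidationError(f"row {i} ({row.variant_id}): eaf outside [0, 1]: {row.eaf}")
        if not 0.0 < row.pval <= 1.0:
            raise ValidationError(f"row {i} ({row.variant_id}): pval outside (0, 1]: {row.pval}")
        if not row.n > 0:
            raise ValidationError(f"row {i} ({row.variant_id}): n must be positive")


def read_gwas(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_name: str | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistic file.

    ``column_map`` maps canonical names (:data:`COLUMNS`) to the file's
    header names; omitted entries default to the canonical name itself.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep)
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise FormatError(f"required column {src!r} (for {canon!r}) not in header")
        rename[src] = canon
    df = raw.rename(columns=rename)
    df["chrom"] = df["chrom"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        df[allele_col] = df[allele_col].astype(str).str.upper()
    name = trait_name if trait_name is not None else str(path)
    return SummaryStats(name, trait_type, df)


def write_gwas(stats: SummaryStats, path) -> None:
    stats.df.to_csv(path, sep="\t", index=False)


def select_instruments(stats: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Keep genome-wide-significant variants (strictly ``pval < p_threshold``)."""
    kept = stats.df[stats.df["pval"] < p_threshold].reset_index(drop=True)
    return SummaryStats(stats.trait_name, stats.trait_type, kept)


class LDTable:
    """Sparse symmetric table of pairwise LD r²; absent pairs are r² = 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return  # self-pairs are implicitly 1
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["variant_id_a", "variant_id_b", "r2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDTable":
        tab = cls()
        for row in df.itertuples(index=False):
            tab.add(str(row.variant_id_a), str(row.variant_id_b), float(row.r2))
        return tab

    @classmethod
    def read(cls, path) -> "LDTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ld_clump(
    stats: SummaryStats,
    ld: LDTable,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryStats:
    """Greedy LD pruning: repeatedly keep the variant with the lowest p-value
    and discard all others on the same chromosome within ``window_kb`` having
    r² ≥ ``r2_threshold`` with it.  Ties on p-value break by variant_id.
    """
    df = stats.df
    order = df.sort_values(["pval", "variant_id"], kind="mergesort").index
    window_bp = window_kb * 1000.0
    alive = dict.fromkeys(order, True)
    kept: list[int] = []
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    vid = df["variant_id"].to_numpy()
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        for j in list(alive):
            if not alive[j]:
                continue
            if chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp:
                if ld.r2(vid[i], vid[j]) >= r2_threshold:
                    alive[j] = False
    kept_mask = df.index.isin(kept)
    out = df[kept_mask].reset_index(drop=True)  # original row order
    return SummaryStats(stats.trait_name, stats.trait_type, out)


def substitute_proxies(
    missing_ids: Iterable[str],
    proxy_table: pd.DataFrame,
    available_ids: Iterable[str] | None = None,
    r2_min: float = 0.8,
) -> tuple[dict[str, str], list[str]]:
    """Choose, per missing instrument, the highest-r² proxy with r² ≥ ``r2_min``.

    ``proxy_table`` has columns target_id, proxy_id, r2 and optionally
    allele_map (a string like ``"A=G,C=T"`` translating target alleles into
    proxy alleles).  Returns (substitution map, ids dropped for lack of an
    adequate proxy).  If ``available_ids`` is given only proxies present in it
    are considered.
    """
    available = None if available_ids is None else set(available_ids)
    mapping: dict[str, str] = {}
    dropped: list[str] = []
    by_target = proxy_table.groupby("target_id") if len(proxy_table) else None
    for target in missing_ids:
        if by_target is None or target not in by_target.groups:
            dropped.append(target)
            continue
        cand = by_target.get_group(target)
        cand = cand[cand["r2"] >= r2_min]
        if available is not None:
            cand = cand[cand["proxy_id"].isin(available)]
        if len(cand) == 0:
            dropped.append(target)
            continue
        best = cand.sort_values(["r2", "proxy_id"], ascending=[False, True]).iloc[0]
        mapping[target] = str(best["proxy_id"])
    return mapping, dropped


def _parse_allele_map(mapping: str) -> dict[str, str]:
    out = {}
    for part in str(mapping).split(","):
        src, dst = part.split("=")
        out[src.strip().upper()] = dst.strip().upper()
    return out


def apply_proxies(
    stats: SummaryStats, mapping: Mapping[str, str], proxy_table: pd.DataFrame
) -> SummaryStats:
    """Rename mapped instruments to their proxies, translating alleles with the
    proxy table's allele_map verbatim.  Statistics (beta, se, eaf, p) carry
    over unchanged — the proxy stands in for the target at r² ≥ the cutoff."""
    df = stats.df.copy()
    has_map = "allele_map" in proxy_table.columns
    lut = proxy_table.set_index(["target_id", "proxy_id"])
    for target, proxy in mapping.items():
        sel = df["variant_id"] == target
        if not sel.any():
            continue
        df.loc[sel, "variant_id"] = proxy
        if has_map:
            amap = _parse_allele_map(lut.loc[(target, proxy), "allele_map"])
            df.loc[sel, "effect_allele"] = df.loc[sel, "effect_allele"].map(amap)
            df.loc[sel, "other_allele"] = df.loc[sel, "other_allele"].map(amap)
    return SummaryStats(stats.trait_name, stats.trait_type, df)


@dataclass
class HarmonizedSet:
    """Allele-aligned instrument matrix joining exposures to one outcome.

    ``beta_x``/``se_x`` are (L, K) arrays over L retained variants and K
    exposures; ``beta_y``/``se_y`` are length-L.  ``actions`` records, per
    retained variant, 'kept' or 'flipped'; variants removed during
    harmonization appear in ``dropped`` with the reason
    ('dropped_palindromic' or 'dropped_incompatible').
    """

    exposure_names: list[str]
    outcome_name: str
    variant_id: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_exposure: np.ndarray
    eaf_outcome: np.ndarray
    actions: np.ndarray
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "action"])
    )

    @property
    def n_snps(self) -> int:
        return len(self.variant_id)

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]

    @property
    def bx(self) -> np.ndarray:
        """Single-exposure effect vector (requires K = 1)."""
        if self.n_exposures != 1:
            raise ValueError("single-exposure accessor on multi-exposure set")
        return self.beta_x[:, 0]

    @property
    def sx(self) -> np.ndarray:
        if self.n_exposures != 1:
            raise ValueError("single-exposure accessor on multi-exposure set")
        return self.se_x[:, 0]

    def to_frame(self) -> pd.DataFrame:
        data = {"variant_id": self.variant_id}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.beta_x[:, k]
            data[f"se_{name}"] = self.se_x[:, k]
        data[f"beta_{self.outcome_name}"] = self.beta_y
        data[f"se_{self.outcome_name}"] = self.se_y
        data["eaf_exposure"] = self.eaf_exposure
        data["eaf_outcome"] = self.eaf_outcome
        data["action"] = self.actions
        frame = pd.DataFrame(data)
        if len(self.dropped):
            drop = self.dropped.copy()
            drop = drop.rename(columns={"action": "action"})
            frame = pd.concat([frame, drop], ignore_index=True)
        return frame


def _align_to_reference(ref: pd.DataFrame, other: pd.DataFrame,
                        palindrome_maf_threshold: float,
                        ambiguity_band: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align ``other`` rows to the reference allele orientation.

    Returns (sign, keep_mask, drop_reason) arrays; sign is +1/-1 applied to
    ``other.beta`` (its eaf flips to 1-eaf when sign is -1).
    """
    n = len(ref)
    ea_r = ref["effect_allele"].to_numpy()
    oa_r = ref["other_allele"].to_numpy()
    ea = other["effect_allele"].to_numpy()
    oa = other["other_allele"].to_numpy()
    eaf_r = ref["eaf"].to_numpy(dtype=float)
    eaf_o = other["eaf"].to_numpy(dtype=float)

    comp = np.vectorize(COMPLEMENT.get)
    cea, coa = comp(ea), comp(oa)

    palin = np.array([_is_palindromic(a, b) for a, b in zip(ea_r, oa_r)])

    sign = np.ones(n)
    keep = np.ones(n, dtype=bool)
    reason = np.full(n, "", dtype=object)

    same = (ea == ea_r) & (oa == oa_r)
    swap = (ea == oa_r) & (oa == ea_r)
    strand_same = (cea == ea_r) & (coa == oa_r)
    strand_swap = (cea == oa_r) & (coa == ea_r)

    # non-palindromic: allele identity (possibly after strand flip) resolves it
    np_mask = ~palin
    incompatible = np_mask & ~(same | swap | strand_same | strand_swap)
    keep[incompatible] = False
    reason[incompatible] = "dropped_incompatible"
    flip = np_mask & ~incompatible & (swap | strand_swap) & ~same & ~strand_same
    sign[flip] = -1.0

    # palindromic: alleles are uninformative (swap == strand flip); use EAF
    pal_same_pair = palin & (same | swap)
    pal_bad = palin & ~pal_same_pair
    keep[pal_bad] = False
    reason[pal_bad] = "dropped_incompatible"

    maf_r = np.minimum(eaf_r, 1.0 - eaf_r)
    with np.errstate(invalid="ignore"):
        high_maf = maf_r > palindrome_maf_threshold
        near_half = (np.abs(eaf_r - 0.5) < ambiguity_band) | (np.abs(eaf_o - 0.5) < ambiguity_band)
    no_freq = np.isnan(eaf_r) | np.isnan(eaf_o)
    pal_drop = pal_same_pair & (high_maf | near_half | no_freq)
    keep[pal_drop] = False
    reason[pal_drop] = "dropped_palindromic"

    pal_ok = pal_same_pair & ~pal_drop
    discordant = pal_ok & ((eaf_r > 0.5) != (eaf_o > 0.5))
    sign[discordant] = -1.0
    return sign, keep, reason


def harmonize(
    exposures: Sequence[SummaryStats] | SummaryStats,
    outcome: SummaryStats,
    palindrome_maf_threshold: float = 0.3,
    ambiguity_band: float = 0.01,
) -> HarmonizedSet:
    """Allele-align one or more exposure datasets with an outcome dataset.

    The first exposure defines the reference orientation.  Variants are the
    intersection across all datasets, in the first exposure's order.  Where a
    dataset's alleles are swapped (or strand-flipped) relative to the
    reference, its beta is negated and eaf replaced by 1 - eaf.  Palindromic
    variants with exposure MAF above ``palindrome_maf_threshold`` — or with an
    EAF within ``ambiguity_band`` of 0.5 in either dataset, or missing EAF —
    are dropped; the rest are aligned by frequency concordance.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise ValueError("at least one exposure required")

    common = set(exposures[0].df["variant_id"])
    for ds in exposures[1:]:
        common &= set(ds.df["variant_id"])
    common &= set(outcome.df["variant_id"])
    ids = [v for v in exposures[0].df["variant_id"] if v in common]
    if not ids:
        raise HarmonizationError(
            f"no shared variants between {[e.trait_name for e in exposures]} "
            f"and {outcome.trait_name}"
        )

    ref = exposures[0].lookup(ids)
    L, K = len(ids), len(exposures)
    beta_x = np.empty((L, K))
    se_x = np.empty((L, K))
    beta_x[:, 0] = ref["beta"].to_numpy()
    se_x[:, 0] = ref["se"].to_numpy()
    keep = np.ones(L, dtype=bool)
    reason = np.full(L, "", dtype=object)
    flipped_any = np.zeros(L, dtype=bool)

    aligned_frames = []
    for ds in list(exposures[1:]) + [outcome]:
        tab = ds.lookup(ids)
        sign, k_ds, r_ds = _align_to_reference(
            ref, tab, palindrome_maf_threshold, ambiguity_band
        )
        newly = k_ds == False  # noqa: E712
        take = keep & newly & (reason == "")
        reason[take] = r_ds[take]
        keep &= k_ds
        flipped_any |= sign < 0
        aligned = tab.copy()
        aligned["beta"] = tab["beta"].to_numpy() * sign
        aligned["eaf"] = np.where(sign < 0, 1.0 - tab["eaf"].to_numpy(), tab["eaf"].to_numpy())
        aligned_frames.append(aligned)

    for k, aligned in enumerate(aligned_frames[:-1], start=1):
        beta_x[:, k] = aligned["beta"].to_numpy()
        se_x[:, k] = aligned["se"].to_numpy()
    out_tab = aligned_frames[-1]

    if not keep.any():
        raise HarmonizationError(
            f"no instruments survive harmonization against {outcome.trait_name}"
        )

    actions = np.where(flipped_any[keep], "flipped", "kept").astype(object)
    dropped = pd.DataFrame(
        {"variant_id": np.asarray(ids, dtype=object)[~keep], "action": reason[~keep]}
    )
    return HarmonizedSet(
        exposure_names=[e.trait_name for e in exposures],
        outcome_name=outcome.trait_name,
        variant_id=np.asarray(ids, dtype=object)[keep],
        beta_x=beta_x[keep],
        se_x=se_x[keep],
        beta_y=out_tab["beta"].to_numpy()[keep],
        se_y=out_tab["se"].to_numpy()[keep],
        eaf_exposure=ref["eaf"].to_numpy(dtype=float)[keep],
        eaf_outcome=out_tab["eaf"].to_numpy(dtype=float)[keep],
        actions=actions,
        dropped=dropped,
    )
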