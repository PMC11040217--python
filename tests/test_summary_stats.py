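"""Instrument selection, clumping, proxies and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.summary_stats import (
    HarmonizationError,
    LDTable,
    ValidationError,
    apply_proxies,
    harmonize,
    ld_clump,
    read_gwas,
    select_instruments,
    substitute_proxies,
    write_gwas,
)

from conftest import make_stats


class TestReadGwas:
    def test_roundtrip(self, tmp_path):
        stats = make_stats()
        path = tmp_path / "t.tsv"
        write_gwas(stats, path)
        back = read_gwas(path, trait_name="trait")
        assert back.n_variants == 3
        pd.testing.assert_frame_equal(back.df, stats.df)

    def test_column_map(self, tmp_path):
        stats = make_stats()
        df = stats.df.rename(columns={"pval": "P", "beta": "BETA"})
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_gwas(path, column_map={"pval": "P", "beta": "BETA"})
        assert list(back.df["pval"]) == list(stats.df["pval"])

    def test_negative_se_names_row(self, tmp_path):
        stats = make_stats()
        df = stats.df.copy()
        df.loc[1, "se"] = -0.01
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="row 1.*se"):
            read_gwas(path)

    def test_duplicate_variant_named(self):
        with pytest.raises(ValidationError, match="rs1"):
            make_stats(variant_id=("rs1", "rs1", "rs3"))

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        make_stats().df.drop(columns=["eaf"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(Exception, match="eaf"):
            read_gwas(path)


class TestSelectInstruments:
    def test_strict_threshold(self):
        stats = make_stats(pval=(1e-9, 1e-7, 4e-8))
        assert select_instruments(stats).n_variants == 2

    def test_boundary_excluded(self):
        stats = make_stats(pval=(5e-8, 1e-9, 0.5))
        kept = select_instruments(stats)
        assert list(kept.df["variant_id"]) == ["rs2"]

    def test_empty_result_allowed(self):
        stats = make_stats(pval=(0.1, 0.2, 0.3))
        assert select_instruments(stats).n_variants == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-300, max_value=1.0), min_size=1, max_size=20))
    def test_idempotent(self, pvals):
        stats = make_stats(
            variant_id=[f"rs{i}" for i in range(len(pvals))],
            beta=[0.1] * len(pvals), se=[0.01] * len(pvals), pval=pvals,
            eaf=[0.2] * len(pvals),
            effect_allele=["A"] * len(pvals), other_allele=["G"] * len(pvals),
        )
        once = select_instruments(stats)
        twice = select_instruments(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestLdClump:
    def test_correlated_pair_keeps_lowest_p(self):
        stats = make_stats(variant_id=("a", "b"), beta=(0.1, 0.1), se=(0.01, 0.01),
                           pval=(1e-10, 1e-9), eaf=(0.2, 0.2),
                           effect_allele=("A", "A"), other_allele=("G", "G"),
                           pos=(1_000_000, 1_100_000))
        ld = LDTable({("a", "b"): 0.5})
        kept = ld_clump(stats, ld, r2_threshold=0.001, window_kb=10_000)
        assert list(kept.df["variant_id"]) == ["a"]

    def test_independent_pair_both_kept(self):
        stats = make_stats(variant_id=("a", "b"), beta=(0.1, 0.1), se=(0.01, 0.01),
                           pval=(1e-10, 1e-9), eaf=(0.2, 0.2),
                           effect_allele=("A", "A"), other_allele=("G", "G"))
        kept = ld_clump(stats, LDTable(), r2_threshold=0.001)
        assert kept.n_variants == 2

    def test_three_mutually_correlated(self):
        stats = make_stats(pval=(1e-12, 1e-10, 1e-9))
        ld = LDTable({("rs1", "rs2"): 0.9, ("rs1", "rs3"): 0.9, ("rs2", "rs3"): 0.9})
        kept = ld_clump(stats, ld)
        assert list(kept.df["variant_id"]) == ["rs1"]

    def test_window_limits_pruning(self):
        # correlated but 20 Mb apart: outside the window, both survive
        stats = make_stats(variant_id=("a", "b"), beta=(0.1, 0.1), se=(0.01, 0.01),
                           pval=(1e-10, 1e-9), eaf=(0.2, 0.2),
                           effect_allele=("A", "A"), other_allele=("G", "G"),
                           pos=(1_000_000, 21_000_000))
        kept = ld_clump(stats, LDTable({("a", "b"): 0.9}))
        assert kept.n_variants == 2

    def test_output_independent_brute_force(self):
        # on random instances no retained pair may violate the pruning rule
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = int(rng.integers(2, 15))
            ids = [f"rs{i}" for i in range(m)]
            stats = make_stats(
                variant_id=ids, beta=[0.1] * m, se=[0.01] * m,
                pval=list(rng.uniform(1e-12, 1e-6, m)), eaf=[0.2] * m,
                effect_allele=["A"] * m, other_allele=["G"] * m,
                pos=list(rng.choice(np.arange(1, 30) * 1_000_000, m, replace=False)),
            )
            ld = LDTable()
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.4:
                        ld.add(ids[i], ids[j], float(rng.random()))
            kept = ld_clump(stats, ld, r2_threshold=0.1, window_kb=10_000)
            pos = dict(zip(stats.df["variant_id"], stats.df["pos"]))
            for i, a in enumerate(kept.df["variant_id"]):
                for b in kept.df["variant_id"][i + 1:]:
                    violates = abs(pos[a] - pos[b]) <= 10_000_000 and ld.r2(a, b) >= 0.1
                    assert not violates, (a, b)


class TestProxies:
    table = pd.DataFrame(
        {
            "target_id": ["rs1", "rs1", "rs2"],
            "proxy_id": ["p1", "p2", "p3"],
            "r2": [0.95, 0.85, 0.7],
            "allele_map": ["A=T,G=C", "A=A,G=G", "A=A,G=G"],
        }
    )

    def test_best_proxy_chosen(self):
        mapping, dropped = substitute_proxies(["rs1"], self.table)
        assert mapping == {"rs1": "p1"} and dropped == []

    def test_low_r2_dropped(self):
        mapping, dropped = substitute_proxies(["rs2"], self.table)
        assert mapping == {} and dropped == ["rs2"]

    def test_empty_missing_set(self):
        mapping, dropped = substitute_proxies([], self.table)
        assert mapping == {} and dropped == []

    def test_availability_filter(self):
        mapping, _ = substitute_proxies(["rs1"], self.table, available_ids={"p2"})
        assert mapping == {"rs1": "p2"}

    def test_allele_map_applied(self):
        stats = make_stats(variant_id=("rs1", "rs9", "rs8"),
                           effect_allele=("A", "C", "C"), other_allele=("G", "T", "T"))
        out = apply_proxies(stats, {"rs1": "p1"}, self.table)
        row = out.df[out.df["variant_id"] == "p1"].iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("T", "C")


class TestHarmonize:
    def test_allele_swap_flips_beta(self):
        exp = make_stats("X", variant_id=("rs1",), beta=(0.1,), se=(0.01,),
                         pval=(1e-9,), eaf=(0.2,), effect_allele=("A",), other_allele=("G",))
        out = make_stats("Y", variant_id=("rs1",), beta=(-0.05,), se=(0.02,),
                         pval=(0.5,), eaf=(0.8,), effect_allele=("G",), other_allele=("A",))
        h = harmonize([exp], out)
        assert h.beta_y[0] == pytest.approx(0.05)
        assert h.actions[0] == "flipped"
        assert h.eaf_outcome[0] == pytest.approx(0.2)

    def test_strand_flip_resolved(self):
        exp = make_stats("X", variant_id=("rs1",), beta=(0.1,), se=(0.01,),
                         pval=(1e-9,), eaf=(0.2,), effect_allele=("A",), other_allele=("G",))
        out = make_stats("Y", variant_id=("rs1",), beta=(0.05,), se=(0.02,),
                         pval=(0.5,), eaf=(0.2,), effect_allele=("T",), other_allele=("C",))
        h = harmonize([exp], out)
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_palindromic_high_maf_dropped(self):
        exp = make_stats("X", variant_id=("rs1", "rs2"), beta=(0.1, 0.1), se=(0.01, 0.01),
                         pval=(1e-9, 1e-9), eaf=(0.45, 0.2),
                         effect_allele=("A", "C"), other_allele=("T", "G"))
        out = make_stats("Y", variant_id=("rs1", "rs2"), beta=(0.05, 0.05), se=(0.02, 0.02),
                         pval=(0.5, 0.5), eaf=(0.45, 0.2),
                         effect_allele=("A", "C"), other_allele=("T", "G"))
        h = harmonize([exp], out)
        assert list(h.variant_id) == ["rs2"]
        assert list(h.dropped["action"]) == ["dropped_palindromic"]

    def test_palindromic_low_maf_frequency_flip(self):
        # exposure EAF 0.10, outcome EAF 0.88: concordant only under a
        # strand flip, so the outcome beta changes sign
        exp = make_stats("X", variant_id=("rs1",), beta=(0.1,), se=(0.01,),
                         pval=(1e-9,), eaf=(0.10,), effect_allele=("A",), other_allele=("T",))
        out = make_stats("Y", variant_id=("rs1",), beta=(0.05,), se=(0.02,),
                         pval=(0.5,), eaf=(0.88,), effect_allele=("A",), other_allele=("T",))
        h = harmonize([exp], out)
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped(self):
        exp = make_stats("X", variant_id=("rs1", "rs2"), beta=(0.1, 0.1), se=(0.01, 0.01),
                         pval=(1e-9, 1e-9), eaf=(0.2, 0.2),
                         effect_allele=("A", "C"), other_allele=("G", "G"))
        out = make_stats("Y", variant_id=("rs1", "rs2"), beta=(0.05, 0.05), se=(0.02, 0.02),
                         pval=(0.5, 0.5), eaf=(0.2, 0.2),
                         effect_allele=("A", "C"), other_allele=("C", "G"))
        h = harmonize([exp], out)
        assert list(h.variant_id) == ["rs2"]
        assert list(h.dropped["action"]) == ["dropped_incompatible"]

    def test_empty_overlap_raises(self):
        exp = make_stats("X", variant_id=("rs1",), beta=(0.1,), se=(0.01,),
                         pval=(1e-9,), eaf=(0.2,), effect_allele=("A",), other_allele=("G",))
        out = make_stats("Y", variant_id=("rs9",), beta=(0.05,), se=(0.02,),
                         pval=(0.5,), eaf=(0.2,), effect_allele=("A",), other_allele=("G",))
        with pytest.raises(HarmonizationError):
            harmonize([exp], out)

    def test_idempotent(self):
        from mrmediate.summary_stats import SummaryStats

        exp = make_stats("X", eaf=(0.2, 0.3, 0.4))
        out = make_stats("Y", beta=(0.05, -0.02, 0.01), pval=(0.5, 0.5, 0.5),
                         eaf=(0.8, 0.3, 0.4),
                         effect_allele=("G", "C", "G"), other_allele=("A", "T", "A"))
        h1 = harmonize([exp], out)
        # rebuild the outcome from the harmonized orientation and re-harmonize
        df = exp.df[exp.df["variant_id"].isin(h1.variant_id)].copy()
        df["beta"] = h1.beta_y
        df["se"] = h1.se_y
        df["eaf"] = h1.eaf_outcome
        h2 = harmonize([exp.subset(h1.variant_id)], SummaryStats("Y", "binary", df))
        np.testing.assert_allclose(h2.beta_y, h1.beta_y)
        assert all(h2.actions == "kept")

    def test_sign_convention_invariance(self):
        # swapping alleles and negating beta in the outcome file must give
        # the same harmonized effects (only the action labels may differ)
        exp = make_stats("X")
        out = make_stats("Y", beta=(0.05, -0.02, 0.01), pval=(0.5, 0.5, 0.5))
        swapped = out.df.copy()
        swapped["effect_allele"], swapped["other_allele"] = (
            out.df["other_allele"], out.df["effect_allele"])
        swapped["beta"] = -out.df["beta"]
        swapped["eaf"] = 1.0 - out.df["eaf"]
        from mrmediate.summary_stats import SummaryStats

        h1 = harmonize([exp], out)
        h2 = harmonize([exp], SummaryStats("Y", "binary", swapped))
        np.testing.assert_allclose(h1.beta_y, h2.beta_y)
        np.testing.assert_allclose(h1.eaf_outcome, h2.eaf_outcome)
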