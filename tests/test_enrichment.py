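"""Paired-read merging, round counting, fold enrichment and variant calling."""

import numpy as np
import pandas as pd
import pytest

from bescreen import enrichment as en
from bescreen.enrichment import (
    MergeParams,
    SiteSpec,
    call_substitutions,
    count_variants,
    enumerate_combinatorial_library,
    fold_enrichment,
    merge_pair,
    select_hits,
)


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="module")
def amplicon_100mer(rng):
    return "".join(rng.choice(list("ACGT"), size=100))


class TestMerge:
    def test_reconstructs_known_amplicon(self, amplicon_100mer):
        s = amplicon_100mer
        # brute-force oracle: the only offset with a perfect >=15 nt overlap
        # is 40, so the merge must reproduce S exactly
        merged = merge_pair(s[:60], _revcomp(s[40:]))
        assert merged.merged
        assert merged.sequence == s
        assert merged.overlap_length == 20

    def test_full_overlap_is_idempotent(self, amplicon_100mer):
        r1 = amplicon_100mer[:60]
        merged = merge_pair(r1, _revcomp(r1))
        assert merged.sequence == r1

    def test_disjoint_reads_fail_to_merge(self):
        merged = merge_pair("A" * 30, _revcomp("C" * 30))
        assert not merged.merged and merged.sequence == ""

    def test_quality_resolves_disagreements(self, amplicon_100mer):
        s = amplicon_100mer
        r1 = s[:60]
        r2_seq = list(s[40:])
        r2_seq[0] = "A" if s[40] != "A" else "G"  # disagree at overlap start
        r2 = _revcomp("".join(r2_seq))
        hi, lo = [40] * 60, [10] * 60
        take_r2 = merge_pair(r1, r2, qual1=lo, qual2=hi)
        assert take_r2.sequence[40] == r2_seq[0]
        take_r1 = merge_pair(r1, r2, qual1=hi, qual2=lo)
        assert take_r1.sequence[40] == s[40]
        # equal quality: ties go to read 1
        tie = merge_pair(r1, r2, qual1=lo, qual2=lo)
        assert tie.sequence[40] == s[40]

    def test_mismatch_fraction_gate(self, amplicon_100mer):
        s = amplicon_100mer
        r2 = list(s[40:])
        for k in range(0, 20, 3):  # 7 mismatches in a 20 nt overlap
            r2[k] = "A" if r2[k] != "A" else "C"
        merged = merge_pair(s[:60], _revcomp("".join(r2)),
                            params=MergeParams(max_mismatch_frac=0.1))
        # the noisy 20-mer overlap is rejected; any surviving merge must
        # have an acceptable mismatch fraction
        if merged.merged:
            assert merged.n_mismatches / merged.overlap_length <= 0.1


class TestCounting:
    def test_exact_counts(self):
        table = count_variants({1: ["X", "X", "X", "Y"], 2: ["Y", "Y"]})
        assert table.loc["X", "round_1"] == 3
        assert table.loc["Y", "round_1"] == 1
        assert table.loc["X", "round_2"] == 0
        assert table.loc["Y", "round_2"] == 2

    def test_order_invariance(self):
        a = count_variants({1: ["X", "Y", "X"], 2: ["Y"]})
        b = count_variants({1: ["X", "X", "Y"], 2: ["Y"]})
        pd.testing.assert_frame_equal(a, b)


class TestFoldEnrichment:
    @staticmethod
    def _table(counts_by_variant):
        return pd.DataFrame(
            counts_by_variant,
            index=[f"round_{i + 1}" for i in range(4)],
        ).T.rename(columns=lambda c: c)

    def test_worked_fold(self):
        # freq_1 = 1e-6, freq_4 = 2e-3 -> fold 2000
        table = pd.DataFrame(
            {
                "round_1": [1, 999_999],
                "round_4": [2_000, 998_000],
            },
            index=pd.Index(["hit", "bulk"], name="variant"),
        )
        rec = fold_enrichment(table)
        assert rec.loc["hit", "fold_change"] == pytest.approx(2000.0)
        assert select_hits(rec) == ["hit"]

    def test_flat_frequencies_fold_one(self):
        table = pd.DataFrame(
            {"round_1": [10, 30], "round_4": [100, 300]},
            index=pd.Index(["a", "b"], name="variant"),
        )
        rec = fold_enrichment(table)
        assert rec["fold_change"].tolist() == pytest.approx([1.0, 1.0])
        assert select_hits(rec) == []

    def test_absent_in_final_round_gives_zero(self):
        table = pd.DataFrame(
            {"round_1": [5, 5], "round_4": [0, 10]},
            index=pd.Index(["gone", "ok"], name="variant"),
        )
        rec = fold_enrichment(table)
        assert rec.loc["gone", "fold_change"] == 0.0

    def test_pseudocount_caps_unseen_variants(self):
        table = pd.DataFrame(
            {"round_1": [0, 1000], "round_4": [500, 500]},
            index=pd.Index(["new", "old"], name="variant"),
        )
        rec = fold_enrichment(table, pseudocount=0.5)
        # denominator frequency floored at 0.5/1000
        assert rec.loc["new", "fold_change"] == pytest.approx(
            0.5 / (0.5 / 1000)
        )

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {f"round_{r}": rng.integers(1, 100, size=8) for r in range(1, 5)},
            index=pd.Index([f"v{i}" for i in range(8)], name="variant"),
        )
        rec = fold_enrichment(table)
        for r in range(1, 5):
            assert rec[f"freq_{r}"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            {f"round_{r}": rng.integers(1, 100, size=8) for r in range(1, 5)},
            index=pd.Index([f"v{i}" for i in range(8)], name="variant"),
        )
        scaled = table.copy()
        scaled["round_4"] = scaled["round_4"] * 17
        a = fold_enrichment(table)["fold_change"]
        b = fold_enrichment(scaled)["fold_change"]
        np.testing.assert_allclose(a, b)

    def test_single_round_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(pd.DataFrame({"round_1": [1]}))


class TestSelectHits:
    def test_strict_threshold_boundary(self):
        rec = pd.DataFrame(
            {"fold_change": [2000.0, 1000.0, 999.0]},
            index=pd.Index(["a", "b", "c"], name="variant"),
        )
        # "more than" 1000-fold: exactly 1000 is excluded
        assert select_hits(rec, threshold=1000.0) == ["a"]

    def test_empty_and_all_below(self):
        assert select_hits(pd.DataFrame({"fold_change": []})) == []
        rec = pd.DataFrame(
            {"fold_change": [1.0, 2.0]},
            index=pd.Index(["a", "b"], name="variant"),
        )
        assert select_hits(rec) == []


class TestVariantCalling:
    ORF = "ATG" + "AAA" * 40 + "TAA"  # 42 codons, K everywhere after M

    def test_single_codon_substitution(self):
        # codon 31 AAA -> AAT gives K31N (codon-table oracle: AAT = Asn)
        var = self.ORF[: 30 * 3] + "AAT" + self.ORF[31 * 3 :]
        call = call_substitutions(var, self.ORF)
        assert call.substitutions == (("K", 31, "N"),)
        assert not call.frameshift

    def test_identical_sequences(self):
        call = call_substitutions(self.ORF, self.ORF)
        assert call.substitutions == ()
        assert not call.frameshift and not call.synonymous_only

    def test_synonymous_only(self):
        var = self.ORF[: 30 * 3] + "AAG" + self.ORF[31 * 3 :]  # AAA->AAG both K
        call = call_substitutions(var, self.ORF)
        assert call.synonymous_only and not call.substitutions

    def test_frameshift_from_single_deletion(self):
        var = self.ORF[: 30 * 3] + self.ORF[30 * 3 + 1 :]
        assert call_substitutions(var, self.ORF).frameshift

    def test_internal_stop_in_reference_rejected(self):
        bad = "ATG" + "TAA" + "AAA" * 3 + "TAA"
        with pytest.raises(ValueError):
            call_substitutions(bad, bad)


class TestCombinatorialLibrary:
    SITES = [
        SiteSpec(14, "R", ("R", "D", "W")),
        SiteSpec(17, "Q", ("Q", "P")),
        SiteSpec(33, "V", ("V", "F", "H", "W", "Y")),
        SiteSpec(39, "K", ("K", "A", "I")),
    ]

    def test_four_site_library_has_90_members(self):
        lib = enumerate_combinatorial_library(self.SITES, include_wt=True)
        assert len(lib) == 3 * 2 * 5 * 3 == 90
        assert "RQVK" in set(lib["name"])  # all-wild-type member

    def test_single_site(self):
        lib = enumerate_combinatorial_library([SiteSpec(5, "A", ("A", "G"))])
        assert list(lib["name"]) == ["AG"[i] for i in range(2)]

    def test_size_is_product_of_site_sets(self):
        lib = enumerate_combinatorial_library(self.SITES)
        brute = [
            (a, b, c, d)
            for a in "RDW"
            for b in "QP"
            for c in "VFHWY"
            for d in "KAI"
        ]
        assert len(lib) == len(brute)
        assert set(lib["name"]) == {"".join(t) for t in brute}

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinatorial_library(
                [SiteSpec(5, "A", ("A",)), SiteSpec(5, "G", ("G",))]
            )
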