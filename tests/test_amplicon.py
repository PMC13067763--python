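"""PAM-relative coordinates, reference assembly, alignment and quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bescreen import amplicon as amp
from bescreen.amplicon import (
    FIXED_SUFFIX,
    AlignParams,
    align_read,
    build_reference,
    find_editable_cytosines,
    infer_editing_window,
    pam_relative_position,
    quantify,
)

PREP2 = "GTAGGTTCGACTCCTATTAT"
PREP7 = "GTCGTCTTCAACGTTCCTTC"
PREP12 = "GCATGGAGCAGATTCTGCCA"


class TestCoordinates:
    @pytest.mark.parametrize(
        "index, expected", [(8, 13), (20, 1), (1, 20), (6, 15)]
    )
    def test_pam_relative_position(self, index, expected):
        assert pam_relative_position(index) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=20))
    def test_mapping_is_an_involution(self, index):
        assert pam_relative_position(pam_relative_position(index)) == index

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pam_relative_position(0)
        with pytest.raises(ValueError):
            pam_relative_position(21)

    @pytest.mark.parametrize(
        "spacer, expected",
        [
            (PREP2, {13}),
            (PREP7, {12, 15}),
            (PREP12, {12}),
            ("AAAATTTTAAAATTTTAAAA", set()),
        ],
    )
    def test_editable_cytosines_in_window(self, spacer, expected):
        assert find_editable_cytosines(spacer, (12, 17)) == expected

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            find_editable_cytosines("N" * 20)


class TestReference:
    def test_assembly_order_and_length(self):
        ref = build_reference("ACGT", PREP2, "TGG")
        assert ref.full_sequence == "ACGT" + "GA" + PREP2 + "TGG" + FIXED_SUFFIX
        assert len(ref.full_sequence) == 4 + 2 + 20 + 3 + 30
        assert ref.analysis_window == (11, 19)

    def test_intervals_consistent(self):
        ref = build_reference("ACGTACGT", PREP2, "TGG")
        s, e = ref.protospacer_interval
        assert ref.full_sequence[s:e] == PREP2
        ps, pe = ref.pam_interval
        assert ref.full_sequence[ps:pe] == "TGG"
        # PAM-relative position 1 is the PAM-proximal protospacer base
        assert ref.full_sequence[ref.pam_relative_to_ref(1)] == PREP2[-1]
        assert ref.ref_to_pam_relative(ref.pam_relative_to_ref(13)) == 13

    def test_wrong_protospacer_length_rejected(self):
        with pytest.raises(ValueError):
            build_reference("ACGT", PREP2[:19], "TGG")
        with pytest.raises(ValueError):
            build_reference("ACGT", PREP2, "")


class TestAlignment:
    def test_identical_read_has_no_edits(self, prep2_reference):
        aln = align_read(prep2_reference.full_sequence, prep2_reference)
        assert aln.aligned and not aln.has_edits and aln.identity == 1.0

    def test_single_substitution_at_position_13(self, prep2_reference):
        ref = prep2_reference
        r0 = ref.pam_relative_to_ref(13)
        read = ref.full_sequence[:r0] + "T" + ref.full_sequence[r0 + 1 :]
        aln = align_read(read, ref)
        assert aln.substitutions == [(r0, "C", "T")]
        assert not aln.insertions and not aln.deletions

    def test_deletion_inside_protospacer(self, prep2_reference):
        ref = prep2_reference
        s = ref.protospacer_interval[0] + 5
        read = ref.full_sequence[:s] + ref.full_sequence[s + 3 :]
        aln = align_read(read, ref)
        assert len(aln.deletions) == 1
        assert aln.indel_overlaps(ref.indel_region)

    def test_garbage_read_flagged_unaligned(self, prep2_reference):
        aln = align_read("T" * 60, prep2_reference)
        assert not aln.aligned


def _edited_alignments(ref, n_clean=8, n_sub=0, n_del=0, position=13):
    """Hand-constructed alignment mixtures for quantification tests."""
    clean = align_read(ref.full_sequence, ref)
    r0 = ref.pam_relative_to_ref(position)
    sub_read = ref.full_sequence[:r0] + "T" + ref.full_sequence[r0 + 1 :]
    sub = align_read(sub_read, ref)
    s = ref.protospacer_interval[0] + 5
    del_read = ref.full_sequence[:s] + ref.full_sequence[s + 3 :]
    dele = align_read(del_read, ref)
    return [clean] * n_clean + [sub] * n_sub + [dele] * n_del


class TestQuantify:
    def test_direct_indel_ratio(self, prep2_reference):
        alns = _edited_alignments(prep2_reference, n_clean=8, n_del=2)
        result, _ = quantify(alns, prep2_reference)
        assert result.indel_pct == pytest.approx(20.0)
        assert result.n_reads_aligned == 10

    def test_all_reference_reads_have_zero_rates(self, prep2_reference):
        result, table = quantify(
            _edited_alignments(prep2_reference, n_clean=5), prep2_reference
        )
        assert result.c_to_t_window_pct == 0.0
        assert result.indel_pct == 0.0
        assert table[["c_to_t", "c_to_a", "c_to_g"]].to_numpy().sum() == 0

    def test_substitution_counted_at_pam_relative_position(self, prep2_reference):
        _, table = quantify(
            _edited_alignments(prep2_reference, n_clean=6, n_sub=4),
            prep2_reference,
        )
        row = table[table.position == 13].iloc[0]
        assert row.ref_base == "C"
        assert row.c_to_t == 4 and row.depth == 10
        assert row.c_to_t_rate == pytest.approx(0.4)

    def test_c_to_d_bounds_c_to_t(self, prep2_reference):
        ref = prep2_reference
        r0 = ref.pam_relative_to_ref(13)
        to_t = ref.full_sequence[:r0] + "T" + ref.full_sequence[r0 + 1 :]
        to_g = ref.full_sequence[:r0] + "G" + ref.full_sequence[r0 + 1 :]
        alns = [align_read(s, ref) for s in (to_t, to_g, ref.full_sequence)]
        result, _ = quantify(alns, ref)
        assert result.c_to_t_window_pct <= result.c_to_d_window_pct

    def test_read_order_permutation_invariance(self, prep2_reference):
        alns = _edited_alignments(prep2_reference, n_clean=5, n_sub=3, n_del=2)
        r1, t1 = quantify(alns, prep2_reference)
        r2, t2 = quantify(alns[::-1], prep2_reference)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_indel_reads_excluded_from_substitution_denominator(
        self, prep2_reference
    ):
        _, table = quantify(
            _edited_alignments(prep2_reference, n_clean=7, n_del=3),
            prep2_reference,
        )
        assert table[table.position == 13].depth.iloc[0] == 7

    def test_zero_aligned_reads_error(self, prep2_reference):
        unaligned = align_read("T" * 60, prep2_reference)
        with pytest.raises(ValueError):
            quantify([unaligned], prep2_reference)

    def test_read_class_partition(self, prep2_reference):
        """unaligned + indel + substitution-only + unedited = total."""
        ref = prep2_reference
        alns = _edited_alignments(ref, n_clean=4, n_sub=3, n_del=2)
        alns.append(align_read("T" * 60, ref))
        n_unaligned = sum(not a.aligned for a in alns)
        aligned = [a for a in alns if a.aligned]
        n_indel = sum(a.indel_overlaps(ref.indel_region) for a in aligned)
        rest = [a for a in aligned if not a.indel_overlaps(ref.indel_region)]
        n_sub_only = sum(a.has_edits for a in rest)
        n_unedited = sum(not a.has_edits for a in rest)
        assert n_unaligned + n_indel + n_sub_only + n_unedited == len(alns)


class TestWindowInference:
    @staticmethod
    def _table(rates):
        return pd.DataFrame(
            {"position": range(1, 21), "c_to_t_rate": rates}
        )

    def test_peaked_profile_recovers_window(self):
        rates = [0.01] * 20
        for p in range(12, 18):
            rates[p - 1] = 0.25
        # brute-force oracle: longest run >= 0.3 * 0.25 is exactly 12..17
        assert infer_editing_window(self._table(rates)) == (12, 17)

    def test_single_nonzero_position(self):
        rates = [0.0] * 20
        rates[6] = 0.4
        assert infer_editing_window(self._table(rates)) == (7, 7)

    def test_uniform_profile_spans_everything(self):
        assert infer_editing_window(self._table([0.2] * 20)) == (1, 20)

    def test_tie_resolves_pam_proximal(self):
        rates = [0.0] * 20
        rates[2] = rates[3] = 0.5  # positions 3-4
        rates[10] = rates[11] = 0.5  # positions 11-12
        assert infer_editing_window(self._table(rates)) == (3, 4)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="no editing"):
            infer_editing_window(self._table([0.0] * 20))
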