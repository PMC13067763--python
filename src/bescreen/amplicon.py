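"""Quantification of base-editing outcomes from amplicon sequencing reads.

Reads are globally aligned to a reference amplicon built as

    barcode + "GA" + protospacer(20 nt) + PAM(3 nt) + fixed suffix

and per-position substitution rates, window aggregates and the indel
frequency are computed. Positions along the protospacer use the
PAM-relative convention: the PAM-proximal protospacer base is position 1
and positions increase toward the 5' end, so 5'-index i in a 20-mer maps
to position 21 - i. This is the only convention under which the three
repeat-target spacers used for selection carry their editable cytosines at
positions 13, {12, 15} and 12 inside the 12-17 window.

Indel frequency follows the standard analyzer definition: the percentage
of aligned reads containing insertions or deletions overlapping the
protospacer + PAM region, divided by the total number of aligned reads.
Reads carrying such indels are excluded from substitution-rate numerators
and denominators so that a read is counted in exactly one outcome class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "FIXED_SUFFIX",
    "DEFAULT_ANALYSIS_WINDOW",
    "AmpliconReference",
    "ReadAlignment",
    "QuantResult",
    "AlignParams",
    "pam_relative_position",
    "find_editable_cytosines",
    "build_reference",
    "align_read",
    "quantify",
    "infer_editing_window",
]

#: Fixed reference suffix appended after the PAM when amplicon references
#: are assembled for the exogenous-target (EMsg) reporter system.
FIXED_SUFFIX = "AGCTTGGCGTAACGGCTTAACTAGATTAAT"

#: Default analyzer quantification window in PAM-relative coordinates.
DEFAULT_ANALYSIS_WINDOW = (11, 19)

_DNA = set("ACGT")


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or not set(seq) <= _DNA:
        raise ValueError(f"{what} must be non-empty A/C/G/T, got {seq!r}")
    return seq


def pam_relative_position(index_from_5prime: int, spacer_length: int = 20) -> int:
    """Map a 1-based 5' protospacer index to its PAM-relative position.

    The PAM-proximal base (5' index = spacer_length) is position 1. The
    mapping is its own inverse: applying it twice returns the input.
    """
    if not 1 <= index_from_5prime <= spacer_length:
        raise ValueError(
            f"index {index_from_5prime} outside 1..{spacer_length}"
        )
    return spacer_length - index_from_5prime + 1


def find_editable_cytosines(
    spacer: str, window: tuple[int, int] = (12, 17)
) -> set[int]:
    """PAM-relative positions of protospacer cytosines inside ``window``.

    ``window`` is an inclusive pair of PAM-relative positions within
    [1, 20].
    """
    spacer = _check_dna(spacer, "spacer")
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    lo, hi = window
    if not (1 <= lo <= hi <= 20):
        raise ValueError(f"invalid window {window}")
    return {
        pam_relative_position(i + 1)
        for i, base in enumerate(spacer)
        if base == "C" and lo <= pam_relative_position(i + 1) <= hi
    }


@dataclass(frozen=True)
class AmpliconReference:
    """Reference amplicon with protospacer/PAM annotation.

    Intervals are half-open and 0-based on ``full_sequence``;
    ``analysis_window`` is an inclusive PAM-relative position pair.
    """

    full_sequence: str
    barcode: str
    protospacer: str
    pam: str
    fixed_suffix: str
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    analysis_window: tuple[int, int]

    @property
    def indel_region(self) -> tuple[int, int]:
        """Half-open protospacer+PAM interval used for the indel definition."""
        return (self.protospacer_interval[0], self.pam_interval[1])

    def pam_relative_to_ref(self, position: int) -> int:
        """0-based full-sequence coordinate of a PAM-relative position."""
        if not 1 <= position <= len(self.protospacer):
            raise ValueError(f"PAM-relative position {position} out of range")
        # PAM-relative 1 is the last protospacer base
        return self.protospacer_interval[1] - position

    def ref_to_pam_relative(self, ref_pos: int) -> int | None:
        """PAM-relative position of a full-sequence coordinate, if any."""
        start, end = self.protospacer_interval
        if start <= ref_pos < end:
            return end - ref_pos
        return None


def build_reference(
    barcode: str,
    protospacer: str,
    pam: str,
    fixed_suffix: str = FIXED_SUFFIX,
    analysis_window: tuple[int, int] = DEFAULT_ANALYSIS_WINDOW,
) -> AmpliconReference:
    """Assemble barcode + GA + protospacer + PAM + fixed suffix."""
    barcode = _check_dna(barcode, "barcode")
    protospacer = _check_dna(protospacer, "protospacer")
    pam = _check_dna(pam, "pam")
    fixed_suffix = _check_dna(fixed_suffix, "fixed_suffix")
    if len(protospacer) != 20:
        raise ValueError(f"protospacer must be 20 nt, got {len(protospacer)}")
    lo, hi = analysis_window
    if not (1 <= lo <= hi <= len(protospacer)):
        raise ValueError(f"invalid analysis window {analysis_window}")
    proto_start = len(barcode) + 2
    proto_end = proto_start + len(protospacer)
    return AmpliconReference(
        full_sequence=barcode + "GA" + protospacer + pam + fixed_suffix,
        barcode=barcode,
        protospacer=protospacer,
        pam=pam,
        fixed_suffix=fixed_suffix,
        protospacer_interval=(proto_start, proto_end),
        pam_interval=(proto_end, proto_end + len(pam)),
        analysis_window=(lo, hi),
    )


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring (affine gaps) and acceptance threshold."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    min_identity: float = 0.6


@dataclass
class ReadAlignment:
    """Edits of one read relative to the reference coordinate space.

    ``substitutions`` are (ref_pos0, ref_base, alt_base); ``insertions``
    are (ref_pos0, length) with the inserted bases sitting between
    ref_pos0 - 1 and ref_pos0; ``deletions`` are half-open (start0, end0)
    reference intervals.
    """

    read_id: str
    aligned: bool
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    identity: float = 0.0

    @property
    def has_edits(self) -> bool:
        return bool(self.substitutions or self.insertions or self.deletions)

    def deleted_positions(self) -> set[int]:
        return {p for s, e in self.deletions for p in range(s, e)}

    def indel_overlaps(self, region: tuple[int, int]) -> bool:
        """True if any indel overlaps the half-open reference ``region``.

        A deletion overlaps on non-empty interval intersection; an
        insertion overlaps when its junction falls strictly inside the
        region (an insertion flush with a boundary leaves the region's
        own bases intact).
        """
        start, end = region
        for s, e in self.deletions:
            if s < end and e > start:
                return True
        for pos, _length in self.insertions:
            if start < pos < end:
                return True
        return False


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # end gaps are free so truncated reads are not penalised
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # biopython < 1.88 naming
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    return aligner


def align_read(
    read: str,
    reference: AmpliconReference,
    params: AlignParams = AlignParams(),
    read_id: str = "",
) -> ReadAlignment:
    """Globally align a read to the reference and extract its edits.

    Deterministic under the fixed scoring (the first optimal alignment is
    taken). Reads whose identity over aligned columns falls below
    ``params.min_identity`` are flagged unaligned rather than raising, and
    are later excluded from every denominator.
    """
    read = _check_dna(read, "read")
    ref = reference.full_sequence
    aligner = _make_aligner(params)
    alignment = next(iter(aligner.align(ref, read)))

    result = ReadAlignment(read_id=read_id, aligned=True)
    matches = 0
    columns = 0
    # aligned blocks come in reference/query coordinate pairs; gaps are the
    # complement between consecutive blocks
    ref_blocks, read_blocks = alignment.aligned
    prev_ref_end: int | None = None
    prev_read_end: int | None = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if prev_ref_end is not None:
            if rs > prev_ref_end:  # deletion from the reference
                result.deletions.append((int(prev_ref_end), int(rs)))
                columns += rs - prev_ref_end
            if qs > prev_read_end:  # insertion into the read
                result.insertions.append((int(rs), int(qs - prev_read_end)))
                columns += qs - prev_read_end
        for r, q in zip(range(rs, re_), range(qs, qe)):
            columns += 1
            if ref[r] == read[q]:
                matches += 1
            else:
                result.substitutions.append((int(r), ref[r], read[q]))
        prev_ref_end, prev_read_end = re_, qe

    # identity over the full read length, so a read matching only a short
    # reference segment (free end gaps) cannot score as well-aligned
    result.identity = matches / len(read)
    if result.identity < params.min_identity:
        return ReadAlignment(read_id=read_id, aligned=False, identity=result.identity)
    return result


@dataclass(frozen=True)
class QuantResult:
    """Aggregate editing outcome for one amplicon target.

    All quantities are percentages of reads (indel) or of scorable
    cytosine observations (substitution classes). ``c_to_d_window_pct``
    counts conversion of window cytosines to any non-C base, so it always
    bounds ``c_to_t_window_pct`` from above.
    """

    c_to_t_window_pct: float
    c_to_d_window_pct: float
    out_of_window_c_to_t_pct: float
    other_subs_window_pct: float
    indel_pct: float
    n_reads_aligned: int


def quantify(
    alignments: Iterable[ReadAlignment],
    reference: AmpliconReference,
) -> tuple[QuantResult, pd.DataFrame]:
    """Compute window aggregates, indel frequency and the per-position table.

    Returns ``(QuantResult, table)`` where ``table`` has one row per
    PAM-relative protospacer position 1-20 with columns ``position``,
    ``ref_base``, ``depth``, ``c_to_t``, ``c_to_a``, ``c_to_g`` (counts)
    and the corresponding ``*_rate`` columns. Positions without a
    reference C have zero C->X counts by construction.

    Reads with indels overlapping protospacer+PAM contribute only to
    ``indel_pct``; remaining aligned reads contribute to substitution
    counts at every reference position they cover (deleted positions,
    from indels outside the region, are skipped).
    """
    alignments = list(alignments)
    aligned = [a for a in alignments if a.aligned]
    if not aligned:
        raise ValueError("no aligned reads")

    region = reference.indel_region
    indel_reads = [a for a in aligned if a.indel_overlaps(region)]
    clean_reads = [a for a in aligned if not a.indel_overlaps(region)]
    indel_pct = 100.0 * len(indel_reads) / len(aligned)

    spacer_len = len(reference.protospacer)
    positions = list(range(1, spacer_len + 1))  # PAM-relative
    ref_pos0 = {p: reference.pam_relative_to_ref(p) for p in positions}
    ref_base = {p: reference.full_sequence[ref_pos0[p]] for p in positions}

    depth = {p: 0 for p in positions}
    counts = {p: {"T": 0, "A": 0, "G": 0} for p in positions}
    # window aggregates over the full amplicon (out-of-window C->T is
    # scored at amplicon level, i.e. every reference C outside the window)
    lo, hi = reference.analysis_window
    window_ref0 = {ref_pos0[p] for p in positions if lo <= p <= hi}
    all_c_ref0 = {
        i for i, b in enumerate(reference.full_sequence) if b == "C"
    }
    window_c_ref0 = {i for i in window_ref0 if i in all_c_ref0}
    out_c_ref0 = all_c_ref0 - window_c_ref0

    window_c_depth = 0
    out_c_depth = 0
    window_any_depth = 0
    n_c_to_t_window = 0
    n_c_to_d_window = 0
    n_c_to_t_out = 0
    n_other_subs_window = 0

    for a in clean_reads:
        deleted = a.deleted_positions()
        subs = {pos: alt for pos, _refb, alt in a.substitutions}
        for p in positions:
            r0 = ref_pos0[p]
            if r0 in deleted:
                continue
            depth[p] += 1
            if ref_base[p] == "C" and subs.get(r0) in counts[p]:
                counts[p][subs[r0]] += 1
        for r0 in window_c_ref0:
            if r0 in deleted:
                continue
            window_c_depth += 1
            alt = subs.get(r0)
            if alt == "T":
                n_c_to_t_window += 1
            if alt in ("A", "G", "T"):
                n_c_to_d_window += 1
        for r0 in out_c_ref0:
            if r0 in deleted:
                continue
            out_c_depth += 1
            if subs.get(r0) == "T":
                n_c_to_t_out += 1
        for r0 in window_ref0:
            if r0 in deleted:
                continue
            window_any_depth += 1
            alt = subs.get(r0)
            if alt is not None and not (
                reference.full_sequence[r0] == "C" and alt == "T"
            ):
                n_other_subs_window += 1

    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    table = pd.DataFrame(
        {
            "position": positions,
            "ref_base": [ref_base[p] for p in positions],
            "depth": [depth[p] for p in positions],
            "c_to_t": [counts[p]["T"] for p in positions],
            "c_to_a": [counts[p]["A"] for p in positions],
            "c_to_g": [counts[p]["G"] for p in positions],
        }
    )
    for col in ("c_to_t", "c_to_a", "c_to_g"):
        table[f"{col}_rate"] = np.where(
            table["depth"] > 0, table[col] / table["depth"].clip(lower=1), 0.0
        )

    result = QuantResult(
        c_to_t_window_pct=_pct(n_c_to_t_window, window_c_depth),
        c_to_d_window_pct=_pct(n_c_to_d_window, window_c_depth),
        out_of_window_c_to_t_pct=_pct(n_c_to_t_out, out_c_depth),
        other_subs_window_pct=_pct(n_other_subs_window, window_any_depth),
        indel_pct=indel_pct,
        n_reads_aligned=len(aligned),
    )
    return result, table


def infer_editing_window(
    table: pd.DataFrame, threshold_fraction: float = 0.3
) -> tuple[int, int]:
    """Empirical editing window from a per-position C->T rate profile.

    Returns the maximal contiguous run of PAM-relative positions whose
    C->T rate is at least ``threshold_fraction`` times the maximal
    positional rate. Ties between equal-length runs resolve toward the
    PAM-proximal (lower-position) run.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    profile = (
        table.sort_values("position")[["position", "c_to_t_rate"]]
        .to_numpy()
    )
    rates = profile[:, 1].astype(float)
    if np.all(rates <= 0.0):
        raise ValueError("no editing detected: all C->T rates are zero")
    cutoff = threshold_fraction * rates.max()
    passing = rates >= cutoff
    best: tuple[int, int] | None = None
    run_start = None
    for i, ok in enumerate(list(passing) + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            run = (run_start, i - 1)
            if best is None or (run[1] - run[0]) > (best[1] - best[0]):
                best = run  # strict > keeps the earlier (PAM-proximal) run on ties
            run_start = None
    assert best is not None
    positions = profile[:, 0].astype(int)
    return int(positions[best[0]]), int(positions[best[1]])
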