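"""Synthetic data generators for the editing-quantification and
selection-enrichment pipelines.

Two simulators, each seeded and byte-deterministic, emit data with the
statistical structure the downstream analyses assume together with a
ground-truth ledger, so parameter recovery can be verified without any
external sequencing data:

* :func:`simulate_amplicon_reads` draws edited amplicon reads — position-
  dependent C->T and C->(A/G) conversion at protospacer cytosines, reads
  carrying indels overlapping protospacer+PAM (geometric lengths, uniform
  start), and uniform per-base sequencing error — and returns them as
  overlapping read pairs plus the full molecules and a per-read event
  ledger.

* :func:`simulate_screen_rounds` draws a four-round selection count table.
  Round 1 samples the input library; each later round re-samples after
  multiplying frequencies by a per-variant survival probability modelling
  the three selection axes: activity (start-codon rescue) x
  exp(-dsb_hazard x repeat copy number) x viability (toxicity survival).
  With relative survival s, the expected enrichment after R rounds is
  s**(R-1).

:func:`fixture_set` packages the sequences the selection system is built
from: the three repeat-target spacers with genomic copy numbers 2/7/12,
the fixed amplicon suffix, the mutagenesis primer flanks and the
four-site combinatorial library specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import FIXED_SUFFIX, AmpliconReference
from .enrichment import SiteSpec

__all__ = [
    "EditingSimSpec",
    "SelectionSimSpec",
    "FixtureSet",
    "SimulatedReads",
    "simulate_amplicon_reads",
    "simulate_screen_rounds",
    "fixture_set",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class EditingSimSpec:
    """Parameters of the edited-amplicon read simulator.

    ``c_to_t_prob`` maps PAM-relative protospacer positions to per-read
    C->T conversion probability (only reference-C positions take effect);
    ``c_to_ag_prob`` is the per-position probability of conversion to A or
    G (split evenly). Indels hit a read with probability ``indel_prob``:
    deletion or insertion with equal odds, geometric length (success
    probability ``indel_len_p``), start uniform over protospacer+PAM.
    ``error_rate`` is the uniform per-base sequencing error. Reads are
    emitted as pairs of length ``read_length`` from the two fragment ends.
    """

    c_to_t_prob: Mapping[int, float] = field(default_factory=dict)
    c_to_ag_prob: Mapping[int, float] = field(default_factory=dict)
    indel_prob: float = 0.0
    indel_len_p: float = 0.5
    error_rate: float = 0.0
    n_reads: int = 1000
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            *self.c_to_t_prob.values(),
            *self.c_to_ag_prob.values(),
            self.indel_prob,
            self.error_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass(frozen=True)
class SimulatedReads:
    """Simulator output: read pairs, full molecules and the event ledger.

    ``pairs`` holds (read1, read2) with read2 already reverse-complemented
    relative to the molecule (i.e. as sequenced); ``full_sequences`` are
    the complete edited molecules; ``ledger`` is a DataFrame with one row
    per read recording the true events (conversion positions, indel
    coordinates) before sequencing error.
    """

    pairs: list[tuple[str, str]]
    full_sequences: list[str]
    ledger: pd.DataFrame


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_amplicon_reads(
    reference: AmpliconReference, spec: EditingSimSpec
) -> SimulatedReads:
    """Draw edited amplicon read pairs with a ground-truth ledger.

    Reads are independent. Identical ``spec`` (including seed) gives
    byte-identical output. The ledger records, per read: which
    PAM-relative positions were converted (and to what), the indel type,
    reference start and length, and whether the indel overlaps the
    protospacer+PAM region (always true under this generator's position
    distribution for deletions starting inside it).
    """
    rng = np.random.default_rng(spec.seed)
    ref = reference.full_sequence
    region_start, region_end = reference.indel_region
    records = []
    pairs: list[tuple[str, str]] = []
    fulls: list[str] = []

    for read_idx in range(spec.n_reads):
        seq = list(ref)
        conversions: list[tuple[int, str]] = []  # (PAM-relative pos, alt)
        for pos, p_t in sorted(spec.c_to_t_prob.items()):
            r0 = reference.pam_relative_to_ref(pos)
            if ref[r0] != "C":
                continue
            p_ag = spec.c_to_ag_prob.get(pos, 0.0)
            u = rng.random()
            if u < p_t:
                seq[r0] = "T"
                conversions.append((pos, "T"))
            elif u < p_t + p_ag:
                alt = "A" if rng.random() < 0.5 else "G"
                seq[r0] = alt
                conversions.append((pos, alt))
        for pos, p_ag in sorted(spec.c_to_ag_prob.items()):
            if pos in spec.c_to_t_prob:
                continue
            r0 = reference.pam_relative_to_ref(pos)
            if ref[r0] != "C":
                continue
            if rng.random() < p_ag:
                alt = "A" if rng.random() < 0.5 else "G"
                seq[r0] = alt
                conversions.append((pos, alt))

        indel_type = ""
        indel_start = -1
        indel_len = 0
        if spec.indel_prob and rng.random() < spec.indel_prob:
            indel_len = int(rng.geometric(spec.indel_len_p))
            if rng.random() < 0.5:
                indel_type = "deletion"
                indel_start = int(rng.integers(region_start, region_end))
                del seq[indel_start : indel_start + indel_len]
            else:
                # insertion junctions are drawn strictly interior so the
                # event always disrupts the region under the overlap rule
                indel_type = "insertion"
                indel_start = int(rng.integers(region_start + 1, region_end))
                insert = "".join(rng.choice(list(_BASES), size=indel_len))
                seq[indel_start:indel_start] = list(insert)

        molecule = "".join(seq)
        if spec.error_rate:
            noisy = list(molecule)
            errs = np.nonzero(rng.random(len(noisy)) < spec.error_rate)[0]
            for e in errs:
                choices = [b for b in _BASES if b != noisy[e]]
                noisy[e] = choices[int(rng.integers(3))]
            molecule_seq = "".join(noisy)
        else:
            molecule_seq = molecule

        fulls.append(molecule_seq)
        read_len = min(spec.read_length, len(molecule_seq))
        pairs.append(
            (molecule_seq[:read_len], _revcomp(molecule_seq[-read_len:]))
        )
        records.append(
            {
                "read": read_idx,
                "conversions": tuple(conversions),
                "n_c_to_t": sum(1 for _p, a in conversions if a == "T"),
                "indel_type": indel_type,
                "indel_start": indel_start,
                "indel_length": indel_len,
            }
        )

    return SimulatedReads(
        pairs=pairs, full_sequences=fulls, ledger=pd.DataFrame(records)
    )


@dataclass(frozen=True)
class SelectionSimSpec:
    """Parameters of the multi-round selection simulator.

    Per-variant survival combines the three selection axes as
    ``activity * exp(-dsb_hazard * copy_number) * viability``; each term
    defaults to neutral. ``bottleneck`` is the number of colonies sampled
    per round (multinomial draw).
    """

    activity: Mapping[str, float] = field(default_factory=dict)
    dsb_hazard: Mapping[str, float] = field(default_factory=dict)
    viability: Mapping[str, float] = field(default_factory=dict)
    copy_number: int = 2
    rounds: int = 4
    bottleneck: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copy_number not in (2, 7, 12):
            raise ValueError("copy_number must be one of the repeat designs 2/7/12")
        if self.rounds < 2:
            raise ValueError("need at least two rounds")
        for table in (self.activity, self.dsb_hazard, self.viability):
            if any(v < 0 for v in table.values()):
                raise ValueError("fitness components must be >= 0")

    def survival(self, variant: str) -> float:
        s = (
            self.activity.get(variant, 1.0)
            * np.exp(-self.dsb_hazard.get(variant, 0.0) * self.copy_number)
            * self.viability.get(variant, 1.0)
        )
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"survival for {variant} outside [0, 1]: {s}")
        return float(s)


def simulate_screen_rounds(
    library: Sequence[str],
    spec: SelectionSimSpec,
    initial_frequencies: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an R-round selection and return (count table, ground truth).

    Round 1 is a multinomial sample of the input library at its initial
    frequencies (uniform by default) — no selection has acted yet. Each
    subsequent round multiplies the current frequencies by per-variant
    survival, renormalises, and draws a fresh multinomial bottleneck. The
    truth table records each variant's survival probability and its
    expected final/first fold change ``(s / mean_s)**(R-1)`` — the
    infinite-bottleneck geometric-growth expectation, accurate while the
    variant remains rare (enriching variants saturate below it as they
    take over the pool).
    """
    if not library:
        raise ValueError("library must be non-empty")
    variants = list(library)
    n = len(variants)
    if initial_frequencies is None:
        freq = np.full(n, 1.0 / n)
    else:
        freq = np.asarray(initial_frequencies, dtype=float)
        freq = freq / freq.sum()
    survival = np.array([spec.survival(v) for v in variants])
    if survival.sum() == 0:
        raise ValueError("library extinct: all survival probabilities are zero")

    rng = np.random.default_rng(spec.seed)
    counts = {}
    p = freq.copy()
    for r in range(1, spec.rounds + 1):
        if r > 1:
            weighted = p * survival
            total = weighted.sum()
            if total == 0:
                raise ValueError("library extinct during selection")
            p = weighted / total
        draw = rng.multinomial(spec.bottleneck, p)
        counts[f"round_{r}"] = draw
        p = draw / draw.sum()

    table = pd.DataFrame(counts, index=pd.Index(variants, name="variant"))
    # deterministic-regime expectation for the fold change
    mean_s = float((freq * survival).sum())
    expected_fold = (survival / mean_s) ** (spec.rounds - 1) if mean_s else np.nan
    truth = pd.DataFrame(
        {
            "survival": survival,
            "expected_fold": expected_fold,
        },
        index=pd.Index(variants, name="variant"),
    )
    return table, truth


@dataclass(frozen=True)
class FixtureSet:
    """Sequences the bacterial selection system is built from.

    ``prep_spacers`` maps genomic repeat copy number to the 20-nt spacer
    of the corresponding selection plasmid; their editable cytosines fall
    at PAM-relative positions 13 (n=2), 12 and 15 (n=7), and 12 (n=12).
    ``mutagenesis_flanks`` are the primer pair bracketing the deaminase
    coding region for random mutagenesis. ``fourmix_sites`` is the
    four-site combinatorial library specification (90 members with wild
    type included).
    """

    prep_spacers: dict[int, str]
    fixed_suffix: str
    mutagenesis_flanks: tuple[str, str]
    fourmix_sites: tuple[SiteSpec, ...]


def fixture_set() -> FixtureSet:
    """Packaged sequence constants used across the pipeline tests."""
    return FixtureSet(
        prep_spacers={
            2: "GTAGGTTCGACTCCTATTAT",
            7: "GTCGTCTTCAACGTTCCTTC",
            12: "GCATGGAGCAGATTCTGCCA",
        },
        fixed_suffix=FIXED_SUFFIX,
        mutagenesis_flanks=(
            "TCACCAAAGAAGAAGCGGAAAGTCAAGCTT",
            "GCCGGAGCTGCCACCGGAGGAGCCTCCGCT",
        ),
        fourmix_sites=(
            SiteSpec(position=14, wild_type="R", allowed=("R", "D", "W")),
            SiteSpec(position=17, wild_type="Q", allowed=("Q", "P")),
            SiteSpec(position=33, wild_type="V", allowed=("V", "F", "H", "W", "Y")),
            SiteSpec(position=39, wild_type="K", allowed=("K", "A", "I")),
        ),
    )
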