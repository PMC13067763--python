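"""Multi-round selection sequencing analysis for directed evolution.

A deaminase variant library passes through iterative rounds of a bacterial
triple selection (base-editing activity rescuing a defective resistance
start codon, elimination of double-strand-break-prone variants via guides
against genomic repeats, and tolerance of continuous expression). Round 1
is the sequenced input library; each later round is the pool recovered
after another selection cycle. Paired amplicon reads are merged by
ungapped overlap, the reconstructed sequences are counted cumulatively per
round, and variants whose relative abundance rises more than 1000-fold
between the first and final rounds are called hits.

Also provided: protein-level substitution calling against the reference
open reading frame, and enumeration of combinatorial mutant libraries from
per-site allowed-residue specifications (e.g. the 90-member four-site
library R14:{R,D,W} x Q17:{Q,P} x V33:{V,F,H,W,Y} x K39:{K,A,I}).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "MergedRead",
    "MergeParams",
    "VariantCall",
    "SiteSpec",
    "merge_pair",
    "count_variants",
    "fold_enrichment",
    "select_hits",
    "call_substitutions",
    "enumerate_combinatorial_library",
    "collapse_to_protein",
]


@dataclass(frozen=True)
class MergeParams:
    """Ungapped paired-read overlap merging parameters."""

    min_overlap: int = 15
    max_mismatch_frac: float = 0.1


@dataclass(frozen=True)
class MergedRead:
    """Result of merging one read pair; ``merged`` is False on failure."""

    sequence: str
    merged: bool
    overlap_length: int = 0
    n_mismatches: int = 0


def merge_pair(
    read1: str,
    read2: str,
    qual1: Sequence[int] | None = None,
    qual2: Sequence[int] | None = None,
    params: MergeParams = MergeParams(),
) -> MergedRead:
    """Reconstruct an amplicon from a read pair by ungapped overlap.

    Read 2 is reverse-complemented, every 3'-of-read-1 overlap offset of
    at least ``min_overlap`` bases is scored, and the candidate with the
    most matching bases (ties to the longer overlap) whose mismatch
    fraction is within ``max_mismatch_frac`` is taken. Disagreements
    inside the overlap resolve to the higher-quality base, ties to read 1.
    Pairs with no acceptable overlap come back flagged unmerged — merging
    never raises on poor data.
    """
    if not read1 or not read2:
        raise ValueError("reads must be non-empty")
    r1 = read1.upper()
    r2 = str(Seq(read2.upper()).reverse_complement())
    q1 = list(qual1) if qual1 is not None else [30] * len(r1)
    q2 = list(qual2) if qual2 is not None else [30] * len(r2)
    if len(q1) != len(r1) or len(q2) != len(r2):
        raise ValueError("quality length must match read length")
    q2 = q2[::-1]  # follow the reverse complement

    best: tuple[int, int, int] | None = None  # (matches, overlap, offset)
    max_overlap = min(len(r1), len(r2))
    # offset = position in r1 where r2 starts; r2 extends the fragment 3'
    for overlap in range(params.min_overlap, max_overlap + 1):
        offset = len(r1) - overlap
        seg1 = r1[offset:]
        seg2 = r2[:overlap]
        mismatches = sum(a != b for a, b in zip(seg1, seg2))
        if mismatches / overlap > params.max_mismatch_frac:
            continue
        matches = overlap - mismatches
        cand = (matches, overlap, offset)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return MergedRead(sequence="", merged=False)

    _matches, overlap, offset = best
    consensus = []
    for k in range(overlap):
        a, b = r1[offset + k], r2[k]
        if a == b:
            consensus.append(a)
        elif q2[k] > q1[offset + k]:
            consensus.append(b)
        else:
            consensus.append(a)
    merged = r1[:offset] + "".join(consensus) + r2[overlap:]
    return MergedRead(
        sequence=merged,
        merged=True,
        overlap_length=overlap,
        n_mismatches=overlap - _matches,
    )


def count_variants(
    reads_per_round: Mapping[int, Iterable[str]],
) -> pd.DataFrame:
    """Cumulative sequence-keyed counts per selection round.

    ``reads_per_round`` maps round number (1-based) to reconstructed,
    trimmed variant sequences. Returns a DataFrame indexed by variant
    sequence with one integer column per round (``round_1`` ...), rows
    sorted by sequence for determinism.
    """
    rounds = sorted(reads_per_round)
    counters = {r: Counter(reads_per_round[r]) for r in rounds}
    variants = sorted(set().union(*[set(c) for c in counters.values()]) or set())
    data = {
        f"round_{r}": [counters[r].get(v, 0) for v in variants] for r in rounds
    }
    table = pd.DataFrame(data, index=pd.Index(variants, name="variant"))
    return table


def fold_enrichment(
    table: pd.DataFrame,
    pseudocount: float = 0.5,
    first_round: int | None = None,
    final_round: int | None = None,
) -> pd.DataFrame:
    """Per-variant frequency trajectories and final/first fold change.

    Abundance per round is count over round total. The fold change divides
    the final-round frequency by ``max(freq_first, pseudocount / total_first)``
    so that variants unseen in the input library get a finite, conservative
    fold (default pseudocount 0.5 reads). Returns a DataFrame with one
    ``freq_r`` column per round plus ``fold_change``.
    """
    round_cols = [c for c in table.columns if c.startswith("round_")]
    if len(round_cols) < 2:
        raise ValueError("need at least two rounds")
    numbers = sorted(int(c.split("_")[1]) for c in round_cols)
    r_first = first_round if first_round is not None else numbers[0]
    r_final = final_round if final_round is not None else numbers[-1]

    out = pd.DataFrame(index=table.index)
    totals = {}
    for r in numbers:
        col = f"round_{r}"
        totals[r] = table[col].sum()
        out[f"freq_{r}"] = table[col] / totals[r] if totals[r] > 0 else 0.0
    floor = pseudocount / totals[r_first] if totals[r_first] > 0 else np.nan
    denom = out[f"freq_{r_first}"].clip(lower=floor)
    out["fold_change"] = out[f"freq_{r_final}"] / denom
    return out


def select_hits(records: pd.DataFrame, threshold: float = 1000.0) -> list[str]:
    """Variants enriched strictly more than ``threshold``-fold.

    The comparison is strict ("more than"): a variant at exactly the
    threshold is not a hit. Hits come back ordered by descending fold
    change, ties by variant name.
    """
    if records.empty:
        return []
    hits = records[records["fold_change"] > threshold]
    hits = hits.sort_values(
        ["fold_change"], ascending=False, kind="mergesort"
    )
    return list(hits.index)


@dataclass(frozen=True)
class VariantCall:
    """Protein-level interpretation of one variant ORF."""

    substitutions: tuple[tuple[str, int, str], ...]  # (refAA, position, altAA)
    frameshift: bool
    synonymous_only: bool

    def __str__(self) -> str:
        if self.frameshift:
            return "frameshift"
        if not self.substitutions:
            return "WT(syn)" if self.synonymous_only else "WT"
        return ",".join(f"{r}{p}{a}" for r, p, a in self.substitutions)


def call_substitutions(variant_dna: str, reference_orf: str) -> VariantCall:
    """Codon-wise protein substitution calling against a reference ORF.

    A length difference not divisible by three flags a frameshift (no
    substitutions are then called). Equal-length sequences are compared
    codon by codon and substitutions reported as refAA+position+altAA;
    in-frame length differences yield no per-position calls either, since
    codon registration downstream of the indel is ambiguous without
    alignment.
    """
    ref = reference_orf.upper()
    var = variant_dna.upper()
    if len(ref) % 3 != 0:
        raise ValueError("reference ORF length must be divisible by 3")
    ref_codons = [ref[i : i + 3] for i in range(0, len(ref), 3)]
    ref_aas, ref_stops = [], 0
    from Bio.Data.CodonTable import standard_dna_table

    for i, codon in enumerate(ref_codons):
        if codon in standard_dna_table.stop_codons:
            if i != len(ref_codons) - 1:
                raise ValueError(f"internal stop codon in reference at codon {i + 1}")
            ref_aas.append("*")
        else:
            ref_aas.append(standard_dna_table.forward_table[codon])

    if len(var) != len(ref):
        return VariantCall(
            substitutions=(),
            frameshift=(len(var) - len(ref)) % 3 != 0,
            synonymous_only=False,
        )

    subs = []
    any_dna_diff = var != ref
    for i in range(len(ref_codons)):
        vc = var[3 * i : 3 * i + 3]
        if vc == ref_codons[i]:
            continue
        if vc in standard_dna_table.stop_codons:
            alt = "*"
        else:
            alt = standard_dna_table.forward_table[vc]
        if alt != ref_aas[i]:
            subs.append((ref_aas[i], i + 1, alt))
    return VariantCall(
        substitutions=tuple(subs),
        frameshift=False,
        synonymous_only=any_dna_diff and not subs,
    )


@dataclass(frozen=True)
class SiteSpec:
    """One mutated protein site: position, wild type, allowed residues."""

    position: int
    wild_type: str
    allowed: tuple[str, ...]

    def __post_init__(self) -> None:
        residues = tuple(r.upper() for r in self.allowed)
        if any(len(r) != 1 or r not in "ACDEFGHIKLMNPQRSTVWY" for r in residues):
            raise ValueError(f"non-standard residues in {self.allowed}")
        object.__setattr__(self, "allowed", residues)
        if len(self.wild_type) != 1:
            raise ValueError("wild_type must be a single residue")


def enumerate_combinatorial_library(
    sites: Sequence[SiteSpec],
    include_wt: bool = True,
    naming: str = "letters",
) -> pd.DataFrame:
    """Cartesian combinatorial mutant library over per-site residue sets.

    With ``include_wt`` each site's wild-type residue is added to its
    allowed set if missing, so the all-wild-type combination is a member.
    ``naming='letters'`` names each variant by the chosen residue letters
    in site order ("RQVK" style). Returns a DataFrame with one column per
    site position plus ``name``; the size equals the product of per-site
    set sizes.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    positions = [s.position for s in sites]
    if len(positions) != len(set(positions)):
        raise ValueError("duplicate site positions")
    pools = []
    for s in sites:
        residues = list(s.allowed)
        if include_wt and s.wild_type not in residues:
            residues.insert(0, s.wild_type)
        # keep stated order but drop accidental duplicates
        seen: list[str] = []
        for r in residues:
            if r not in seen:
                seen.append(r)
        pools.append(seen)
    rows = []
    for combo in itertools.product(*pools):
        if naming == "letters":
            name = "".join(combo)
        else:
            name = "-".join(
                f"{s.wild_type}{s.position}{r}" for s, r in zip(sites, combo)
            )
        rows.append((name, *combo))
    return pd.DataFrame(rows, columns=["name", *[f"pos_{p}" for p in positions]])


def collapse_to_protein(
    table: pd.DataFrame, reference_orf: str
) -> pd.DataFrame:
    """Collapse a nucleotide-keyed round-count table to protein level.

    Synonymous nucleotide variants merge under their protein call string;
    frameshifted sequences group under ``"frameshift"``.
    """
    keys = [str(call_substitutions(v, reference_orf)) for v in table.index]
    out = table.copy()
    out.index = pd.Index(keys, name="variant")
    return out.groupby(level=0).sum().sort_index()
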