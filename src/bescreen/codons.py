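"""Balanced degenerate-codon design for site-saturation mutagenesis.

A degenerate codon is written with IUPAC ambiguity symbols (V = A/C/G,
S = C/G, ...) and denotes the mixture of all concrete codons matching the
pattern. Conventional saturation schemes such as NNK or NNS encode the 20
amino acids with unequal multiplicities (leucine, arginine and serine get
three codons each under NNK) and carry a stop codon. A *balanced* scheme
instead combines several tailored degenerate codons so that every target
amino acid is encoded by exactly one concrete codon, and the primers are
mixed in proportion to each codon's expansion size.

The reference five-codon scheme VAS / DGG / TNC / VYC / ATG covers the 20
standard amino acids exactly once each (HQNKDE / WRG / FSYC / LPITVA / M)
and is mixed 6:3:4:6:1. :func:`design_balanced_scheme` generalises the
construction as an exact-cover search over the 3375 degenerate codons.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "STANDARD_AA",
    "DegenerateCodon",
    "CodonScheme",
    "SchemeReport",
    "expand",
    "translate_set",
    "verify_scheme",
    "mixing_ratio",
    "design_balanced_scheme",
    "build_primer_set",
    "PAPER_SCHEME",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# the 15 IUPAC nucleotide symbols (Biopython's table adds a non-IUPAC "X")
_IUPAC_NT: dict[str, str] = {
    k: v for k, v in ambiguous_dna_values.items() if k != "X"
}

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class DegenerateCodon:
    """Three IUPAC nucleotide symbols and their concrete expansion."""

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols.upper()
        if len(s) != 3 or any(c not in _IUPAC_NT for c in s):
            raise ValueError(f"invalid IUPAC codon {self.symbols!r}")
        object.__setattr__(self, "symbols", s)

    @property
    def expansion(self) -> frozenset[str]:
        return expand(self)

    @property
    def size(self) -> int:
        """Product of per-symbol degeneracies."""
        return len(self.expansion)

    def __str__(self) -> str:
        return self.symbols


def expand(codon: DegenerateCodon | str) -> frozenset[str]:
    """Cartesian IUPAC expansion of a degenerate codon."""
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    pools = [_IUPAC_NT[c] for c in codon.symbols]
    return frozenset("".join(p) for p in itertools.product(*pools))


def translate_set(codons: Iterable[str]) -> tuple[Counter, int]:
    """Translate concrete codons under the standard genetic code.

    Returns ``(amino-acid multiset, stop-codon count)``.
    """
    aas: Counter = Counter()
    stops = 0
    for codon in codons:
        codon = codon.upper()
        if codon in _STOP_CODONS:
            stops += 1
        else:
            aas[_CODON_TABLE[codon]] += 1
    return aas, stops


@dataclass(frozen=True)
class CodonScheme:
    """An ordered set of degenerate codons used together at one site."""

    codons: tuple[DegenerateCodon, ...]

    def __post_init__(self) -> None:
        if not self.codons:
            raise ValueError("scheme must contain at least one codon")
        coerced = tuple(
            c if isinstance(c, DegenerateCodon) else DegenerateCodon(c)
            for c in self.codons
        )
        object.__setattr__(self, "codons", coerced)

    @classmethod
    def from_strings(cls, symbols: Iterable[str]) -> "CodonScheme":
        return cls(tuple(DegenerateCodon(s) for s in symbols))

    @property
    def amino_acids(self) -> Counter:
        aas, _ = translate_set(self.all_concrete_codons())
        return aas

    def all_concrete_codons(self) -> list[str]:
        out: list[str] = []
        for codon in self.codons:
            out.extend(sorted(codon.expansion))
        return out

    def __str__(self) -> str:
        return "/".join(str(c) for c in self.codons)


#: The published five-codon scheme covering all 20 amino acids 1:1.
PAPER_SCHEME = CodonScheme.from_strings(["VAS", "DGG", "TNC", "VYC", "ATG"])


@dataclass(frozen=True)
class SchemeReport:
    """Audit of a scheme: multiplicities, balance, stops, overlaps, rarity."""

    multiplicity: Mapping[str, int]
    total_codons: int
    stop_count: int
    balanced: bool
    overlapping_codons: frozenset[str]
    rare_codons: frozenset[str]

    @property
    def n_amino_acids(self) -> int:
        return len(self.multiplicity)


def verify_scheme(
    scheme: CodonScheme,
    rare_codon_table: Mapping[str, float] | None = None,
    rare_threshold: float = 0.1,
) -> SchemeReport:
    """Audit a scheme for balance (every amino acid exactly once) and stops.

    A scheme is *balanced* when every encoded amino acid has multiplicity
    exactly one, no expansion contains a stop codon, and no concrete codon
    arises from two degenerate codons. With an optional per-codon usage
    table, codons below ``rare_threshold`` relative usage are flagged
    (rarity down-ranks a scheme; it never voids it).
    """
    concrete = scheme.all_concrete_codons()
    dupes = frozenset(c for c, n in Counter(concrete).items() if n > 1)
    aas, stops = translate_set(concrete)
    balanced = (
        stops == 0
        and not dupes
        and all(n == 1 for n in aas.values())
    )
    rare: frozenset[str] = frozenset()
    if rare_codon_table is not None:
        rare = frozenset(
            c for c in set(concrete)
            if rare_codon_table.get(c, 0.0) < rare_threshold
        )
    return SchemeReport(
        multiplicity=dict(sorted(aas.items())),
        total_codons=len(concrete),
        stop_count=stops,
        balanced=balanced,
        overlapping_codons=dupes,
        rare_codons=rare,
    )


def mixing_ratio(scheme: CodonScheme) -> list[int]:
    """Per-codon expansion sizes, reported raw (no common-factor reduction).

    For a balanced scheme these are the molar primer-mixing proportions
    that give every amino acid equal representation.
    """
    return [c.size for c in scheme.codons]


def _candidate_codons(
    target: frozenset[str], forbidden: frozenset[str]
) -> list[tuple[DegenerateCodon, frozenset[str]]]:
    """Degenerate codons whose expansion encodes a stop-free, duplicate-free
    subset of ``target`` and avoids forbidden concrete codons."""
    symbols = sorted(_IUPAC_NT)
    out = []
    for combo in itertools.product(symbols, repeat=3):
        codon = DegenerateCodon("".join(combo))
        concrete = codon.expansion
        if concrete & forbidden:
            continue
        aas, stops = translate_set(concrete)
        if stops:
            continue
        if any(n > 1 for n in aas.values()):
            continue
        covered = frozenset(aas)
        if covered <= target:
            out.append((codon, covered))
    # canonical order: larger coverage first, then lexicographic symbols
    out.sort(key=lambda t: (-len(t[1]), t[0].symbols))
    return out


def design_balanced_scheme(
    target_aas: Iterable[str],
    max_codons: int = 5,
    forbidden: Iterable[str] = (),
    max_solutions: int = 100,
    rare_codon_table: Mapping[str, float] | None = None,
    rare_threshold: float = 0.1,
) -> list[CodonScheme]:
    """Exact-cover search for balanced schemes over a target amino-acid set.

    Every returned scheme encodes each target amino acid exactly once with
    no stop codons, using at most ``max_codons`` degenerate codons. The
    search is a depth-first exact cover over all 3375 IUPAC codons whose
    expansions translate to stop-free sub-multisets of the target, with
    deterministic canonical ordering, so results are independent of the
    order the targets are given in. Schemes containing codons deemed rare
    under an optional usage table are down-ranked to the end of the list,
    never excluded. Infeasible constraints yield an empty list.
    """
    target = frozenset(a.upper() for a in target_aas)
    if not target:
        raise ValueError("target amino-acid set must be non-empty")
    if not target <= STANDARD_AA:
        raise ValueError(f"non-standard amino acids: {sorted(target - STANDARD_AA)}")
    forbidden = frozenset(c.upper() for c in forbidden)

    candidates = _candidate_codons(target, forbidden)

    # bitmask encoding of amino-acid subsets; candidates sharing a coverage
    # set are grouped so the exact cover runs over distinct masks only
    aa_order = sorted(target)
    aa_bit = {a: 1 << i for i, a in enumerate(aa_order)}
    groups: dict[int, list[DegenerateCodon]] = {}
    for codon, covered in candidates:
        mask = 0
        for a in covered:
            mask |= aa_bit[a]
        groups.setdefault(mask, []).append(codon)
    masks = sorted(
        groups, key=lambda m: (-bin(m).count("1"), groups[m][0].symbols)
    )
    for mask in masks:
        groups[mask].sort(key=lambda c: c.symbols)
    by_bit: dict[int, list[int]] = {aa_bit[a]: [] for a in aa_order}
    for idx, mask in enumerate(masks):
        for a in aa_order:
            if mask & aa_bit[a]:
                by_bit[aa_bit[a]].append(idx)

    full = (1 << len(aa_order)) - 1
    partitions: list[tuple[int, ...]] = []

    def dfs(uncovered: int, chosen: tuple[int, ...]) -> None:
        if uncovered == 0:
            partitions.append(chosen)
            return
        if len(chosen) >= max_codons:
            return
        # branch on the uncovered amino acid with fewest usable masks
        pivot_bit, pivot_opts = None, None
        for a in aa_order:
            bit = aa_bit[a]
            if not uncovered & bit:
                continue
            opts = [i for i in by_bit[bit] if masks[i] & ~uncovered == 0]
            if pivot_opts is None or len(opts) < len(pivot_opts):
                pivot_bit, pivot_opts = bit, opts
                if not opts:
                    return
        assert pivot_opts is not None
        for idx in pivot_opts:
            dfs(uncovered & ~masks[idx], chosen + (idx,))

    dfs(full, ())

    # expand mask partitions into concrete codon combinations, capped
    unique: list[CodonScheme] = []
    for partition in partitions:
        pools = [groups[masks[i]] for i in sorted(partition)]
        for combo in itertools.product(*pools):
            ordered = sorted(combo, key=lambda c: (-c.size, c.symbols))
            unique.append(CodonScheme(tuple(ordered)))
            if len(unique) >= max_solutions:
                break
        if len(unique) >= max_solutions:
            break

    if rare_codon_table is not None:
        unique.sort(
            key=lambda s: len(
                verify_scheme(s, rare_codon_table, rare_threshold).rare_codons
            )
        )
    return unique


def build_primer_set(
    scheme: CodonScheme, flank5: str, flank3: str
) -> list[dict]:
    """One degenerate primer per codon, with molar mixture fractions.

    Fractions are expansion size over total concrete codons, so a balanced
    scheme delivers every amino acid at equal molarity. Primer sequences
    carry the IUPAC codon between the two flanks.
    """
    if not flank5 or not flank3:
        raise ValueError("primer flanks must be non-empty")
    total = sum(mixing_ratio(scheme))
    records = []
    for i, codon in enumerate(scheme.codons, start=1):
        records.append(
            {
                "name": f"primer_{i}_{codon}",
                "sequence": flank5.upper() + codon.symbols + flank3.upper(),
                "codon": codon.symbols,
                "fraction": codon.size / total,
            }
        )
    return records
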