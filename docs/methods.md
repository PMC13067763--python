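# Methods

## Composite scoring (BEPI)

The package scores a base-editor outcome pair (C→T %, indel %) with
`(c_to_t − indel) / exp(indel / 10)`. The exponential term penalises high
indel burdens; the linear numerator term separates 0 % from low indel
levels, which the precursor form `c_to_t / exp(indel / 10)` does weakly
(its 0 %-vs-1 %-indel discrimination at 50 % conversion is 4.76 score
units against 5.66 for the selected form — both reproduced by
`criteria_check`). Scores are computed at full precision and rounded to
two decimals only for display. Negative scores (indel exceeding
conversion) are returned as-is; clamping would hide a pathological
editor.

The screening grid uses seven C→T levels spanning 2.5–100 % and eight
indel levels spanning 0–10 %. Only the counts and endpoints are fixed by
the screening design; the interior defaults {2.5, 5, 10, 25, 50, 75, 100}
and {0, 0.5, 1, 2.5, 5, 7.5, 9, 10} are configurable. Fifteen formula
slots exist in the registry, organised into four families (arithmetic,
rational, logarithmic, exponential-decay); only formulations 11 and 14
have published algebra, so the other thirteen are deliberate placeholders
that users can fill — the package does not invent their forms.
`rank_variants` breaks score ties lexicographically by variant name so
rankings are reproducible.

## Amplicon quantification

References are assembled as `barcode + GA + protospacer(20) + PAM(3) +
fixed suffix(30)`. Protospacer positions are expressed PAM-relatively:
the PAM-proximal base is position 1, increasing toward 5′, i.e. 5′ index
i maps to 21 − i. This is the only convention under which the three
repeat-target selection spacers carry their editable cytosines at
positions 13, {12, 15} and 12 inside a 12–17 window, so it is adopted
package-wide; the analysis window itself is explicit configuration
(default 11–19) rather than a guessed analyzer internal.

Reads are aligned globally (affine gaps: match +2, mismatch −3, open −5,
extend −1; end gaps free) with Biopython's `PairwiseAligner`; the first
optimal alignment is taken, making results deterministic under the fixed
scoring. Identity is matches over full read length, so a read matching
only a short reference segment cannot pass the 60 % acceptance threshold;
sub-threshold reads are flagged unaligned and excluded from every
denominator.

Indel frequency is the fraction of aligned reads with an insertion or
deletion overlapping the protospacer∪PAM interval (half-open
intersection for deletions; an insertion counts when its junction falls
strictly inside the interval — a junction flush with a boundary leaves
the region's bases intact). Reads carrying such indels contribute only to
the indel class and are excluded from substitution numerators and
denominators entirely, so each read lands in exactly one outcome class
(unaligned / indel / substitution-only / unedited). Window aggregates
follow three event classes: C→T at window cytosines, C→T at any
amplicon cytosine outside the window, and all other substitutions at
window positions; C→D counts conversion to any of A/G/T and therefore
bounds C→T from above.

The empirical editing window is the maximal contiguous run of positions
whose C→T rate reaches a threshold fraction (default 0.3) of the maximal
positional rate, ties resolved toward the PAM-proximal run; an all-zero
profile is an error rather than a degenerate window.

## Balanced codon design

Degenerate codons are expanded by Cartesian product over the 15 IUPAC
nucleotide symbols and translated under the standard genetic code. A
scheme is balanced when every encoded amino acid has multiplicity exactly
one, no expansion contains a stop codon, and no concrete codon arises
twice. Mixing ratios are raw expansion sizes (molar mixing is assumed),
so a balanced scheme delivers every amino acid at equal molarity.

`design_balanced_scheme` is an exact-cover search: candidate codons are
those of the 3375 whose stop-free expansions translate to duplicate-free
subsets of the target set; candidates sharing a coverage set are grouped,
the cover runs over distinct coverage bitmasks (branching on the
uncovered amino acid with fewest options), and mask partitions are then
expanded into concrete codon combinations, capped at `max_solutions`
(default 100). Ordering is canonical (coverage size descending, then
lexicographic), so output is deterministic and invariant under target-set
permutation; full enumeration for the 20-amino-acid target (14 448
five-codon schemes, containing the reference VAS/DGG/TNC/VYC/ATG scheme)
runs in about a second. Rare-codon handling is advisory: with an optional
per-organism usage table, schemes containing codons below a configurable
frequency (default 0.1) are down-ranked, never excluded, since no
specific usage table is canonical. Stop codons always disqualify a
scheme.

## Selection enrichment

Read pairs are merged by ungapped overlap: read 2 is
reverse-complemented, all overlaps of at least 15 nt are scored, and the
candidate with the most matching bases (ties to the longer overlap) is
accepted if its mismatch fraction is ≤ 0.1; within-overlap disagreements
resolve to the higher-quality base, ties to read 1. Amplicons are
fixed-length, so gapped merging is deliberately not attempted; unmerged
pairs are dropped from counting. Counting is exact and sequence-keyed at
the nucleotide level, with optional collapsing to protein level (the
counting question — nucleotide vs protein — needs both views: selections
are sequenced as DNA but hits are reported as protein substitutions).

Fold enrichment divides final-round frequency by
`max(freq_first, pseudocount / total_first)` with a 0.5-read pseudocount,
so variants unseen in the input library get a finite, conservative fold
rather than infinity. Round 1 is the sequenced input library; selection
acts on each subsequent transition, so a variant with relative survival
s has expected fold `s^(R−1)` over R rounds while it remains rare
(enriching variants saturate below this as they take over the pool). The
hit threshold (default 1000-fold) is strict — exactly 1000 is not a hit —
reading "more than" literally.

Substitution calling compares equal-length variant ORFs codon-wise and
reports refAA+position+altAA; a length difference not divisible by three
flags a frameshift. In-frame length differences produce no per-position
calls, since codon registration downstream of an indel is ambiguous
without alignment — a deliberate limitation.

## Structure geometry

Inter-residue distances default to side-chain reference atoms (NZ for
lysine, OH for tyrosine, CB otherwise, CA for glycine), with a CA mode
provided; the published entrance distances plausibly reflect side-chain
geometry but the measuring atoms are not stated, so the rule is explicit
and configurable. Structures are read from PDB/mmCIF via gemmi (first
model, altloc A). Pocket surface areas are consumed from tables only —
pocket computation is out of scope — averaged per scanned position over
replicate predicted structures (the scanning design uses five), and
ranked by descending mean with ties toward the lower residue number; the
top rank is the key site. Trilateration solves the three sphere
equations in the anchor-plane frame, returning both mirror solutions in
the generic case, one when the point lies in the plane (within 1e−6 Å),
and none with a residual report when the distances are inconsistent;
collinear anchors are an error.

## Synthetic data

The read simulator emulates the data the quantifier consumes: per-read,
position-specific C→T and C→(A/G) conversion at protospacer cytosines;
with a configurable probability, one indel per read (deletion or
insertion with equal odds, geometric length with p = 0.5, start uniform
over protospacer∪PAM, insertion junctions drawn strictly interior so
every simulated indel disrupts the region under the overlap rule); and
uniform per-base sequencing error. Reads are emitted as end-pairs of the
edited molecule plus a ground-truth ledger, and identical spec + seed
gives byte-identical output. It does not model instrument-specific
quality profiles, PCR duplicates or strand biases, so passing parameter
recovery shows the estimator is consistent under the stated event model,
not that it is robust to every real-data artefact.

The selection simulator models per-variant survival as the product of the
three selection axes — activity (start-codon rescue probability) ×
exp(−dsb_hazard × repeat copy number) × viability (toxicity survival) —
with copy number in {2, 7, 12} matching the three selection plasmid
designs. Rounds are multinomial bottleneck draws (default 100 000) from
survival-reweighted frequencies. The quantitative form of the survival
model is a modelling choice made for testing the counting and enrichment
stages; the underlying biology specifies the axes, not their algebra.

Problem sizes in the test suite (2000 reads for rate recovery, 400 for
ledger-exact checks, 20 seeds × 50 variants for neutral calibration) were
chosen so binomial standard errors are small relative to the effects
being checked while the whole suite stays fast.

## Known limitations

- Quality scores inform merging only, not base calling in quantification.
- The aligner's first-optimal-alignment convention can place an
  ambiguous indel at any equivalent position within a homopolymer run;
  counts are unaffected unless the run crosses the protospacer∪PAM
  boundary.
- Thirteen of the fifteen registry formula slots are intentionally
  unpopulated (unpublished algebra).
- The enrichment model ignores plasmid co-transformation multiplicity
  and assumes one variant per cell.
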