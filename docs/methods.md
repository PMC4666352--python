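# Methods

## The triplex model

An intrastrand triplex is a single-strand fold with three stems and two
loops: `stemA – loop1 – stemB – loop2 – stemC`, stems 6–15 nt, loops 1–6 nt.
Both fold-backs are antiparallel (the same geometry as a hairpin folded onto
a hairpin), so stemA pairs stemB in reverse and stemC stacks parallel to
stemA: the base triad presented at stack position `k` of an `L`-nt stem is
`(stemA[k], stemB[L−1−k], stemC[k])`. A triad is valid when it belongs to the
class's set (see README table); the four classes are the four 5′→3′ orders of
the Y/R/(R)H tracts along one strand. Stems may mix triads within one class
("mixed stems"), e.g. a C-G·G stem may carry a T-A·A or T-A·T triad. A
mismatch is one stack position whose triad falls outside the class set,
regardless of which stem carries the offending base; one mismatch is allowed
for stems ≥ 7 nt, none for 6-nt stems, because a 7-nt stem is the shortest
for which an imperfect triplex is still plausibly stable.

The scanner enumerates **every** qualifying `(anchor, stem, loop1, loop2)`
tuple per class and strand (`collapse="all"`). This mirrors a plain
write-one-entry-per-match enumeration and makes counts well defined but
multiplicities high: one physical motif typically yields several tuples
(sub-stems, shifted loops). `collapse="leftmost_longest"` reduces every set
of transitively overlapping same-class, same-strand tuples to one
representative (smallest start, then largest stem, then smallest loop1, then
smallest loop2) and is the right mode for genome summaries. For circular
records the overlap relation is computed modulo the genome length; without
this, a cluster spanning the origin would split differently depending on
where the coordinate origin happens to sit, and collapsed counts would not
be rotation invariant.

Circular replicons are scanned by appending the first
`3·max_stem + 2·max_loop` characters (the longest possible motif, 57 nt at
defaults) to the end of the sequence; a hit is reported iff its
forward-strand start lies inside the original coordinates, so every
origin-spanning motif is counted exactly once. Records shorter than the pad
are scanned as linear with a warning. The reverse strand is searched by
scanning the reverse complement and mapping intervals back.

`N` (any ambiguity code, mapped at load time) never participates in a valid
triad or basepair but may sit in loops. `U` is rejected: purine-motif
triplexes cannot form in RNA and the tool is DNA-only. These two rules are
our conventions; the triad rules themselves are defined only on A/C/G/T.

### Strand duality

Complementation maps triads pairwise between classes: C-G·G ↔ C·C-G and
T-A·A ↔ T·T-A (class II ↔ IV), A·A-T ↔ A-T·T and G·G-C ↔ G-C·C
(class I ↔ III). Hence every mismatch-free class I/II hit whose triads avoid
T·A-T has an exact class III/IV mirror on the opposite strand over the same
interval with loops swapped — T·A-T complements to A·T-A, which belongs to no
class, so T·A-T-containing hits are exempt. The test suite asserts this
property wholesale on G/C-rich fixtures.

## Hairpins

The comparison structure is an inverted repeat able to fold into a
stem-loop: arms of 9–15 nt around a 1–6 nt loop with at most one
non-complementary arm position. Hairpins are strand-symmetric, so only the
forward strand is scanned.

## TM_ECO

The consensus `CCCTCNCCC N(3–6) GGGNGAGGG N(3) GGGNGAGGG [GTC-]` is matched
with a regular expression; the loop1 quantifier is lazy, which implements the
shortest-loop1-per-anchor rule and makes the decomposition unique (each
G-rich stem starts with `GGG`, so a longer loop1 can never re-anchor a stem
inside itself for the fixtures and genomes we generate). Matching is
non-overlapping and greedy left-to-right per strand — our convention; genuine
overlapping consensus matches are not expected in real genomes.

Typing follows the last base of the second loop: A → type A (the loop
presents a T·T-A-like context), G → type B (C·C-G), anything else
"unassigned". The annotated reference set contains loop2 variants `CTG` and
`TCG` that are conventionally typed B, so the final base is the only rule
consistent with all 23 annotated motifs.

Two mismatch counts are reported per hit:

- `mismatches` — stack positions whose triad falls outside the class II set.
  This is the physical count used everywhere a triplex mismatch is meant
  (including the type-A-with-mismatch acceptance number).
- `stem_a_mismatches` — stemA letters outside the class II pyrimidine
  alphabet {C,T}. This drives the conventional "type [mm]" label: it
  reproduces the packaged reference annotation on all 23 motifs, whereas the
  triad count disagrees on exactly one (motif 8, whose G-rich stemB carries a
  T at its free position, giving triad T·T-A — a class IV triad — at one
  stack position; its conventional annotation is plain "B"). Both counts
  agree on every other motif, and on every motif whose deviation sits in the
  C-rich stem.

Inverted-repeat pairs are called greedily left-to-right: two neighbouring
opposite-strand motifs whose gap is at most 200 nt pair up, each motif used
once. The 200-nt default separates the five annotated pairs (gaps 16–59 nt)
cleanly from all other inter-motif distances in the reference set; the value
is our choice, as no threshold is standard.

## Scrambled controls

The null model for motif enrichment is a uniform random permutation of the
genome's characters (Fisher–Yates), preserving length and mononucleotide
composition exactly. One seed produces one control genome scanned with
identical parameters; the CLI supports replicate seeds with mean ± sd.
Long-stem (≥ 9 nt) motifs are overwhelmingly unlikely to re-form by chance
after shuffling, which the sign-test property check exploits.

Summary binning: stem G+C is computed over the 3L stem positions only (loops
are arbitrary spacers); "GC50" means strictly greater than 50% — exactly half
G+C bins as AT50. Genome G+C excludes N positions from the denominator.

## Variability statistic

`n_i` counts the distinct symbols among {A, C, G, T, gap} in alignment column
i — a gap is one state, `N` is no state (an all-N column counts 1). This is
the only reading under which fully conserved columns score `n_i − 1 = 0` and
the statistic stays in [0, 4]. `v_j` is the centered window-11 mean of
`n_i − 1`; columns without a full window carry NaN and can neither open nor
close a region (the edges are simply undefined, not zero).

Region calling is a two-threshold state machine: open at the first column of
the first run of ≥ 10 consecutive `v_j > 0.9`; close at the column preceding
the first subsequent run of ≥ 10 consecutive `v_j < 0.5` (the closing run is
outside the region; columns between 0.5 and 0.9 inside a region stay in);
without a closing run the region extends to the last defined column.

## Locus categorization

The query is a motif with 500 nt of flank on each side; homology hits arrive
as 12-column tabular rows (1-based inclusive query coordinates, converted to
0-based half-open). The thresholds are our choices, made so the four
categories are mutually exclusive and testable (the source procedure names
none): a query interval is *covered* when inside a segment with ≥ 90%
identity; coverage gaps shorter than 10 nt are ignored; a *change* is a
≥ 10 nt gap or a covered span at < 99% identity.

- no segment at all → `no_homology`;
- any gap > 300 nt → `region_missing`;
- changes present and all inside the annotated intergenic interval →
  `intergenic_change`;
- otherwise → `no_change`.

Subcategories (for region_missing / intergenic_change): `tm_missing` when
the motif interval is entirely uncovered, `tm_mutated` when covered but not
at 100% identity throughout. `palindrome_effect` replaces either when the
caller sets `hairpin_check`, asserting that a hairpin-capable remnant of a
palindromic motif pair survives in the subject — the flag is an approximation
of a qualitative observation and is off by default. Without an intergenic
annotation (BED), `intergenic_change` cannot be assigned; such loci fall back
to the region_missing / no_change logic with a warning.

## Synthetic data

`gen_genome` draws i.i.d. (order-0) background — the same null the scramble
control embodies — with motifs overwritten at fixed positions
(reverse-complemented for minus-strand implants; implants may not overlap).
`gen_tmeco_sequence` constructs consensus-matching motifs with an exact
requested type and triad-mismatch count by controlling the three free stem
positions (loop1 avoids G so the decomposition stays unique).
`gen_alignment` builds alignments with exact per-column state counts:
identical rows outside the declared blocks, exactly `states_per_column`
distinct symbols per column inside. All generators are pure functions of
their arguments including the seed.

What the generators do **not** emulate: real genomes have repeat families,
skewed dinucleotide statistics and mobile elements; real alignments have
indel blocks, phylogenetic correlation between rows and alignment error.
Passing tests therefore demonstrate the correctness of the algorithms and
the internal consistency of the statistics under the stated null — not
field performance on arbitrary genomes.

## Problem sizes and numerical choices

The brute-force oracle comparisons run 50 seeded sequences of 120–260 nt
(mixed compositions plus implanted motifs of every class); the duality,
rotation (20 rotations of a 600-nt circular genome), variability-contrast
(50 replicates of 8 × 1200-column alignments) and scramble sign-test
(20 seeds, 6 implanted long-stem motifs each) checks use similarly small,
fully generated inputs. Genome-scale scans are supported through the same
API/CLI but are not part of the test suite. The scanner is exact — no
heuristics, no floating-point thresholds beyond the G+C fractions — so
problem size affects runtime only, not results. Ties in collapse
representatives are broken deterministically; all outputs are sorted by
(start, end, class, strand, loops) so repeated runs are byte-identical.

## Known limitations

- No thermodynamic scoring: a reported motif is a sequence-pattern match,
  not a stability prediction; H-DNA (duplex-context) triplexes and
  triplex-forming-oligo target sites are out of scope.
- Enumeration multiplicity is a convention (`all` vs `leftmost_longest`);
  absolute genome-wide counts depend on the mode chosen.
- The conventional "mm" label and the triad-mismatch count can disagree when
  a motif's deviation sits in a G-rich stem (see TM_ECO section).
- Whole-genome alignment and homology search themselves are consumed, not
  computed: alignments come in as gapped FASTA, homology as tabular hits.
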