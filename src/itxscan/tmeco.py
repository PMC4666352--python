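"""TM_ECO consensus motif search, classification and inverted-repeat pairing.

TM_ECO is the G/C-rich class II intrastrand triplex motif found repeatedly
in *E. coli* and related enterobacteria:

    5'-CCCTCNCCC N(3-6) GGGNGAGGG N(3) GGGNGAGGG [GTC-]-3'

i.e. a C-rich 9-nt stem, a 3-6 nt loop, a G-rich 9-nt stem, a 3-nt loop, a
second G-rich 9-nt stem and an optional single-base tail. Motifs are typed
by the last base of the second loop: A -> type A (T*T-A triad presented to
the stack), G -> type B (C*C-G); anything else is left unassigned.

Two mismatch counts are carried per hit. ``mismatches`` counts stack
positions whose (stemA, stemB, stemC) triad falls outside the class II set
{C-G*G, T-A*A, T-A*T} - the physical notion of a mismatched base triple.
``stem_a_mismatches`` counts stemA letters outside the class II pyrimidine
alphabet {C,T}; this is the count that reproduces the conventional
"type A/B [mm]" annotation of the *E. coli* K-12 MG1655 reference motifs
(one motif there carries a deviant base in a G-rich stem and is
conventionally annotated without "mm" although its triad count is 1; see
docs/methods.md).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import GenomeRecord, reverse_complement
from .triplex_core import TRIPLET_TABLE

__all__ = [
    "CONSENSUS_PATTERN",
    "TmecoParts",
    "TmecoHit",
    "TmecoPair",
    "TmecoParseError",
    "parse_tmeco",
    "classify_tmeco",
    "find_tmeco",
    "find_inverted_pairs",
    "write_tmeco_tsv",
]

# lazy loop1 quantifier implements the shortest-loop1-per-anchor rule
CONSENSUS_PATTERN = re.compile(
    r"(CCCTC[ACGT]CCC)([ACGT]{3,6}?)(GGG[ACGT]GAGGG)([ACGT]{3})(GGG[ACGT]GAGGG)([GTC]?)"
)

_CLASS_II = TRIPLET_TABLE["II"]
_CLASS_II_STEM_A = frozenset("CT")


class TmecoParseError(ValueError):
    """Raised when a sequence does not match the TM_ECO consensus."""


@dataclass(frozen=True)
class TmecoParts:
    """Decomposition of one consensus match (parts concatenate to the motif)."""

    stemA: str
    loop1: str
    stemB: str
    loop2: str
    stemC: str
    tail: str = ""

    @property
    def motif(self) -> str:
        return self.stemA + self.loop1 + self.stemB + self.loop2 + self.stemC + self.tail

    def __len__(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class TmecoHit:
    """One TM_ECO consensus match with forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand regardless
    of ``strand``; ``parts`` is the motif-strand decomposition.
    """

    record_id: str
    start: int
    end: int
    strand: str
    parts: TmecoParts
    tm_type: str
    mismatches: int
    stem_a_mismatches: int

    @property
    def loop2(self) -> str:
        return self.parts.loop2

    @property
    def type_label(self) -> str:
        """Conventional annotation: type letter plus " mm" for a deviant stemA."""
        return self.tm_type + (" mm" if self.stem_a_mismatches >= 1 else "")

    def genome_minutes(self, genome_length: int) -> float:
        """Cosmetic map position in 'minutes' (100-minute circular map)."""
        return round(self.start / genome_length * 100 * 2) / 2


@dataclass(frozen=True)
class TmecoPair:
    """Two closely spaced TM_ECO motifs in inverted-repeat configuration."""

    plus_hit: TmecoHit
    minus_hit: TmecoHit
    gap: int


def parse_tmeco(seq: str) -> TmecoParts:
    """Decompose a motif-strand sequence against the TM_ECO consensus.

    The shortest loop1 is taken on ties, which makes the decomposition
    unique. Raises :class:`TmecoParseError` for non-matching input.
    """
    m = CONSENSUS_PATTERN.fullmatch(seq.upper())
    if m is None:
        raise TmecoParseError(f"sequence does not match the TM_ECO consensus: {seq!r}")
    return TmecoParts(*m.groups())


def classify_tmeco(parts: TmecoParts) -> tuple[str, int]:
    """Type a parsed motif and count its mismatched base triads.

    Type is decided by the last base of the second loop (A -> "A",
    G -> "B", otherwise "unassigned"). Mismatches are stack positions k in
    0..8 whose triad (stemA[k], stemB[8-k], stemC[k]) is outside the class II
    set.
    """
    last = parts.loop2[-1]
    tm_type = {"A": "A", "G": "B"}.get(last, "unassigned")
    mism = sum(
        (parts.stemA[k], parts.stemB[8 - k], parts.stemC[k]) not in _CLASS_II
        for k in range(9)
    )
    return tm_type, mism


def stem_a_mismatches(parts: TmecoParts) -> int:
    """Count stemA letters outside the class II pyrimidine alphabet {C,T}."""
    return sum(b not in _CLASS_II_STEM_A for b in parts.stemA)


def _hits_in_frame(frame: str, record_id: str, strand: str, n: int) -> list[TmecoHit]:
    hits = []
    for m in CONSENSUS_PATTERN.finditer(frame):
        parts = TmecoParts(*m.groups())
        tm_type, mism = classify_tmeco(parts)
        s, e = m.start(), m.end()
        if strand == "-":
            s, e = n - m.end(), n - m.start()
        hits.append(
            TmecoHit(
                record_id=record_id,
                start=s,
                end=e,
                strand=strand,
                parts=parts,
                tm_type=tm_type,
                mismatches=mism,
                stem_a_mismatches=stem_a_mismatches(parts),
            )
        )
    return hits


def find_tmeco(record: GenomeRecord) -> list[TmecoHit]:
    """Find all non-overlapping TM_ECO consensus matches on both strands.

    Matching is greedy left-to-right per strand (non-overlapping within a
    strand); per stemA anchor the shortest loop1 is taken. Minus-strand
    matches are reported with forward-strand coordinates and strand "-".
    """
    n = len(record.seq)
    hits = _hits_in_frame(record.seq, record.id, "+", n)
    hits += _hits_in_frame(reverse_complement(record.seq), record.id, "-", n)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_inverted_pairs(hits: list[TmecoHit], max_gap: int = 200) -> list[TmecoPair]:
    """Pair adjacent opposite-strand motifs into inverted repeats.

    Greedy left-to-right over hits sorted by start: two neighbouring hits on
    opposite strands whose gap (nt between the inner motif ends) is at most
    ``max_gap`` form a pair; each hit is used at most once.
    """
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    pairs: list[TmecoPair] = []
    i = 0
    while i + 1 < len(ordered):
        a, b = ordered[i], ordered[i + 1]
        gap = b.start - a.end
        if a.strand != b.strand and gap <= max_gap:
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            pairs.append(TmecoPair(plus_hit=plus, minus_hit=minus, gap=gap))
            i += 2
        else:
            i += 1
    return pairs


def write_tmeco_tsv(hits: list[TmecoHit], path, genome_length: int | None = None) -> None:
    """Write hits with reference-table-like columns.

    Coordinates are 1-based inclusive; antisense rows are printed with
    descending coordinates (motif-strand convention).
    """
    with open(path, "w") as fh:
        fh.write("no\tsequence\tlength\ttype\tgenome_localization\tminutes\tstrand\n")
        for i, h in enumerate(hits, start=1):
            if h.strand == "+":
                loc = f"{h.start + 1}-{h.end}"
            else:
                loc = f"{h.end}-{h.start + 1}"
            minutes = (
                f"{h.genome_minutes(genome_length):g}" if genome_length else ""
            )
            fh.write(
                f"{i}\t{h.parts.motif}\t{len(h.parts)}\t{h.type_label}\t{loc}\t"
                f"{minutes}\t{h.strand}\n"
            )
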