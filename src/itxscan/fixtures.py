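"""Seeded synthetic-data generators and the packaged reference motif table.

Every stage of the pipeline is testable without downloads: genomes are drawn
as i.i.d. (order-0) background - the same null the mononucleotide scramble
control embodies - with motifs implanted at known positions; alignments are
built with exact per-column state counts so the v_j statistic has known
values by construction. All generators are pure functions of their
arguments, including the seed.

The 23 TM_ECO motifs annotated in the *E. coli* K-12 MG1655 chromosome ship
as a plain-TSV package resource (sequence, length, conventional type label,
1-based genome coordinates in motif-strand orientation, map minutes,
strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio import GenomeRecord, reverse_complement
from .variability import Alignment

__all__ = [
    "ImplantSpec",
    "Table1Row",
    "gen_genome",
    "gen_tmeco_sequence",
    "gen_alignment",
    "table1_fixtures",
]

_BASES = np.array(list("ACGT"))
_ALN_SYMBOLS = list("ACGT-")


@dataclass(frozen=True)
class ImplantSpec:
    """A motif to overwrite into a synthetic genome at a fixed position."""

    motif: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.position < 0:
            raise ValueError("position must be >= 0")
        bad = set(self.motif) - set("ACGTN")
        if bad:
            raise ValueError(f"motif contains invalid characters {sorted(bad)}")

    @property
    def interval(self) -> tuple[int, int]:
        return self.position, self.position + len(self.motif)


@dataclass(frozen=True)
class Table1Row:
    """One annotated reference motif (coordinates 1-based, printed order)."""

    no: int
    sequence: str
    length: int
    type_label: str
    start: int
    end: int
    minutes: float
    strand: str

    @property
    def forward_interval(self) -> tuple[int, int]:
        """0-based half-open forward-strand interval."""
        lo, hi = min(self.start, self.end), max(self.start, self.end)
        return lo - 1, hi


def gen_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    implants: list[ImplantSpec] | None = None,
    record_id: str = "synthetic",
    circular: bool = False,
) -> GenomeRecord:
    """Draw an i.i.d. background genome and overwrite implants into it.

    Background base probabilities are P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2.
    Minus-strand implants are inserted as their reverse complement. Implants
    must fit and must not overlap one another.
    """
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    implants = list(implants or [])
    intervals = sorted(spec.interval for spec in implants)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"implants overlap: ({s1},{e1}) and ({s2},{e2})")
    for spec in implants:
        if spec.interval[1] > length:
            raise ValueError(f"implant at {spec.position} does not fit in {length} nt")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(_BASES, size=length, p=p))
    for spec in implants:
        motif = spec.motif if spec.strand == "+" else reverse_complement(spec.motif)
        seq[spec.position : spec.position + len(motif)] = list(motif)
    return GenomeRecord(id=record_id, seq="".join(seq), circular=circular)


def gen_tmeco_sequence(tm_type: str, mismatches: int, seed: int = 0) -> str:
    """Generate a consensus-matching TM_ECO motif with a known classification.

    ``tm_type`` fixes the last base of the second loop ("A" -> A, "B" -> G);
    ``mismatches`` (0 or 1) fixes the number of mismatched class II base
    triads exactly. Loop bases are randomized per seed (loop1 avoids G so
    the consensus decomposition stays unique).
    """
    if tm_type not in ("A", "B"):
        raise ValueError("tm_type must be 'A' or 'B'")
    if mismatches not in (0, 1):
        raise ValueError("mismatches must be 0 or 1")
    rng = np.random.default_rng(seed)

    def pick(letters: str) -> str:
        return letters[rng.integers(len(letters))]

    # free consensus positions: stemA[5]=a, stemB[3]=b, stemC[3]=c.
    # stack triad k5 = (a, b, A) is valid only as (T, A, A); triad k3 =
    # (T, A, c) is valid for c in {A, T}; every other triad is fixed C-G*G.
    a, b, c = "T", "A", pick("AT")
    if mismatches == 1:
        if rng.integers(2) == 0:
            c = pick("GC")  # break triad k3
        else:
            a, b = [("G", "A"), ("T", "G"), ("C", "A"), ("T", "T")][rng.integers(4)]
    loop1 = "".join(pick("ACT") for _ in range(int(rng.integers(3, 7))))
    loop2 = pick("ACGT") + pick("ACGT") + ("A" if tm_type == "A" else "G")
    tail = pick("GTC") if rng.integers(2) else ""
    return (
        f"CCCTC{a}CCC" + loop1 + f"GGG{b}GAGGG" + loop2 + f"GGG{c}GAGGG" + tail
    )


def gen_alignment(
    n_rows: int,
    length: int,
    blocks: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
) -> Alignment:
    """Build an alignment with exact per-column state counts.

    Outside the ``(start, end, states_per_column)`` blocks every row is
    identical (one state per column); inside a block every column realizes
    exactly ``states_per_column`` distinct symbols from {A,C,G,T,-}.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    blocks = list(blocks or [])
    states = np.ones(length, dtype=int)
    for start, end, k in blocks:
        if not (0 <= start < end <= length):
            raise ValueError(f"block ({start},{end}) outside alignment of {length}")
        if not (1 <= k <= min(5, n_rows)):
            raise ValueError(
                f"states_per_column={k} impossible with {n_rows} rows"
            )
        states[start:end] = k
    rng = np.random.default_rng(seed)
    cols = np.empty((length, n_rows), dtype="<U1")
    for j in range(length):
        k = states[j]
        symbols = rng.choice(_ALN_SYMBOLS, size=k, replace=False)
        # guarantee each symbol appears at least once
        assignment = np.concatenate(
            [np.arange(k), rng.integers(0, k, size=n_rows - k)]
        )
        rng.shuffle(assignment)
        cols[j] = symbols[assignment]
    rows = tuple("".join(cols[:, i]) for i in range(n_rows))
    ids = tuple(f"strain_{i + 1}" for i in range(n_rows))
    return Alignment(ids=ids, rows=rows)


def table1_fixtures() -> list[Table1Row]:
    """Load the packaged 23-motif *E. coli* K-12 MG1655 reference table."""
    text = (
        resources.files("itxscan").joinpath("data/tm_eco_mg1655.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows = []
    for ln in lines[1:]:
        no, seq, length, label, start, end, minutes, strand = ln.split("\t")
        rows.append(
            Table1Row(
                no=int(no),
                sequence=seq,
                length=int(length),
                type_label=label,
                start=int(start),
                end=int(end),
                minutes=float(minutes),
                strand=strand,
            )
        )
    return rows
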