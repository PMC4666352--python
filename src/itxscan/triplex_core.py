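"""Intrastrand triplex and hairpin motif enumeration.

An intrastrand triplex arises when a single DNA strand folds back twice so
that three tracts (stemA, stemB, stemC, each 6-15 nt, separated by two
arbitrary 1-6 nt loops) stack into a triple helix. Four classes exist,
distinguished by the 5'->3' order of the pyrimidine-rich (Y), purine-rich
(R) and (reverse-)Hoogsteen ((R)H) tracts:

    class I   (R)H - R - Y   purine motif    triads A*A-T, G*G-C, T*A-T
    class II  Y - R - (R)H   purine motif    triads C-G*G, T-A*A, T-A*T
    class III R - Y - H      pyrimidine motif triads A-T*T, G-C*C
    class IV  H - Y - R      pyrimidine motif triads T*T-A, C*C-G

Both fold-backs are antiparallel, so the stacked triad at position ``k`` of
an ``L``-long stem reads ``(stemA[k], stemB[L-1-k], stemC[k])``. "Mixed"
stems are allowed: any triad from the class's set may appear at any stack
position. One stack position whose triad falls outside the class's set is a
mismatch; a single mismatch is tolerated for stems of 7 nt or longer, none
for 6-nt stems.

The scanner enumerates every qualifying ``(start, stem, loop1, loop2)``
tuple per class and strand (``collapse="all"``, mirroring one output row per
entry); ``collapse="leftmost_longest"`` reduces each cluster of mutually
overlapping same-class same-strand tuples to a single representative for
genome summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqio import (
    GenomeRecord,
    circular_extend,
    circular_padding,
    reverse_complement,
)

__all__ = [
    "TRIPLET_TABLE",
    "STEM_A_ALPHABET",
    "CLASSES",
    "TriplexParams",
    "TriplexHit",
    "HairpinHit",
    "triplet_valid",
    "allowance",
    "find_triplexes",
    "find_hairpins",
    "collapse_hits",
    "write_hits_tsv",
    "write_hits_bed",
]

CLASSES = ("I", "II", "III", "IV")

#: allowed (stemA, stemB, stemC) triads per class, read at one stack position
TRIPLET_TABLE: dict[str, frozenset[tuple[str, str, str]]] = {
    "I": frozenset({("A", "A", "T"), ("G", "G", "C"), ("T", "A", "T")}),
    "II": frozenset({("C", "G", "G"), ("T", "A", "A"), ("T", "A", "T")}),
    "III": frozenset({("A", "T", "T"), ("G", "C", "C")}),
    "IV": frozenset({("T", "T", "A"), ("C", "C", "G")}),
}

#: per-class stemA letters (projection of the triad set onto its first slot)
STEM_A_ALPHABET: dict[str, frozenset[str]] = {
    cls: frozenset(t[0] for t in triads) for cls, triads in TRIPLET_TABLE.items()
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c

# one bit per class; N (code 4) never appears in any triad, hence never valid
_LUTMASK = np.zeros((5, 5, 5), dtype=np.uint8)
for _ci, _cls in enumerate(CLASSES):
    for _a, _b2, _c2 in TRIPLET_TABLE[_cls]:
        _LUTMASK[_CODE[_a], _CODE[_b2], _CODE[_c2]] |= 1 << _ci

# Watson-Crick pair lookup for the hairpin scan
_PAIR = np.zeros((5, 5), dtype=np.uint8)
for _a, _b2 in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
    _PAIR[_CODE[_a], _CODE[_b2]] = 1


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def triplet_valid(triplex_class: str, a: str, b: str, c: str) -> bool:
    """True iff (a, b, c) is an allowed stack triad of ``triplex_class``.

    Any N makes the triad invalid.
    """
    if triplex_class not in TRIPLET_TABLE:
        raise ValueError(f"unknown triplex class {triplex_class!r}")
    for base in (a, b, c):
        if base not in _CODE:
            raise ValueError(f"invalid base {base!r}")
    return (a, b, c) in TRIPLET_TABLE[triplex_class]


def allowance(stem_len: int, allow_mismatch: bool = True) -> int:
    """Mismatch allowance as a pure function of stem length.

    No mismatches for 6-nt stems, at most one for stems of 7 nt or longer
    (unless mismatches are disabled altogether).
    """
    return 1 if (allow_mismatch and stem_len >= 7) else 0


@dataclass(frozen=True)
class TriplexParams:
    """Search-space parameters for :func:`find_triplexes`."""

    min_stem: int = 6
    max_stem: int = 15
    min_loop: int = 1
    max_loop: int = 6
    allow_mismatch: bool = True
    classes: tuple[str, ...] = CLASSES
    strands: tuple[str, ...] = ("+", "-")
    circular: bool = False
    collapse: str = "all"

    def __post_init__(self) -> None:
        if not (6 <= self.min_stem <= self.max_stem):
            raise ValueError("stem range must satisfy 6 <= min_stem <= max_stem")
        if not (1 <= self.min_loop <= self.max_loop):
            raise ValueError("loop range must satisfy 1 <= min_loop <= max_loop")
        for cls in self.classes:
            if cls not in TRIPLET_TABLE:
                raise ValueError(f"unknown triplex class {cls!r}")
        for s in self.strands:
            if s not in ("+", "-"):
                raise ValueError(f"unknown strand {s!r}")
        if self.collapse not in ("all", "leftmost_longest"):
            raise ValueError(f"unknown collapse policy {self.collapse!r}")

    def allowance(self, stem_len: int) -> int:
        return allowance(stem_len, self.allow_mismatch)


@dataclass(frozen=True)
class TriplexHit:
    """One enumerated intrastrand triplex.

    ``start``/``end`` are 0-based half-open forward-strand coordinates (for
    circular scans ``end`` may exceed the genome length when the motif spans
    the origin). The stem/loop strings are in motif-strand 5'->3'
    orientation; ``stem_gc`` is the G+C fraction over the 3L stem positions.
    """

    record_id: str
    start: int
    end: int
    strand: str
    triplex_class: str
    stem_len: int
    loop1_len: int
    loop2_len: int
    stemA: str
    loop1: str
    stemB: str
    loop2: str
    stemC: str
    mismatches: int
    stem_gc: float

    @property
    def motif(self) -> str:
        return self.stemA + self.loop1 + self.stemB + self.loop2 + self.stemC

    def triads(self) -> list[tuple[str, str, str]]:
        L = self.stem_len
        return [(self.stemA[k], self.stemB[L - 1 - k], self.stemC[k]) for k in range(L)]


@dataclass(frozen=True)
class HairpinHit:
    """One inverted-repeat hairpin (strand-agnostic by symmetry)."""

    record_id: str
    start: int
    end: int
    stem_len: int
    loop_len: int
    arm1: str
    loop: str
    arm2: str
    mismatches: int

    @property
    def motif(self) -> str:
        return self.arm1 + self.loop + self.arm2


def _scan_frame_triplex(x: np.ndarray, params: TriplexParams):
    """Yield (class, pos, L, l1, l2, mismatches) over one oriented frame."""
    n = len(x)
    class_bits = [(cls, CLASSES.index(cls)) for cls in params.classes]
    for L in range(params.min_stem, params.max_stem + 1):
        allow = params.allowance(L)
        for l1 in range(params.min_loop, params.max_loop + 1):
            for l2 in range(params.min_loop, params.max_loop + 1):
                span = 3 * L + l1 + l2
                m = n - span + 1
                if m <= 0:
                    continue
                counts = np.zeros((len(class_bits), m), dtype=np.int16)
                for k in range(L):
                    a = x[k : k + m]
                    b = x[2 * L + l1 - 1 - k : 2 * L + l1 - 1 - k + m]
                    c = x[2 * L + l1 + l2 + k : 2 * L + l1 + l2 + k + m]
                    mask = _LUTMASK[a, b, c]
                    for ci, (_, bit) in enumerate(class_bits):
                        counts[ci] += (mask >> bit) & 1
                for ci, (cls, _) in enumerate(class_bits):
                    mism = L - counts[ci]
                    for p in np.nonzero(mism <= allow)[0]:
                        yield cls, int(p), L, l1, l2, int(mism[p])


def _gc_fraction(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


def _build_triplex_hit(record_id, cls, strand, fstart, fend, motif, L, l1, l2, mism):
    stemA = motif[:L]
    loop1 = motif[L : L + l1]
    stemB = motif[L + l1 : 2 * L + l1]
    loop2 = motif[2 * L + l1 : 2 * L + l1 + l2]
    stemC = motif[2 * L + l1 + l2 :]
    return TriplexHit(
        record_id=record_id,
        start=fstart,
        end=fend,
        strand=strand,
        triplex_class=cls,
        stem_len=L,
        loop1_len=l1,
        loop2_len=l2,
        stemA=stemA,
        loop1=loop1,
        stemB=stemB,
        loop2=loop2,
        stemC=stemC,
        mismatches=mism,
        stem_gc=_gc_fraction(stemA + stemB + stemC),
    )


def _scan_sequence(record: GenomeRecord, params: TriplexParams) -> tuple[str, int]:
    """Resolve the (possibly circularly extended) scan sequence."""
    n = len(record.seq)
    if params.circular and record.circular:
        pad = circular_padding(params.max_stem, params.max_loop)
        if pad > n:
            warnings.warn(
                f"record {record.id!r} is shorter than the circular pad "
                f"({pad} nt); scanning as linear",
                stacklevel=3,
            )
            return record.seq, n
        return circular_extend(record, params.max_stem, params.max_loop), n
    return record.seq, n


def find_triplexes(record: GenomeRecord, params: TriplexParams | None = None) -> list[TriplexHit]:
    """Enumerate intrastrand triplex motifs of the requested classes.

    Every position is tested as a stemA anchor for every stem length, loop1
    and loop2 combination; a tuple qualifies when at most ``allowance(L)``
    stack positions carry an invalid triad. The reverse strand is searched by
    scanning the reverse complement and mapping coordinates back to the
    forward strand. Circular records are scanned across the origin and each
    motif is reported once (anchored at its forward start within the
    original coordinates).
    """
    params = params or TriplexParams()
    if not record.seq:
        return []
    scan_seq, n = _scan_sequence(record, params)
    nx = len(scan_seq)
    hits: list[TriplexHit] = []
    for strand in params.strands:
        frame = scan_seq if strand == "+" else reverse_complement(scan_seq)
        x = _encode(frame)
        for cls, p, L, l1, l2, mism in _scan_frame_triplex(x, params):
            span = 3 * L + l1 + l2
            if strand == "+":
                fstart, fend = p, p + span
            else:
                fstart, fend = nx - (p + span), nx - p
            if fstart >= n:  # duplicate copy inside the circular pad
                continue
            hits.append(
                _build_triplex_hit(
                    record.id, cls, strand, fstart, fend,
                    frame[p : p + span], L, l1, l2, mism,
                )
            )
    hits.sort(key=_hit_order)
    if params.collapse == "leftmost_longest":
        circ = n if (params.circular and record.circular and nx > n) else None
        hits = collapse_hits(hits, "leftmost_longest", circular_length=circ)
    return hits


def _hit_order(h) -> tuple:
    cls = getattr(h, "triplex_class", "")
    strand = getattr(h, "strand", "+")
    return (h.start, h.end, cls, strand,
            getattr(h, "loop1_len", getattr(h, "loop_len", 0)),
            getattr(h, "loop2_len", 0))


def find_hairpins(
    record: GenomeRecord,
    min_stem: int = 9,
    max_stem: int = 15,
    min_loop: int = 1,
    max_loop: int = 6,
    max_mismatch: int = 1,
    circular: bool = False,
    collapse: str = "all",
) -> list[HairpinHit]:
    """Enumerate inverted-repeat hairpins (default: the TM-like pattern).

    The two arms must be reverse-complementary at all but at most
    ``max_mismatch`` stem positions. A hairpin on the reverse strand is the
    same fold, so only the forward strand is scanned.
    """
    if not record.seq:
        return []
    if not (min_stem <= max_stem) or not (min_loop <= max_loop):
        raise ValueError("invalid stem/loop ranges")
    n = len(record.seq)
    if circular and record.circular:
        pad = 2 * max_stem + max_loop
        if pad > n:
            warnings.warn(
                f"record {record.id!r} shorter than circular pad; scanning as linear",
                stacklevel=2,
            )
            scan_seq = record.seq
        else:
            scan_seq = record.seq + record.seq[:pad]
    else:
        scan_seq = record.seq
    x = _encode(scan_seq)
    nx = len(x)
    hits: list[HairpinHit] = []
    for s in range(min_stem, max_stem + 1):
        for loop in range(min_loop, max_loop + 1):
            span = 2 * s + loop
            m = nx - span + 1
            if m <= 0:
                continue
            good = np.zeros(m, dtype=np.int16)
            for k in range(s):
                a = x[k : k + m]
                b = x[2 * s + loop - 1 - k : 2 * s + loop - 1 - k + m]
                good += _PAIR[a, b]
            mism = s - good
            for p in np.nonzero(mism <= max_mismatch)[0]:
                p = int(p)
                if p >= n:
                    continue
                motif = scan_seq[p : p + span]
                hits.append(
                    HairpinHit(
                        record_id=record.id,
                        start=p,
                        end=p + span,
                        stem_len=s,
                        loop_len=loop,
                        arm1=motif[:s],
                        loop=motif[s : s + loop],
                        arm2=motif[s + loop :],
                        mismatches=int(mism[p]),
                    )
                )
    hits.sort(key=_hit_order)
    if collapse == "leftmost_longest":
        circ = n if (circular and record.circular and nx > n) else None
        hits = collapse_hits(hits, "leftmost_longest", circular_length=circ)
    return hits


def collapse_hits(hits: list, policy: str, circular_length: int | None = None) -> list:
    """Reduce overlapping same-class same-strand hits to one representative.

    ``policy="all"`` is the identity. ``policy="leftmost_longest"`` groups
    mutually overlapping hits of equal class and strand (transitively, and
    modulo the genome length for circular scans) and keeps, per group, the
    hit with the smallest start, then the largest stem, then the smallest
    loop1, then the smallest loop2.
    """
    if policy == "all":
        return sorted(hits, key=_hit_order)
    if policy != "leftmost_longest":
        raise ValueError(f"unknown collapse policy {policy!r}")

    def group_key(h):
        return (getattr(h, "triplex_class", None), getattr(h, "strand", None))

    def rep_key(h):
        return (
            h.start,
            -h.stem_len,
            getattr(h, "loop1_len", getattr(h, "loop_len", 0)),
            getattr(h, "loop2_len", 0),
        )

    groups: dict[tuple, list] = {}
    for h in hits:
        groups.setdefault(group_key(h), []).append(h)

    out = []
    for members in groups.values():
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        intervals = [(h.start, h.end, i) for i, h in enumerate(members)]
        if circular_length is not None:
            intervals += [
                (h.start - circular_length, h.end - circular_length, i)
                for i, h in enumerate(members)
            ]
        intervals.sort()
        run_end = None
        run_rep = None
        for s, e, i in intervals:
            if run_end is not None and s < run_end:
                union(run_rep, i)
                run_end = max(run_end, e)
            else:
                run_rep, run_end = i, e
        comps: dict[int, list] = {}
        for i, h in enumerate(members):
            comps.setdefault(find(i), []).append(h)
        for comp in comps.values():
            out.append(min(comp, key=rep_key))
    out.sort(key=_hit_order)
    return out


def write_hits_tsv(hits: list[TriplexHit], path) -> None:
    """Write triplex hits as TSV (1-based location, per-stem/loop columns)."""
    cols = (
        "record\tlocation\ttype\tstem_size\tloop1_size\tloop2_size\tstrand\t"
        "stemA\tloop1\tstemB\tloop2\tstemC\tmismatches\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hits:
            fh.write(
                f"{h.record_id}\t{h.start + 1}\t{h.triplex_class}\t{h.stem_len}\t"
                f"{h.loop1_len}\t{h.loop2_len}\t{h.strand}\t{h.stemA}\t{h.loop1}\t"
                f"{h.stemB}\t{h.loop2}\t{h.stemC}\t{h.mismatches}\n"
            )


def write_hits_bed(hits: list[TriplexHit], path) -> None:
    """Write hits as BED6 (0-based half-open; name=class, score=stem length)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.record_id}\t{h.start}\t{h.end}\t{h.triplex_class}\t"
                f"{h.stem_len}\t{h.strand}\n"
            )
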