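"""Alignment-column variability statistic and locus categorization.

Given a multiple alignment of homologous loci from closely related strains
(locally collinear blocks realigned with a standard aligner), the per-column
state count n_i is the number of distinct symbols - A, C, G, T or gap -
observed in column i. The windowed statistic

    v_j = (1/l) * sum_{i = j-(l-1)/2}^{j+(l-1)/2} (n_i - 1)

(window l = 11 by default) is the average excess variability around column
j: 0 for a fully conserved neighbourhood, up to 4 when every column in the
window realizes all five states. A variable region opens at the first column
of a run of at least 10 consecutive columns with v_j > 0.9 and closes just
before the first subsequent run of 10 consecutive columns with v_j < 0.5.

Locus categorization consumes 12-column tabular homology hits (megaBLAST
"outfmt 6" dialect) for a query window around a motif (500 nt of flank on
each side) against one subject genome and assigns one of four categories:
no change, region missing (an uncovered stretch longer than 300 nt),
intergenic change (changes confined to the annotated intergenic interval)
or no homology (no hit at all), with missing/mutated motif subcategories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "Alignment",
    "VariabilityParams",
    "VariabilityProfile",
    "VariableRegion",
    "HomologySegment",
    "LocusComparison",
    "read_aligned_fasta",
    "read_blast_tab",
    "segments_from_table",
    "read_bed",
    "column_states",
    "variability_profile",
    "detect_variable_regions",
    "variable_length_at",
    "categorize_locus",
    "write_regions_tsv",
    "write_loci_tsv",
]

_SYMBOLS = "ACGT-"
_SYM_CODE = {c: i for i, c in enumerate(_SYMBOLS)}

BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment: equal-length rows over {A,C,G,T,N,-}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(f"ragged alignment: row {rid!r} has length {len(row)}")
            bad = set(row) - set("ACGTN-")
            if bad:
                raise ValueError(f"row {rid!r} contains invalid symbols {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class VariabilityParams:
    """Window and region-calling thresholds for the v_j statistic."""

    window: int = 11
    start_threshold: float = 0.9
    end_threshold: float = 0.5
    run_length: int = 10

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0 <= self.end_threshold <= 4 and 0 <= self.start_threshold <= 4):
            raise ValueError("thresholds must lie in [0, 4]")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


@dataclass(frozen=True)
class VariabilityProfile:
    """Per-column state counts n and windowed values v (NaN at edges)."""

    n: np.ndarray
    v: np.ndarray
    params: VariabilityParams


@dataclass(frozen=True)
class VariableRegion:
    """One variable interval in alignment-column coordinates (inclusive)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class HomologySegment:
    """One homology hit in query coordinates (0-based half-open)."""

    qstart: int
    qend: int
    pident: float
    sseqid: str = ""

    def __post_init__(self) -> None:
        if self.qend <= self.qstart:
            raise ValueError("segment must satisfy qstart < qend")
        if not (0 <= self.pident <= 100):
            raise ValueError("pident must lie in [0, 100]")


@dataclass(frozen=True)
class LocusComparison:
    """Category and subcategory for one (locus, subject genome) pair."""

    category: str
    subcategory: str = "none"
    locus_id: str = ""
    subject_id: str = ""


def read_aligned_fasta(path) -> Alignment:
    """Read a gapped FASTA alignment (gaps as '-')."""
    aln = AlignIO.read(str(path), "fasta")
    ids = tuple(rec.id for rec in aln)
    rows = tuple(str(rec.seq).upper().replace(".", "-") for rec in aln)
    return Alignment(ids=ids, rows=rows)


def read_blast_tab(path) -> pd.DataFrame:
    """Read 12-column tabular homology output (outfmt 6 dialect)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=BLAST_TAB_COLUMNS)
    if df.empty:
        return df
    return df


def segments_from_table(df: pd.DataFrame, subject_id: str | None = None) -> list[HomologySegment]:
    """Convert tabular rows to query-coordinate segments.

    Tabular query coordinates are 1-based inclusive; they become 0-based
    half-open here.
    """
    if subject_id is not None:
        df = df[df["sseqid"] == subject_id]
    segs = []
    for row in df.itertuples(index=False):
        qs, qe = int(row.qstart), int(row.qend)
        if qe < qs:
            qs, qe = qe, qs
        segs.append(HomologySegment(qstart=qs - 1, qend=qe,
                                    pident=float(row.pident),
                                    sseqid=str(row.sseqid)))
    return segs


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def column_states(alignment: Alignment) -> np.ndarray:
    """Per-column count of distinct symbols among {A,C,G,T,-}.

    N is not a state and is excluded; a column consisting only of N counts
    as a single state by convention.
    """
    mat = np.array([[_SYM_CODE.get(c, 5) for c in row] for row in alignment.rows],
                   dtype=np.int8)
    counts = np.zeros(alignment.width, dtype=np.int64)
    for code in range(5):
        counts += (mat == code).any(axis=0)
    return np.maximum(counts, 1)


def variability_profile(n: np.ndarray, params: VariabilityParams | None = None) -> VariabilityProfile:
    """Windowed mean of (n_i - 1), centered; edge columns are NaN.

    Raises when the window is even or longer than the alignment.
    """
    params = params or VariabilityParams()
    n = np.asarray(n, dtype=float)
    l = params.window
    if l > len(n):
        raise ValueError(f"window ({l}) longer than alignment ({len(n)})")
    core = np.convolve(n - 1.0, np.ones(l) / l, mode="valid")
    v = np.full(len(n), np.nan)
    half = (l - 1) // 2
    v[half : half + len(core)] = core
    return VariabilityProfile(n=n.astype(np.int64), v=v, params=params)


def _run_starts(flags: np.ndarray, run_length: int) -> np.ndarray:
    """Boolean array: True where a run of >= run_length True flags begins."""
    if len(flags) < run_length:
        return np.zeros(len(flags), dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(flags, run_length)
    starts = np.zeros(len(flags), dtype=bool)
    starts[: len(windows)] = windows.all(axis=1)
    return starts


def detect_variable_regions(
    v: np.ndarray, params: VariabilityParams | None = None
) -> list[VariableRegion]:
    """Call variable regions from a v_j vector.

    A region opens at the first column of the first run of ``run_length``
    consecutive values above ``start_threshold`` and closes at the column
    preceding the first subsequent run of ``run_length`` consecutive values
    below ``end_threshold`` (the closing run itself is outside the region);
    without a closing run the region extends to the last defined column.
    """
    params = params or VariabilityParams()
    v = np.asarray(v, dtype=float)
    defined = ~np.isnan(v)
    if not defined.any():
        return []
    first, last = np.nonzero(defined)[0][[0, -1]]
    hi = defined & (v > params.start_threshold)
    lo = defined & (v < params.end_threshold)
    rl = params.run_length
    hi_starts = _run_starts(hi, rl)
    lo_starts = _run_starts(lo, rl)
    regions: list[VariableRegion] = []
    i = first
    while i <= last:
        opens = np.nonzero(hi_starts[i:])[0]
        if len(opens) == 0:
            break
        start = i + int(opens[0])
        closes = np.nonzero(lo_starts[start:])[0]
        if len(closes) == 0:
            regions.append(VariableRegion(start=start, end=int(last)))
            break
        close = start + int(closes[0])
        regions.append(VariableRegion(start=start, end=close - 1))
        i = close + rl
    return regions


def variable_length_at(regions: list[VariableRegion], pos: int) -> int:
    """Length of the variable region containing ``pos`` (0 if none does)."""
    for r in regions:
        if r.contains(pos):
            return r.length
    return 0


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _complement(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    gaps = []
    pos = 0
    for s, e in intervals:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        gaps.append((pos, length))
    return gaps


def _within(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def categorize_locus(
    query_length: int,
    tm_interval: tuple[int, int],
    intergenic_interval: tuple[int, int] | None,
    segments: list[HomologySegment],
    hairpin_check: bool = False,
    locus_id: str = "",
    subject_id: str = "",
    cover_identity: float = 90.0,
    change_identity: float = 99.0,
    min_gap: int = 10,
    missing_min: int = 300,
) -> LocusComparison:
    """Categorize one motif locus against one subject genome.

    Segments are homology hits in query coordinates (the motif plus 500 nt of
    flank on each side, typically). Categories:

    - ``no_homology``: no segment at all.
    - ``region_missing``: some stretch longer than ``missing_min`` nt of the
      query is uncovered by any segment of at least ``cover_identity``.
    - ``intergenic_change``: the uncovered stretches (>= ``min_gap`` nt) and
      sub-``change_identity`` segments are all confined to the annotated
      intergenic interval.
    - ``no_change``: nothing above holds (in particular: full coverage at
      >= ``change_identity`` up to sub-``min_gap`` gaps).

    Subcategory (for region_missing / intergenic_change only): ``tm_missing``
    when the motif interval is entirely uncovered, ``tm_mutated`` when it is
    covered but not at 100% identity throughout, and ``palindrome_effect``
    when ``hairpin_check`` is set and the motif is partially lost - the
    caller asserts a hairpin-capable remnant survives in the subject.
    Without an intergenic annotation, loci that are not region_missing fall
    back to no_change with a warning.
    """
    for seg in segments:
        if seg.qstart < 0 or seg.qend > query_length:
            raise ValueError(
                f"segment ({seg.qstart}, {seg.qend}) outside query of length {query_length}"
            )
    if not segments:
        return LocusComparison("no_homology", "none", locus_id, subject_id)

    covered = _merge_intervals(
        [(s.qstart, s.qend) for s in segments if s.pident >= cover_identity]
    )
    gaps = [g for g in _complement(covered, query_length) if g[1] - g[0] >= min_gap]
    mutated_spans = _merge_intervals(
        [(s.qstart, s.qend) for s in segments
         if cover_identity <= s.pident < change_identity]
    )
    changes = gaps + mutated_spans

    if any(e - s > missing_min for s, e in gaps):
        category = "region_missing"
    elif not changes:
        category = "no_change"
    elif intergenic_interval is None:
        warnings.warn(
            "no intergenic annotation supplied; intergenic_change cannot be "
            "assigned", stacklevel=2,
        )
        category = "no_change"
    elif all(_within(ch, intergenic_interval) for ch in changes):
        category = "intergenic_change"
    else:
        category = "no_change"

    subcategory = "none"
    if category in ("region_missing", "intergenic_change"):
        ts, te = tm_interval
        tm_cov = [
            (max(ts, s), min(te, e)) for s, e in covered if min(te, e) > max(ts, s)
        ]
        covered_len = sum(e - s for s, e in tm_cov)
        if covered_len == 0:
            subcategory = "tm_missing"
        else:
            full = covered_len == te - ts
            perfect = all(
                s.pident == 100.0
                for s in segments
                if s.pident >= cover_identity and s.qstart < te and s.qend > ts
            )
            if not (full and perfect):
                subcategory = "tm_mutated"
        if hairpin_check and subcategory in ("tm_missing", "tm_mutated"):
            subcategory = "palindrome_effect"
    return LocusComparison(category, subcategory, locus_id, subject_id)


def write_regions_tsv(regions: list[VariableRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\n")
        for r in regions:
            fh.write(f"{r.start}\t{r.end}\t{r.length}\n")


def write_loci_tsv(loci: list[LocusComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tsubject\tcategory\tsubcategory\n")
        for lc in loci:
            fh.write(f"{lc.locus_id}\t{lc.subject_id}\t{lc.category}\t{lc.subcategory}\n")
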