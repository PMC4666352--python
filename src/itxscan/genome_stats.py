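"""Per-genome scan summaries and wild-type vs scrambled-control comparison.

The enrichment null for motif content is a mononucleotide shuffle of the
genome: it preserves length and base composition exactly, so any excess of
motifs in the wild-type sequence over its scrambled twin reflects sequence
order, not composition. Summaries bin hits by class, stem size and stem G+C
content; motifs whose stems are more than 50% G+C are counted as "GC50",
the rest (including exactly 50%) as "AT50".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seqio import GenomeRecord, scramble_sequence
from .triplex_core import CLASSES, TriplexHit, TriplexParams, find_triplexes

__all__ = ["ScanSummary", "ComparisonReport", "summarize_hits", "compare_wt_scrambled",
           "write_summary_tsv", "format_report"]


@dataclass(frozen=True)
class ScanSummary:
    """Counts of one scan: total, per class, per stem size, by stem G+C bin."""

    genome_id: str
    genome_length: int
    genome_gc: float
    total: int
    per_class: dict[str, int]
    per_stem_size: dict[int, int]
    gc50: int
    at50: int

    def class_fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {cls: 0.0 for cls in CLASSES}
        return {cls: self.per_class[cls] / self.total for cls in CLASSES}


@dataclass(frozen=True)
class ComparisonReport:
    """Wild-type vs scrambled-control scan of one genome under one seed."""

    wt: ScanSummary
    scrambled: ScanSummary
    seed: int

    @property
    def ratio_total(self) -> float | None:
        return self.scrambled.total / self.wt.total if self.wt.total else None

    def per_stem_ratios(self) -> dict[int, float | None]:
        out = {}
        for size, wt_n in self.wt.per_stem_size.items():
            sc_n = self.scrambled.per_stem_size.get(size, 0)
            out[size] = sc_n / wt_n if wt_n else None
        return out


def _genome_gc(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def summarize_hits(
    hits: list[TriplexHit],
    genome: GenomeRecord,
    min_stem: int = 6,
    max_stem: int = 15,
) -> ScanSummary:
    """Bin one genome's hits by class, stem size and stem G+C content.

    Genome G+C is computed over A/C/G/T positions only (N excluded).
    """
    per_class = {cls: 0 for cls in CLASSES}
    per_stem = {size: 0 for size in range(min_stem, max_stem + 1)}
    gc50 = 0
    for h in hits:
        per_class[h.triplex_class] += 1
        per_stem[h.stem_len] = per_stem.get(h.stem_len, 0) + 1
        if h.stem_gc > 0.5:
            gc50 += 1
    return ScanSummary(
        genome_id=genome.id,
        genome_length=len(genome.seq),
        genome_gc=_genome_gc(genome.seq),
        total=len(hits),
        per_class=per_class,
        per_stem_size=per_stem,
        gc50=gc50,
        at50=len(hits) - gc50,
    )


def compare_wt_scrambled(
    genome: GenomeRecord, params: TriplexParams, seed: int
) -> ComparisonReport:
    """Scan a genome and its mononucleotide-scrambled control identically."""
    wt_hits = find_triplexes(genome, params)
    control = replace(genome, id=f"{genome.id}_scrambled",
                      seq=scramble_sequence(genome.seq, seed))
    sc_hits = find_triplexes(control, params)
    return ComparisonReport(
        wt=summarize_hits(wt_hits, genome, params.min_stem, params.max_stem),
        scrambled=summarize_hits(sc_hits, control, params.min_stem, params.max_stem),
        seed=seed,
    )


def write_summary_tsv(summaries: list[ScanSummary], path) -> None:
    """One row per genome: totals, per-class counts, G/C bins."""
    with open(path, "w") as fh:
        fh.write(
            "genome\tlength\tgc\ttotal\t"
            + "\t".join(f"class_{c}" for c in CLASSES)
            + "\tgc50\tat50\n"
        )
        for s in summaries:
            fh.write(
                f"{s.genome_id}\t{s.genome_length}\t{s.genome_gc:.4f}\t{s.total}\t"
                + "\t".join(str(s.per_class[c]) for c in CLASSES)
                + f"\t{s.gc50}\t{s.at50}\n"
            )


def format_report(report: ComparisonReport) -> str:
    """Human-readable block for one wild-type vs scrambled comparison."""
    lines = [
        f"genome {report.wt.genome_id} ({report.wt.genome_length} nt, "
        f"GC {report.wt.genome_gc:.1%})",
        f"  wild-type hits: {report.wt.total}",
        f"  scrambled hits: {report.scrambled.total} (seed {report.seed})",
    ]
    if report.ratio_total is not None:
        lines.append(f"  scrambled/wt ratio: {report.ratio_total:.1%}")
    wt_frac = report.wt.class_fractions()
    sc_frac = report.scrambled.class_fractions()
    lines.append(
        "  class fractions wt:        "
        + "  ".join(f"{c} {wt_frac[c]:.1%}" for c in CLASSES)
    )
    lines.append(
        "  class fractions scrambled: "
        + "  ".join(f"{c} {sc_frac[c]:.1%}" for c in CLASSES)
    )
    sizes = sorted(report.wt.per_stem_size)
    lines.append(
        "  per-stem-size wt/scrambled: "
        + "  ".join(
            f"{s}:{report.wt.per_stem_size[s]}/{report.scrambled.per_stem_size.get(s, 0)}"
            for s in sizes
        )
    )
    return "\n".join(lines)
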