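"""Sequence I/O and plumbing for genome scans.

Genomes come in as plain (multi-record) FASTA. On load every sequence is
uppercased and IUPAC ambiguity codes are mapped to ``N``; the scanners treat
``N`` as a base that can never participate in a valid triplet or basepair,
so ambiguous positions simply cannot anchor a motif. ``U`` is rejected:
purine-motif triplexes cannot form in RNA and this is strictly a DNA tool.

Bacterial chromosomes and plasmids are circular, so a scan must be able to
see motifs that span the origin. Following the usual trick, the first
``3*max_stem + 2*max_loop`` characters (the longest possible motif) are
appended to the end of the sequence before scanning and hits are reported
only when they start inside the original coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "normalize_sequence",
    "reverse_complement",
    "circular_extend",
    "circular_padding",
    "scramble_sequence",
]

#: canonical bases; everything else in a loaded sequence becomes N
DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC one-letter codes (minus ACGT) all collapse to N at load time
_AMBIGUITY = "RYSWKMBDHVN"
_NORMALIZE = str.maketrans(_AMBIGUITY, "N" * len(_AMBIGUITY))


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input (empty file / empty record)."""


@dataclass
class GenomeRecord:
    """One named DNA sequence, the unit every scanner operates on.

    ``seq`` is uppercase over {A,C,G,T,N}. ``circular`` marks replicons that
    should be scanned across the origin.
    """

    id: str
    seq: str
    description: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str, name: str = "<seq>") -> str:
    """Uppercase ``raw`` and map ambiguity codes to N.

    ``U`` raises (RNA input), as does anything that is not an IUPAC code.
    """
    seq = raw.upper()
    if "U" in seq:
        raise ValueError(f"record {name!r} looks like RNA (contains U); DNA required")
    seq = seq.translate(_NORMALIZE)
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"record {name!r} contains invalid characters: {sorted(bad)}")
    return seq


def read_fasta(path, circular: bool = False) -> list[GenomeRecord]:
    """Read a multi-record FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased, non-ACGT IUPAC letters become N, multi-line
    sequences are concatenated and record order is preserved. Raises
    :class:`FastaFormatError` for empty files or empty records, and
    ``ValueError`` for duplicate ids.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(
                id=rec.id,
                seq=normalize_sequence(str(rec.seq), rec.id),
                description=rec.description,
                circular=circular,
            )
        )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write records as 60-column wrapped FASTA."""
    bio = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def reverse_complement(seq: str) -> str:
    """Standard reverse complement over {A,C,G,T,N} (N maps to N)."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def circular_padding(max_stem: int, max_loop: int) -> int:
    """Length of the origin-spanning pad: 3*max_stem + 2*max_loop."""
    return 3 * max_stem + 2 * max_loop


def circular_extend(record: GenomeRecord, max_stem: int = 15, max_loop: int = 6) -> str:
    """Append the genome prefix to its end to simulate the circular replicon.

    The pad is the longest motif the parameters allow (three stems plus two
    loops), so every origin-spanning motif appears contiguously exactly once.
    Raises if the record is linear or shorter than the pad (no more than one
    wrap-around is ever simulated).
    """
    if not record.circular:
        raise ValueError(f"record {record.id!r} is not circular")
    if max_stem < 6 or max_loop < 1:
        raise ValueError("max_stem must be >= 6 and max_loop >= 1")
    pad = circular_padding(max_stem, max_loop)
    if pad > len(record.seq):
        raise ValueError(
            f"record {record.id!r} ({len(record.seq)} nt) is shorter than the "
            f"circular pad ({pad} nt)"
        )
    return record.seq + record.seq[:pad]


def scramble_sequence(seq: str, seed: int) -> str:
    """Mononucleotide-composition-preserving shuffle (the enrichment null).

    A uniform random permutation (Fisher-Yates, via numpy) of the characters,
    deterministic for a given seed. Length and the exact count of every
    letter are preserved.
    """
    if not seq:
        raise ValueError("cannot scramble an empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"cannot scramble characters {sorted(bad)}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    rng = np.random.default_rng(seed)
    return rng.permutation(arr).tobytes().decode("ascii")
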