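"""Independent brute-force enumerations used as oracles by the test suite.

These deliberately share no code with the package scanners: plain string
slicing and per-position triad checks, exhaustive over every
(position, stem, loop1, loop2, class, strand) tuple.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

TRIADS = {
    "I": {("A", "A", "T"), ("G", "G", "C"), ("T", "A", "T")},
    "II": {("C", "G", "G"), ("T", "A", "A"), ("T", "A", "T")},
    "III": {("A", "T", "T"), ("G", "C", "C")},
    "IV": {("T", "T", "A"), ("C", "C", "G")},
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_triplexes(
    seq: str,
    min_stem: int = 6,
    max_stem: int = 15,
    min_loop: int = 1,
    max_loop: int = 6,
    allow_mismatch: bool = True,
    classes=("I", "II", "III", "IV"),
    strands=("+", "-"),
):
    """Every qualifying tuple as (start, end, strand, class, L, l1, l2, mism)."""
    n = len(seq)
    out = []
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        for cls in classes:
            table = TRIADS[cls]
            for p in range(n):
                for L in range(min_stem, max_stem + 1):
                    allow = 1 if (allow_mismatch and L >= 7) else 0
                    for l1 in range(min_loop, max_loop + 1):
                        for l2 in range(min_loop, max_loop + 1):
                            span = 3 * L + l1 + l2
                            if p + span > n:
                                continue
                            stem_a = s[p : p + L]
                            stem_b = s[p + L + l1 : p + 2 * L + l1]
                            stem_c = s[p + 2 * L + l1 + l2 : p + span]
                            mism = 0
                            for k in range(L):
                                if (stem_a[k], stem_b[L - 1 - k], stem_c[k]) not in table:
                                    mism += 1
                                    if mism > allow:
                                        break
                            if mism <= allow:
                                if strand == "+":
                                    fs, fe = p, p + span
                                else:
                                    fs, fe = n - (p + span), n - p
                                out.append((fs, fe, strand, cls, L, l1, l2, mism))
    return sorted(out)


def brute_force_hairpins(
    seq: str,
    min_stem: int = 9,
    max_stem: int = 15,
    min_loop: int = 1,
    max_loop: int = 6,
    max_mismatch: int = 1,
):
    """Every qualifying tuple as (start, end, stem, loop, mismatches)."""
    n = len(seq)
    out = []
    for p in range(n):
        for s in range(min_stem, max_stem + 1):
            for loop in range(min_loop, max_loop + 1):
                span = 2 * s + loop
                if p + span > n:
                    continue
                arm1 = seq[p : p + s]
                arm2 = seq[p + s + loop : p + span]
                mism = 0
                for k in range(s):
                    if _COMP[arm1[k]] != arm2[s - 1 - k]:
                        mism += 1
                        if mism > max_mismatch:
                            break
                if mism <= max_mismatch:
                    out.append((p, p + span, s, loop, mism))
    return sorted(out)


def brute_force_column_states(rows) -> list[int]:
    """Per-column distinct-symbol recount (set-based, N excluded)."""
    width = len(rows[0])
    counts = []
    for j in range(width):
        symbols = {row[j] for row in rows} & set("ACGT-")
        counts.append(max(len(symbols), 1))
    return counts
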