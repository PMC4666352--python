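"""Shared fixtures: seeded sequences and hand-built triplex motifs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from itxscan.fixtures import table1_fixtures
from itxscan.triplex_core import TRIPLET_TABLE

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1_rows():
    return table1_fixtures()


def random_dna(seed: int, length: int, probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    """Seeded i.i.d. DNA with base order A, C, G, T."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length, p=list(probs)))


def make_triplex_motif(
    triplex_class: str,
    stem_len: int,
    loop1_len: int,
    loop2_len: int,
    seed: int = 0,
    n_bad: int = 0,
) -> str:
    """Assemble a motif from random allowed triads of one class.

    ``n_bad`` stack positions are overwritten with a triad that is invalid
    for every class (N-free), yielding a motif with exactly that many
    mismatches.
    """
    rng = np.random.default_rng(seed)
    triads = sorted(TRIPLET_TABLE[triplex_class])
    picks = [triads[rng.integers(len(triads))] for _ in range(stem_len)]
    for k in rng.choice(stem_len, size=n_bad, replace=False):
        picks[k] = ("C", "C", "C")  # (C,C,C) is in no class's triad set
    stem_a = "".join(p[0] for p in picks)
    stem_b = "".join(p[1] for p in picks)[::-1]
    stem_c = "".join(p[2] for p in picks)
    loop1 = "".join(rng.choice(list("ACGT"), size=loop1_len))
    loop2 = "".join(rng.choice(list("ACGT"), size=loop2_len))
    return stem_a + loop1 + stem_b + loop2 + stem_c
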