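"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from skipquant import bax_like_pair, fixture_pair
from skipquant.references import IsoformPair
from skipquant.simulate import reverse_complement


@pytest.fixture(scope="session")
def toy_pair() -> IsoformPair:
    """3-exon toy pair, window bases 8-13, junction after base 10."""
    return fixture_pair()


@pytest.fixture(scope="session")
def bax_pair() -> IsoformPair:
    """Synthetic six-exon BAX-like pair with the default 30-40 window."""
    return bax_like_pair()


def brute_force_affine_local(
    read: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Textbook Gotoh local-alignment score, written independently of the
    package's aligner (three explicit DP matrices, no vectorization)."""
    n, m = len(ref), len(read)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in read (ref consumed)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in ref (read consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            a, b = ref[i - 1], read[j - 1]
            sub = match if (a == b and a != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def junction_kmer_oracle(
    read: str, pair: IsoformPair, min_anchor: int, check_rc: bool = True
) -> str:
    """Substring oracle for error-free reads.

    A reference is supported iff the read occurs verbatim at a placement
    that covers the whole diagnostic window and leaves at least
    ``min_anchor`` bases on each side of that reference's junction.  Exactly
    one supported reference gives its call; both give AMBIGUOUS; none gives
    NON_JUNCTION.  Independent of the package's aligner: pure str.find.
    """
    w0, w1 = pair.window
    supported = {}
    for refname in ("canonical", "skipped"):
        ref = pair.model(refname).sequence
        j = pair.junction_pos(refname)
        hit = False
        for query in ([read, reverse_complement(read)] if check_rc else [read]):
            p = ref.find(query)
            while p >= 0 and not hit:
                if (
                    p <= w0
                    and p + len(query) >= w1
                    and j - p >= min_anchor
                    and p + len(query) - j >= min_anchor
                ):
                    hit = True
                p = ref.find(query, p + 1)
        supported[refname] = hit
    if supported["canonical"] and supported["skipped"]:
        return "AMBIGUOUS"
    if supported["canonical"]:
        return "ALPHA"
    if supported["skipped"]:
        return "DELTA2"
    return "NON_JUNCTION"


def seeded_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
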