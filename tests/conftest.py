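"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from bclink import (
    BarcodeSpec,
    FlankDefinition,
    FragmentationConfig,
    GenomicRange,
    fragment_template,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spec():
    return BarcodeSpec()


@pytest.fixture(scope="session")
def flanks():
    return FlankDefinition()


@pytest.fixture(scope="session")
def reference():
    """600 bp random reference, fixed for the whole session."""
    r = np.random.default_rng(2024)
    return "".join(r.choice(list("ACGT"), size=600))


@pytest.fixture(scope="session")
def fragment_pool(reference):
    """Fragment pool cut from the reference (>= 50 nt after the size cut)."""
    r = np.random.default_rng(77)
    cfg = FragmentationConfig(dutp_fraction=0.04, min_fragment_len=50)
    pool = []
    for _ in range(120):
        pool.extend(fragment_template(reference, cfg, r))
    assert len(pool) >= 200
    return pool


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force / closed-form)

def oracle_levenshtein(a: str, b: str) -> int:
    """Full O(nm) DP, no banding, no early exit."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[m]


def oracle_purity(ranges, tol_bp: int = 20) -> float:
    """Purity by direct enumeration of the stated rule.

    ``ranges`` are (start, end, strand) triples (single reference assumed).
    """
    counts = Counter(ranges)
    consensus = min(counts, key=lambda k: (-counts[k], k))
    s0, e0, st0 = consensus
    good = sum(
        c for (s, e, st), c in counts.items()
        if st == st0 and abs(s - s0) <= tol_bp and abs(e - e0) <= tol_bp
    )
    return good / len(ranges)


def oracle_align_all_offsets(fragment: str, reference: str, max_mm: int):
    """Brute-force ungapped alignment over every offset and both strands.

    Returns the best (start, end, strand) or None if no hit under the
    mismatch ceiling or if two hits tie the best score.
    """
    from bclink import revcomp

    n = len(fragment)
    best_score, winners = None, []
    for strand, query in (("+", fragment), ("-", revcomp(fragment))):
        for off in range(len(reference) - n + 1):
            mism = sum(1 for a, b in zip(query, reference[off : off + n])
                       if a != b)
            if mism > max_mm:
                continue
            score = n - 2 * mism
            if best_score is None or score > best_score:
                best_score, winners = score, [(off, off + n, strand)]
            elif score == best_score:
                winners.append((off, off + n, strand))
    if best_score is None or len(winners) > 1:
        return None
    return winners[0]


def make_range(start: int, end: int, strand: str = "+", read_id: str = "",
               ref_id: str = "ref") -> GenomicRange:
    return GenomicRange(ref_id, start, end, strand, read_id=read_id)
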