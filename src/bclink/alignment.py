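"""Desk-scale alignment of extracted fragments to the reference.

A self-contained seed-and-extend local aligner: exact k-mer seeds locate
candidate diagonals on both strands, candidates are scored first by a fast
ungapped (substitution-only) comparison and, failing that, by an affine-gap
fit alignment (global in the fragment, free ends in a reference window).
Only the single best alignment is reported, and only if no second distinct
location ties the best score -- the unique-valid-alignment filter that keeps
repeat-derived fragments out of the lookup table.

Scoring is fixed: match +1, mismatch -1, gap open -2, gap extend -1.
Coordinates are 0-based half-open throughout; BED on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .extraction import ExtractionRecord
from .fragmentation import revcomp

__all__ = [
    "GenomicRange",
    "ReferenceIndex",
    "AlignmentParams",
    "align_fragment",
    "attach_barcode",
    "ranges_to_bed",
]

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2    # cost of the first base of a gap
GAP_EXTEND = -1  # cost of each further base

_NEG = -(10**9)


@dataclass(frozen=True)
class GenomicRange:
    """An oriented interval on the reference (0-based half-open)."""

    ref_id: str
    start: int
    end: int
    strand: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Fragment identity: coordinates and orientation, not read id."""
        return (self.ref_id, self.start, self.end, self.strand)


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment acceptance knobs.

    ``min_len``: fragments shorter than this are not aligned (too ambiguous).
    ``max_mismatch_rate``: ceiling on the mismatch-equivalent fraction; an
    alignment is accepted iff its score is at least
    ``(1 - 2*max_mismatch_rate) * len(fragment)``, which for ungapped
    alignments is exactly a mismatch-rate ceiling.
    ``band``: half-width of the reference window slack for gapped extension.
    """

    min_len: int = 20
    max_mismatch_rate: float = 0.1
    band: int = 8


class ReferenceIndex:
    """Exact k-mer seed index over the forward reference strand."""

    def __init__(self, ref_id: str, sequence: str, k: int = 15) -> None:
        if not sequence:
            raise ValueError("empty reference")
        self.ref_id = ref_id
        self.sequence = sequence.upper()
        self.k = min(k, len(self.sequence))
        self._arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        self._kmers: dict[str, list[int]] = {}
        for i in range(len(self.sequence) - self.k + 1):
            self._kmers.setdefault(self.sequence[i : i + self.k], []).append(i)

    def __len__(self) -> int:
        return len(self.sequence)

    def seed_offsets(self, query: str) -> set[int]:
        """Candidate alignment start offsets (may be slightly off-diagonal)."""
        k = self.k
        offsets: set[int] = set()
        if len(query) < k:
            return offsets
        qpos = list(range(0, len(query) - k + 1, k))
        if qpos[-1] != len(query) - k:
            qpos.append(len(query) - k)
        for q in qpos:
            for pos in self._kmers.get(query[q : q + k], ()):
                offsets.add(pos - q)
        return offsets


def _ungapped_score(index: ReferenceIndex, query_arr: np.ndarray, offset: int
                    ) -> int | None:
    n = query_arr.size
    if offset < 0 or offset + n > len(index):
        return None
    mism = int((index._arr[offset : offset + n] != query_arr).sum())
    return n - 2 * mism


def _fit_align(query: str, window: str) -> tuple[int, int, int]:
    """Affine-gap alignment, global in ``query``, free ends in ``window``.

    Returns ``(score, win_start, win_end)`` of the best placement.  Plain DP
    over the (small) window; start coordinates are propagated alongside
    scores so no traceback is needed.
    """
    n, m = len(query), len(window)
    # state: best score ending at (i, j) with query[:i] consumed
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]      # last op: align
    Ix = [[_NEG] * (m + 1) for _ in range(n + 1)]     # gap in window (del ref)
    Iy = [[_NEG] * (m + 1) for _ in range(n + 1)]     # gap in query (ins ref)
    Sm = [[0] * (m + 1) for _ in range(n + 1)]        # start column per state
    Sx = [[0] * (m + 1) for _ in range(n + 1)]
    Sy = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0
        Sm[0][j] = j
    for i in range(1, n + 1):
        Ix[i][0] = GAP_OPEN if i == 1 else Ix[i - 1][0] + GAP_EXTEND
        qc = query[i - 1]
        Mi, Mp = M[i], M[i - 1]
        Ixi, Ixp = Ix[i], Ix[i - 1]
        Iyi = Iy[i]
        Smi, Smp = Sm[i], Sm[i - 1]
        Sxi, Sxp = Sx[i], Sx[i - 1]
        Syi = Sy[i]
        for j in range(1, m + 1):
            sub = MATCH if qc == window[j - 1] else MISMATCH
            # align query[i-1] to window[j-1]
            best, src = Mp[j - 1], Smp[j - 1]
            if Ixp[j - 1] > best:
                best, src = Ixp[j - 1], Sxp[j - 1]
            if Iy[i - 1][j - 1] > best:
                best, src = Iy[i - 1][j - 1], Sy[i - 1][j - 1]
            Mi[j] = best + sub
            Smi[j] = src
            # gap in window: consume query base without window base
            if Mp[j] + GAP_OPEN >= Ixp[j] + GAP_EXTEND:
                Ixi[j], Sxi[j] = Mp[j] + GAP_OPEN, Smp[j]
            else:
                Ixi[j], Sxi[j] = Ixp[j] + GAP_EXTEND, Sxp[j]
            # gap in query: consume window base without query base
            if Mi[j - 1] + GAP_OPEN >= Iyi[j - 1] + GAP_EXTEND:
                Iyi[j], Syi[j] = Mi[j - 1] + GAP_OPEN, Smi[j - 1]
            else:
                Iyi[j], Syi[j] = Iyi[j - 1] + GAP_EXTEND, Syi[j - 1]
    best_score, best_j, best_start = _NEG, 0, 0
    for j in range(m + 1):
        for row, srow in ((M, Sm), (Ix, Sx), (Iy, Sy)):
            if row[n][j] > best_score:
                best_score, best_j, best_start = row[n][j], j, srow[n][j]
    return best_score, best_start, best_j


def align_fragment(
    fragment: str,
    index: ReferenceIndex,
    params: AlignmentParams | None = None,
) -> GenomicRange | None:
    """Best unique local alignment of ``fragment`` against the reference.

    Returns the aligned range (strand '-' when the reverse complement
    matches) or ``None`` when no alignment meets the score threshold, the
    fragment is shorter than ``min_len``, or a second distinct location ties
    the best score (non-unique).
    """
    if not fragment:
        raise ValueError("empty fragment")
    if params is None:
        params = AlignmentParams()
    fragment = fragment.upper()
    n = len(fragment)
    if n < params.min_len:
        return None
    threshold = (1.0 - 2.0 * params.max_mismatch_rate) * n
    hits: dict[tuple[int, int, str], int] = {}
    for strand in "+-":
        query = fragment if strand == "+" else revcomp(fragment)
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        for offset in index.seed_offsets(query):
            score = _ungapped_score(index, qarr, offset)
            start, end = offset, offset + n
            if score is None or score < threshold:
                w0 = max(0, offset - params.band)
                w1 = min(len(index), offset + n + params.band)
                if w1 - w0 < 1:
                    continue
                score, s, e = _fit_align(query, index.sequence[w0:w1])
                start, end = w0 + s, w0 + e
            if score >= threshold and end > start:
                key = (start, end, strand)
                if score > hits.get(key, _NEG):
                    hits[key] = score
    if not hits:
        return None
    best = max(hits.values())
    winners = [k for k, v in hits.items() if v == best]
    if len(winners) > 1:
        return None
    start, end, strand = winners[0]
    return GenomicRange(index.ref_id, start, end, strand)


def attach_barcode(
    ranges: Sequence[GenomicRange],
    records: Sequence[ExtractionRecord],
) -> tuple[list[tuple[str, GenomicRange]], int]:
    """Join aligned ranges to extracted barcodes on ``read_id``.

    Returns ``(pairs, dropped)`` where each pair is
    ``(barcode sequence, range tagged with the read id)``; reads present on
    only one side are dropped and counted.  Duplicate read ids on either
    side are an error.
    """
    by_id: dict[str, GenomicRange] = {}
    for r in ranges:
        if r.read_id in by_id:
            raise ValueError(f"duplicate read_id in ranges: {r.read_id!r}")
        by_id[r.read_id] = r
    pairs: list[tuple[str, GenomicRange]] = []
    seen: set[str] = set()
    dropped = 0
    for rec in records:
        if rec.read_id in seen:
            raise ValueError(f"duplicate read_id in records: {rec.read_id!r}")
        seen.add(rec.read_id)
        rng_ = by_id.pop(rec.read_id, None)
        if rng_ is None or not rec.passed or rec.barcode is None:
            dropped += 1
            continue
        pairs.append((rec.barcode.sequence, rng_))
    dropped += len(by_id)  # ranges without a barcode-side record
    return pairs, dropped


def ranges_to_bed(ranges: Iterable[GenomicRange], path: str | Path) -> None:
    """Write ranges as BED6 (name = read id, score column unused)."""
    with open(path, "w") as fh:
        for r in ranges:
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")
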