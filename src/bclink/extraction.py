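"""Barcode and fragment recovery from paired reads by flank matching.

The barcode-side read has the layout ``5'-flank | barcode | 3'-flank``; the
constant flanks come from the vector backbone around the degenerate insert.
Extraction locates both flanks (substitution-tolerant, leftmost match wins),
takes the interval between them as the barcode, and applies the observed
length filter (default 18..22 nt) and an optional phred filter over the
barcode bases.  The fragment-side mate is trimmed of any constitutive flank
read-through but is never length-filtered.

Failures are recorded per read (``no_flank`` / ``length_filter`` /
``phred_filter``), counted, and never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .barcode import Barcode, BarcodeSpec, passes_length_filter
from .fragmentation import revcomp

__all__ = [
    "FailReason",
    "FlankDefinition",
    "ExtractionRecord",
    "find_approx",
    "extract_barcode",
    "phred_filter_barcode",
    "extract_fragment",
    "extract_read_pairs",
]

#: Default stand-ins for the vector's constant regions flanking the barcode.
DEFAULT_FLANK5 = "ACGCTCTTCCGA"
DEFAULT_FLANK3 = "AGATCGGTGCGT"


class FailReason(str, Enum):
    NONE = "none"
    NO_FLANK = "no_flank"
    LENGTH_FILTER = "length_filter"
    PHRED_FILTER = "phred_filter"


@dataclass(frozen=True)
class FlankDefinition:
    """Constant sequences flanking the barcode and the matching tolerance.

    ``max_mismatch`` substitutions are allowed per flank (indel-tolerant flank
    matching is deliberately not attempted: the flanks are short and indels
    inside them are rare compared to substitutions).  ``search_window``
    optionally restricts how far into the read the 5' flank may start.
    """

    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    max_mismatch: int = 1
    search_window: int | None = None

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class ExtractionRecord:
    """Outcome of extracting one read pair."""

    read_id: str
    barcode: Barcode | None = None
    fragment_seq: str | None = None
    fail_reason: FailReason = FailReason.NONE

    @property
    def passed(self) -> bool:
        return self.fail_reason is FailReason.NONE


def find_approx(
    haystack: str,
    needle: str,
    max_mismatch: int = 0,
    start: int = 0,
    end: int | None = None,
) -> int:
    """Leftmost offset where ``needle`` matches with <= ``max_mismatch``
    substitutions, or -1.  ``end`` bounds the allowed *start* offset.
    """
    n = len(needle)
    last = len(haystack) - n
    if end is not None:
        last = min(last, end)
    if last < start:
        return -1
    exact = haystack.find(needle, start, last + n)
    if max_mismatch == 0 or exact == start:
        return exact
    if exact != -1:
        last = exact  # an earlier approximate hit could still win
    hay = np.frombuffer(haystack.encode(), dtype=np.uint8)
    ned = np.frombuffer(needle.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(hay, n)[start : last + 1]
    mism = (windows != ned).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatch)
    return int(hits[0]) + start if hits.size else -1


def extract_barcode(
    seq: str,
    qualities: Sequence[int] | None,
    flanks: FlankDefinition,
    spec: BarcodeSpec,
    read_id: str = "",
) -> ExtractionRecord:
    """Locate the barcode between the two flanks of a barcode-side read.

    The 5' flank is searched first (leftmost match, optionally within
    ``search_window``), then the 3' flank downstream of it.  The interval
    between the two flank matches is the barcode; the observed-length filter
    is applied.  Failures are recorded, not raised.
    """
    rec = ExtractionRecord(read_id=read_id)
    p5 = find_approx(seq, flanks.flank5, flanks.max_mismatch,
                     end=flanks.search_window)
    if p5 < 0:
        rec.fail_reason = FailReason.NO_FLANK
        return rec
    bc_start = p5 + len(flanks.flank5)
    p3 = find_approx(seq, flanks.flank3, flanks.max_mismatch, start=bc_start)
    if p3 < 0:
        rec.fail_reason = FailReason.NO_FLANK
        return rec
    bc_seq = seq[bc_start:p3]
    if not passes_length_filter(bc_seq, spec) or not bc_seq:
        rec.fail_reason = FailReason.LENGTH_FILTER
        return rec
    quals = list(qualities[bc_start:p3]) if qualities is not None else None
    rec.barcode = Barcode(bc_seq, quals)
    return rec


def phred_filter_barcode(
    rec: ExtractionRecord, min_phred: int, mode: str = "min"
) -> ExtractionRecord:
    """Fail the record if its barcode quality falls below ``min_phred``.

    ``mode='min'`` (default) requires every barcode base to reach the
    threshold -- the strict reading of filtering "inside the barcode
    region"; ``mode='mean'`` applies the threshold to the mean quality.
    ``min_phred=0`` disables the filter.  Records that already failed pass
    through unchanged.
    """
    if min_phred == 0 or not rec.passed or rec.barcode is None:
        return rec
    if rec.barcode.qualities is None:
        raise ValueError("phred filtering requested but barcode has no qualities")
    quals = np.asarray(rec.barcode.qualities)
    stat = quals.min() if mode == "min" else quals.mean()
    if stat < min_phred:
        return replace(rec, barcode=None, fail_reason=FailReason.PHRED_FILTER)
    return rec


def extract_fragment(seq: str, flanks: FlankDefinition) -> str:
    """Trim constitutive flank read-through off a fragment-side read.

    Any detected occurrence (either flank, either orientation) truncates the
    read from that point on; no length restriction is applied.
    """
    candidates = (
        flanks.flank3,
        flanks.flank5,
        revcomp(flanks.flank5),
        revcomp(flanks.flank3),
    )
    cut = len(seq)
    for cand in candidates:
        pos = find_approx(seq, cand, flanks.max_mismatch)
        if 0 <= pos < cut:
            cut = pos
    return seq[:cut]


def extract_read_pairs(
    pairs: Iterable[tuple[str, str, Sequence[int] | None, str, Sequence[int] | None]],
    flanks: FlankDefinition,
    spec: BarcodeSpec,
    min_phred: int = 0,
    phred_mode: str = "min",
) -> tuple[list[ExtractionRecord], Counter]:
    """Extract every ``(read_id, seq1, qual1, seq2, qual2)`` pair.

    Returns the records (one per pair, in input order; fragment attached only
    to passing records) and a tally of fail reasons.
    """
    records: list[ExtractionRecord] = []
    tally: Counter = Counter()
    for read_id, seq1, qual1, seq2, _qual2 in pairs:
        rec = extract_barcode(seq1, qual1, flanks, spec, read_id=read_id)
        rec = phred_filter_barcode(rec, min_phred, mode=phred_mode)
        if rec.passed:
            rec.fragment_seq = extract_fragment(seq2, flanks)
        tally[rec.fail_reason.value] += 1
        records.append(rec)
    return records, tally
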