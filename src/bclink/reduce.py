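"""Per-barcode consensus and the purity parameter: the lookup table.

Reads are grouped by exact barcode sequence; single-read barcodes
(singlets) are set aside, since a fraction cannot be formed from one read.
Within each multi-read group, identical aligned ranges (same start, end,
strand) are counted and the most abundant range is the consensus.  Reads
whose range is not identical but falls within +/- ``tol_bp`` (default 20)
of the consensus on *both* endpoints, on the same strand, are accepted as
the same fragment (read-end wobble), and

    purity = (consensus + tolerated reads) / (all reads of the barcode).

Purity is 1 exactly when every read of a barcode points at one fragment; it
decays towards 0 as chimeras, heterodimers or false clustering attach the
barcode to multiple fragments.  The mapping barcode -> consensus range (with
purity) is the library's lookup table.

Tie-breaks (deterministic): equal range counts are resolved to the
lexicographically smallest ``(ref_id, start, end, strand)``; strand is part
of fragment identity throughout, so opposite-strand reads never count
toward a consensus.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import GenomicRange

__all__ = [
    "BarcodeGroup",
    "ConsensusRecord",
    "LookupTable",
    "group_by_barcode",
    "split_singlets",
    "consensus_and_purity",
    "build_lookup_table",
    "purity_distribution",
]


@dataclass
class BarcodeGroup:
    """All aligned ranges observed for one barcode sequence."""

    barcode: str
    ranges: list[GenomicRange]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("empty barcode group")

    def __len__(self) -> int:
        return len(self.ranges)


@dataclass(frozen=True)
class ConsensusRecord:
    """One lookup-table row: barcode -> consensus fragment with purity."""

    barcode: str
    consensus: GenomicRange
    consensus_count: int
    total_count: int
    purity: float

    def __post_init__(self) -> None:
        if not (1 <= self.consensus_count <= self.total_count):
            raise ValueError("need 1 <= consensus_count <= total_count")


def group_by_barcode(
    pairs: Iterable[tuple[str, GenomicRange]]
) -> list[BarcodeGroup]:
    """One group per distinct barcode (upper-cased); ranges conserved.

    Output is sorted by barcode sequence for determinism.
    """
    buckets: dict[str, list[GenomicRange]] = defaultdict(list)
    for barcode, rng in pairs:
        buckets[barcode.upper()].append(rng)
    return [BarcodeGroup(bc, buckets[bc]) for bc in sorted(buckets)]


def split_singlets(
    groups: Sequence[BarcodeGroup],
) -> tuple[list[BarcodeGroup], list[BarcodeGroup]]:
    """Partition into (singlets, multis) by group size == 1.

    Singlets are reported but excluded from purity distributions: a purity
    cannot be determined from one read (and single-read barcodes are most
    often sequencing errors of a real barcode).
    """
    singlets = [g for g in groups if len(g) == 1]
    multis = [g for g in groups if len(g) > 1]
    return singlets, multis


def consensus_and_purity(group: BarcodeGroup, tol_bp: int = 20) -> ConsensusRecord:
    """Consensus range and purity for a multi-read barcode group."""
    if len(group) < 2:
        raise ValueError("purity is undefined for a singlet group")
    counts = Counter(r.key for r in group.ranges)
    # highest count, then lexicographically smallest identity
    consensus_key = min(counts, key=lambda k: (-counts[k], k))
    ref_id, start, end, strand = consensus_key
    consensus_count = 0
    for (kref, kstart, kend, kstrand), c in counts.items():
        if (
            kref == ref_id
            and kstrand == strand
            and abs(kstart - start) <= tol_bp
            and abs(kend - end) <= tol_bp
        ):
            consensus_count += c
    total = len(group)
    return ConsensusRecord(
        barcode=group.barcode,
        consensus=GenomicRange(ref_id, start, end, strand),
        consensus_count=consensus_count,
        total_count=total,
        purity=consensus_count / total,
    )


class LookupTable:
    """Keyed table barcode -> :class:`ConsensusRecord`, with run metadata."""

    def __init__(
        self,
        records: Iterable[ConsensusRecord] = (),
        metadata: Mapping | None = None,
    ) -> None:
        self._records: dict[str, ConsensusRecord] = {}
        self.metadata: dict = dict(metadata or {})
        for rec in records:
            if rec.barcode in self._records:
                raise ValueError(f"duplicate barcode key {rec.barcode!r}")
            self._records[rec.barcode] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._records

    def __getitem__(self, barcode: str) -> ConsensusRecord:
        return self._records[barcode]

    def __iter__(self):
        return iter(self._records)

    def records(self) -> list[ConsensusRecord]:
        return [self._records[b] for b in sorted(self._records)]

    def purities(self) -> np.ndarray:
        return np.array([r.purity for r in self.records()], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "barcode": r.barcode,
                "ref_id": r.consensus.ref_id,
                "start": r.consensus.start,
                "end": r.consensus.end,
                "strand": r.consensus.strand,
                "consensus_count": r.consensus_count,
                "total_count": r.total_count,
                "purity": r.purity,
            }
            for r in self.records()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "barcode", "ref_id", "start", "end", "strand",
                "consensus_count", "total_count", "purity",
            ],
        )

    def to_tsv(self, path: str | Path, metadata_path: str | Path | None = None
               ) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata, fh, indent=2, sort_keys=True)
                fh.write("\n")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 metadata_path: str | Path | None = None) -> "LookupTable":
        df = pd.read_csv(path, sep="\t")
        records = [
            ConsensusRecord(
                barcode=str(row.barcode),
                consensus=GenomicRange(
                    str(row.ref_id), int(row.start), int(row.end), str(row.strand)
                ),
                consensus_count=int(row.consensus_count),
                total_count=int(row.total_count),
                purity=float(row.purity),
            )
            for row in df.itertuples()
        ]
        metadata = None
        if metadata_path is not None:
            with open(metadata_path) as fh:
                metadata = json.load(fh)
        return cls(records, metadata)


def build_lookup_table(
    records: Iterable[ConsensusRecord],
    singlet_count: int = 0,
    metadata: Mapping | None = None,
) -> LookupTable:
    """Assemble the lookup table; singlet tally is carried as metadata."""
    meta = dict(metadata or {})
    meta.setdefault("singlet_count", singlet_count)
    return LookupTable(records, meta)


def purity_distribution(table: LookupTable | Sequence[ConsensusRecord]) -> dict:
    """Descriptive summary of the purity distribution over barcodes.

    Histogram uses 101 fixed bins on [0, 1] (beanplot-style reporting).
    """
    purities = (
        table.purities()
        if isinstance(table, LookupTable)
        else np.array([r.purity for r in table], dtype=float)
    )
    if purities.size == 0:
        raise ValueError("empty lookup table")
    hist, edges = np.histogram(purities, bins=101, range=(0.0, 1.0))
    q = np.quantile(purities, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "n": int(purities.size),
        "mean": float(purities.mean()),
        "min": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "max": float(q[4]),
        "hist_counts": hist.tolist(),
        "hist_edges": edges.tolist(),
    }
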