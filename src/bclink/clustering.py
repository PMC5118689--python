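"""Barcode clustering by Levenshtein distance, and its purity validation.

Sequencing errors inflate the apparent number of unique barcodes far beyond
the physical clone count, so barcode counting requires clustering reads
back onto true barcodes.  Two algorithms are implemented:

* **sphere clustering** -- sequences sorted by count; scanning downward,
  each unclaimed sequence becomes a centroid unless a strictly
  higher-count centroid lies within the Levenshtein radius, in which case
  the nearest such centroid claims it.  A sequence at equal minimal
  distance to two centroids at the moment of claiming is ambiguous and
  discarded.
* **message passing** -- each sequence passes its count to its nearest
  strictly-higher-count neighbour within the radius; transfers chain until
  they reach a root, and the surviving roots are the cluster centroids.
  Among equal-distance candidate parents the higher count wins; a residual
  tie (equal distance *and* equal count between distinct parents) discards
  the sequence, as does descending from a discarded parent.

Both algorithms are deterministic: input is canonically sorted by
(count desc, sequence asc) before processing.  Pairwise distances go
through :func:`levenshtein` (capped edit distance); candidate pairs are
prefiltered with a pigeonhole chunk index so all-pairs comparison is never
materialised on large inputs.

Validation: relabel every read by its barcode's cluster centroid, re-run
the purity reduction, and read false merges directly off the purity
distribution -- two truly distinct barcodes merged into one cluster point
at different fragments and drag purity below 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import GenomicRange
from .reduce import (
    LookupTable,
    build_lookup_table,
    consensus_and_purity,
    group_by_barcode,
    purity_distribution,
    split_singlets,
)

try:  # fast C edit distance; pure-Python DP below is the fallback
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None

__all__ = [
    "BarcodeCount",
    "BarcodeCluster",
    "ClusteringResult",
    "ClusteringConfig",
    "levenshtein",
    "sphere_cluster",
    "message_passing_cluster",
    "cluster",
    "validate_clustering",
    "subsample_reads",
    "library_overlap",
    "cluster_sweep",
]


@dataclass(frozen=True)
class BarcodeCount:
    """A unique barcode sequence and its read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class BarcodeCluster:
    """A cluster of barcode sequences claimed by one centroid."""

    centroid: str
    members: list[BarcodeCount]
    total_count: int


@dataclass
class ClusteringResult:
    """Clusters plus the sequences discarded as ambiguous ties."""

    clusters: list[BarcodeCluster]
    discarded: list[BarcodeCount]

    def assignment(self) -> dict[str, str]:
        """Map member sequence -> centroid sequence."""
        out: dict[str, str] = {}
        for cl in self.clusters:
            for m in cl.members:
                out[m.sequence] = cl.centroid
        return out

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class ClusteringConfig:
    """Algorithm choice and the Levenshtein radius."""

    algorithm: str = "message_passing"
    max_dist: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("sphere", "message_passing"):
            raise ValueError("algorithm must be 'sphere' or 'message_passing'")
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")


def _levenshtein_dp(a: str, b: str, cap: int) -> int:
    """Banded unit-cost edit distance, early exit above ``cap``."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if abs(la - lb) > cap:
        return cap + 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    prev = list(range(la + 1))
    for j in range(1, lb + 1):
        lo = max(1, j - cap)
        hi = min(la, j + cap)
        cur = [cap + 1] * (la + 1)
        if lo == 1:
            cur[0] = j if j <= cap else cap + 1
        bj = b[j - 1]
        row_min = cur[0] if lo == 1 else cap + 1
        for i in range(lo, hi + 1):
            c = min(
                prev[i] + 1,
                cur[i - 1] + 1,
                prev[i - 1] + (a[i - 1] != bj),
            )
            cur[i] = c if c <= cap else cap + 1
            if cur[i] < row_min:
                row_min = cur[i]
        if row_min > cap:
            return cap + 1
        prev = cur
    return prev[la] if prev[la] <= cap else cap + 1


def levenshtein(a: str, b: str, cap: int) -> int:
    """Unit-cost edit distance, returning ``cap + 1`` whenever it exceeds
    ``cap`` (the caller only needs 'within radius or not, and how far')."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if a == b:
        return 0
    if _edlib is not None:
        d = _edlib.align(a, b, task="distance", k=cap)["editDistance"]
        # some edlib builds treat k <= 0 as "no limit"; clamp defensively
        return d if 0 <= d <= cap else cap + 1
    return _levenshtein_dp(a, b, cap)


def _canonical_order(counts: Sequence[BarcodeCount]) -> list[BarcodeCount]:
    seqs = [c.sequence for c in counts]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate sequences in barcode count input")
    return sorted(counts, key=lambda c: (-c.count, c.sequence))


class _ChunkIndex:
    """Pigeonhole prefilter for capped Levenshtein neighbour queries.

    Every sequence is split into ``d+1`` disjoint chunks of fixed length
    ``q``; if two sequences are within edit distance ``d``, at least one
    chunk of the query survives unedited and occurs in the other sequence
    within ``d`` positions of its own slot, so indexing each sequence's
    chunks at slot starts shifted by -d..d guarantees a shared key for
    every true neighbour pair.  Candidates are then verified exactly.

    For small inputs (or degenerate chunk sizes) the index degrades to
    brute force, which is exact by construction.
    """

    BRUTE_LIMIT = 512

    def __init__(self, max_dist: int, min_seq_len: int, n_total: int) -> None:
        self.d = max_dist
        self.q = min_seq_len // (max_dist + 1) if max_dist >= 0 else 0
        self.brute = n_total <= self.BRUTE_LIMIT or self.q < 2
        self._buckets: dict[tuple[int, str], list[int]] = defaultdict(list)
        self._all: list[int] = []
        self._seqs: list[str] = []

    def add(self, idx: int, seq: str) -> None:
        self._all.append(idx)
        self._seqs.append(seq)
        if self.brute:
            return
        q, d = self.q, self.d
        for slot in range(d + 1):
            base = slot * q
            for shift in range(-d, d + 1):
                s = base + shift
                if 0 <= s and s + q <= len(seq):
                    self._buckets[(slot, seq[s : s + q])].append(idx)

    def candidates(self, seq: str) -> list[int]:
        if self.brute:
            return self._all
        q, d = self.q, self.d
        out: set[int] = set()
        for slot in range(d + 1):
            base = slot * q
            if base + q <= len(seq):
                out.update(self._buckets.get((slot, seq[base : base + q]), ()))
        return list(out)


def _min_len(counts: Sequence[BarcodeCount]) -> int:
    return min((len(c.sequence) for c in counts), default=0)


def sphere_cluster(
    counts: Sequence[BarcodeCount], cfg: ClusteringConfig
) -> ClusteringResult:
    """Greedy fixed-radius clustering in descending count order."""
    if cfg.algorithm != "sphere":
        raise ValueError("config.algorithm must be 'sphere'")
    entries = _canonical_order(counts)
    d = cfg.max_dist
    index = _ChunkIndex(d, _min_len(entries), len(entries))
    centroids: list[BarcodeCluster] = []
    centroid_of: list[BarcodeCluster] = []  # parallel to index insertion
    discarded: list[BarcodeCount] = []
    for e in entries:
        best_d = d + 1
        best: list[BarcodeCluster] = []
        if d > 0:
            for ci in index.candidates(e.sequence):
                cl = centroid_of[ci]
                # claims require strictly greater count than the claimed
                if cl.members[0].count <= e.count:
                    continue
                dist = levenshtein(e.sequence, cl.centroid, d)
                if dist > d:
                    continue
                if dist < best_d:
                    best_d, best = dist, [cl]
                elif dist == best_d:
                    best.append(cl)
        if len(best) == 1:
            best[0].members.append(e)
            best[0].total_count += e.count
        elif len(best) > 1:
            discarded.append(e)
        else:
            cl = BarcodeCluster(centroid=e.sequence, members=[e],
                                total_count=e.count)
            centroids.append(cl)
            index.add(len(centroid_of), e.sequence)
            centroid_of.append(cl)
    return ClusteringResult(clusters=centroids, discarded=discarded)


def message_passing_cluster(
    counts: Sequence[BarcodeCount], cfg: ClusteringConfig
) -> ClusteringResult:
    """Count transfer to the nearest strictly-higher-count neighbour."""
    if cfg.algorithm != "message_passing":
        raise ValueError("config.algorithm must be 'message_passing'")
    entries = _canonical_order(counts)
    d = cfg.max_dist
    index = _ChunkIndex(d, _min_len(entries), len(entries))
    parent = [-1] * len(entries)       # index of parent entry, -1 = root
    ambiguous = [False] * len(entries)
    for i, e in enumerate(entries):
        if d > 0:
            best_d = d + 1
            best_count = -1
            best_idx: list[int] = []
            for ci in index.candidates(e.sequence):
                other = entries[ci]
                if other.count <= e.count:
                    continue
                dist = levenshtein(e.sequence, other.sequence, d)
                if dist > d:
                    continue
                if dist < best_d or (dist == best_d and other.count > best_count):
                    best_d, best_count, best_idx = dist, other.count, [ci]
                elif dist == best_d and other.count == best_count:
                    best_idx.append(ci)
            if len(best_idx) == 1:
                parent[i] = best_idx[0]
            elif len(best_idx) > 1:
                ambiguous[i] = True
        index.add(i, e.sequence)
    # resolve roots; anything below an ambiguous node is unassignable too
    root = [-2] * len(entries)

    def _root(i: int) -> int:
        chain = []
        while root[i] == -2:
            if ambiguous[i]:
                root[i] = -1
                break
            if parent[i] == -1:
                root[i] = i
                break
            chain.append(i)
            i = parent[i]
        r = root[i]
        for j in chain:
            root[j] = r
        return r

    clusters: dict[int, BarcodeCluster] = {}
    discarded: list[BarcodeCount] = []
    for i, e in enumerate(entries):
        r = _root(i)
        if r == -1:
            discarded.append(e)
            continue
        cl = clusters.get(r)
        if cl is None:
            cl = clusters[r] = BarcodeCluster(
                centroid=entries[r].sequence, members=[], total_count=0
            )
        cl.members.append(e)
        cl.total_count += e.count
    ordered = [clusters[r] for r in sorted(clusters)]
    return ClusteringResult(clusters=ordered, discarded=discarded)


def cluster(
    counts: Sequence[BarcodeCount], cfg: ClusteringConfig
) -> ClusteringResult:
    """Dispatch on ``cfg.algorithm``."""
    if cfg.algorithm == "sphere":
        return sphere_cluster(counts, cfg)
    return message_passing_cluster(counts, cfg)


def counts_from_pairs(
    pairs: Iterable[tuple[str, GenomicRange]]
) -> list[BarcodeCount]:
    """Tally unique barcode sequences over (barcode, range) read pairs."""
    tally: dict[str, int] = defaultdict(int)
    for bc, _ in pairs:
        tally[bc.upper()] += 1
    return [BarcodeCount(s, c) for s, c in sorted(tally.items())]


def validate_clustering(
    result: ClusteringResult,
    pairs: Sequence[tuple[str, GenomicRange]],
    tol_bp: int = 20,
) -> tuple[LookupTable, dict]:
    """Post-clustering purity readout.

    Relabels every read's barcode by its cluster centroid (reads of
    discarded barcodes are dropped), re-runs the consensus/purity
    reduction, and returns the post-cluster lookup table plus its purity
    summary.  False merges surface as purity < 1.
    """
    assignment = result.assignment()
    relabelled = [
        (assignment[bc.upper()], rng)
        for bc, rng in pairs
        if bc.upper() in assignment
    ]
    groups = group_by_barcode(relabelled)
    singlets, multis = split_singlets(groups)
    records = [consensus_and_purity(g, tol_bp=tol_bp) for g in multis]
    table = build_lookup_table(
        records,
        singlet_count=len(singlets),
        metadata={"dropped_reads": len(pairs) - len(relabelled)},
    )
    summary = purity_distribution(records) if records else {"n": 0}
    return table, summary


def subsample_reads(
    pairs: Sequence[tuple[str, GenomicRange]],
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, GenomicRange]]:
    """Bernoulli thinning of reads, emulating reduced sequencing depth."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(pairs)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]


def library_overlap(
    table_a: LookupTable, table_b: LookupTable
) -> tuple[int, float]:
    """Barcode-key intersection of two libraries and its count correlation.

    Returns ``(n_shared, pearson_r)``; the correlation is NaN when fewer
    than three barcodes are shared.  Truly independent libraries drawn from
    the (VHDB)x5 space share essentially nothing (expected overlap
    n^2 / 3^20), so any sizeable overlap flags cross-contamination.
    """
    shared = sorted(set(table_a) & set(table_b))
    if len(shared) < 3:
        return len(shared), float("nan")
    a = np.array([table_a[b].total_count for b in shared], dtype=float)
    b = np.array([table_b[b].total_count for b in shared], dtype=float)
    if a.std() == 0 or b.std() == 0:
        return len(shared), float("nan")
    return len(shared), float(np.corrcoef(a, b)[0, 1])


def cluster_sweep(
    pairs: Sequence[tuple[str, GenomicRange]],
    algorithms: Sequence[str] = ("sphere", "message_passing"),
    max_dists: Sequence[int] = (0, 1, 2, 3, 4),
    depth_fractions: Sequence[float] = (1.0,),
    tol_bp: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Machine-readable sweep over (algorithm, radius, depth fraction).

    One row per condition with the unique-cluster count, discarded fraction
    and purity quantiles -- the tabular analogue of threshold-sweep plots.
    """
    rows = []
    for frac in depth_fractions:
        sub = subsample_reads(pairs, frac, seed=seed)
        counts = counts_from_pairs(sub)
        total = sum(c.count for c in counts)
        for algo in algorithms:
            for d in max_dists:
                cfg = ClusteringConfig(algorithm=algo, max_dist=d, seed=seed)
                res = cluster(counts, cfg)
                _, summary = validate_clustering(res, sub, tol_bp=tol_bp)
                rows.append({
                    "algorithm": algo,
                    "max_dist": d,
                    "depth_fraction": frac,
                    "n_reads": total,
                    "n_unique": len(counts),
                    "n_clusters": res.n_clusters,
                    "discarded_fraction":
                        sum(c.count for c in res.discarded) / max(total, 1),
                    "purity_mean": summary.get("mean", float("nan")),
                    "purity_median": summary.get("median", float("nan")),
                    "purity_q25": summary.get("q25", float("nan")),
                })
    return pd.DataFrame(rows)
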