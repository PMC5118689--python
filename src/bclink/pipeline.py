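"""End-to-end assessment workflow: reads -> lookup table -> reports.

Stages: extraction (flank matching + filters) -> alignment (unique valid
alignments only) -> barcode join -> reduction (consensus + purity), with
optional barcode clustering and its purity validation.  Stage counters are
conserved (reads in = passed + failed-by-reason) and logged as one JSON
line per stage; outputs embed the config hash and seed so identical runs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentParams, GenomicRange, ReferenceIndex, align_fragment
from .barcode import BarcodeSpec
from .clustering import (
    ClusteringConfig,
    cluster,
    counts_from_pairs,
    validate_clustering,
)
from .extraction import FailReason, FlankDefinition, extract_read_pairs
from .reduce import (
    LookupTable,
    build_lookup_table,
    consensus_and_purity,
    group_by_barcode,
    purity_distribution,
    split_singlets,
)
from .simulate import LibraryTruth

logger = logging.getLogger("bclink")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "assess_read_pairs",
    "run_pipeline",
    "report",
    "write_report",
    "config_hash",
]


@dataclass
class PipelineConfig:
    """Everything one assessment run needs; hashable for provenance."""

    fastq1: str = ""
    fastq2: str = ""
    reference_fasta: str = ""
    output_dir: str = "."
    spec: BarcodeSpec = field(default_factory=BarcodeSpec)
    flanks: FlankDefinition = field(default_factory=FlankDefinition)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    tol_bp: int = 20
    min_phred: int = 0
    clustering: ClusteringConfig | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            return x
        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the analysis configuration (provenance stamp).

    The output directory is excluded: it locates results but does not
    affect them, and runs of one config into two directories must still be
    recognisably identical.
    """
    d = cfg.to_dict()
    d.pop("output_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log_stage(stage: str, **counters) -> None:
    logger.info(json.dumps({"stage": stage, **counters}, sort_keys=True))


@dataclass
class PipelineResult:
    table: LookupTable
    counters: dict
    purity_summary: dict
    post_cluster_table: LookupTable | None = None
    post_cluster_summary: dict | None = None
    pairs: list[tuple[str, GenomicRange]] = field(default_factory=list)


def assess_read_pairs(
    read_pairs: Iterable[tuple[str, str, Sequence[int] | None, str, Sequence[int] | None]],
    reference_id: str,
    reference_seq: str,
    spec: BarcodeSpec | None = None,
    flanks: FlankDefinition | None = None,
    aln: AlignmentParams | None = None,
    tol_bp: int = 20,
    min_phred: int = 0,
    clustering: ClusteringConfig | None = None,
) -> PipelineResult:
    """In-memory assessment of ``(read_id, seq1, qual1, seq2, qual2)`` pairs.

    This is the library entry point the file-based pipeline and the CLI
    wrap; it returns the lookup table, conserved stage counters, and the
    purity summary (plus post-clustering versions when requested).
    """
    spec = spec or BarcodeSpec()
    flanks = flanks or FlankDefinition()
    aln = aln or AlignmentParams()

    records, tally = extract_read_pairs(read_pairs, flanks, spec,
                                        min_phred=min_phred)
    n_in = len(records)
    _log_stage("extract", reads_in=n_in, **{k: v for k, v in sorted(tally.items())})

    index = ReferenceIndex(reference_id, reference_seq)
    pairs: list[tuple[str, GenomicRange]] = []
    n_unaligned = 0
    for rec in records:
        if not rec.passed or rec.barcode is None or not rec.fragment_seq:
            continue
        rng = align_fragment(rec.fragment_seq, index, aln)
        if rng is None:
            n_unaligned += 1
            continue
        pairs.append(
            (rec.barcode.sequence,
             dataclasses.replace(rng, read_id=rec.read_id))
        )
    _log_stage("align", candidates=tally.get("none", 0),
               aligned=len(pairs), unaligned=n_unaligned)

    groups = group_by_barcode(pairs)
    singlets, multis = split_singlets(groups)
    consensus = [consensus_and_purity(g, tol_bp=tol_bp) for g in multis]
    table = build_lookup_table(consensus, singlet_count=len(singlets))
    summary = purity_distribution(consensus) if consensus else {"n": 0}
    counters = {
        "reads_in": n_in,
        "extraction_failed": {
            k: v for k, v in sorted(tally.items()) if k != FailReason.NONE.value
        },
        "extraction_passed": tally.get(FailReason.NONE.value, 0),
        "unaligned": n_unaligned,
        "joined": len(pairs),
        "singlets": len(singlets),
        "multis": len(multis),
    }
    _log_stage("reduce", singlets=len(singlets), multis=len(multis))

    result = PipelineResult(table=table, counters=counters,
                            purity_summary=summary, pairs=pairs)
    if clustering is not None:
        counts = counts_from_pairs(pairs)
        res = cluster(counts, clustering)
        post_table, post_summary = validate_clustering(res, pairs, tol_bp=tol_bp)
        result.post_cluster_table = post_table
        result.post_cluster_summary = post_summary
        _log_stage("cluster", algorithm=clustering.algorithm,
                   max_dist=clustering.max_dist, n_unique=len(counts),
                   n_clusters=res.n_clusters, discarded=len(res.discarded))
    return result


def _read_fastq(path: str | Path):
    from Bio import SeqIO
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def _read_reference(path: str | Path) -> tuple[str, str]:
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def _paired_reads(fastq1: str | Path, fastq2: str | Path):
    for (id1, s1, q1), (id2, s2, q2) in zip(
        _read_fastq(fastq1), _read_fastq(fastq2), strict=True
    ):
        rid = id1.rsplit("/", 1)[0]
        if rid != id2.rsplit("/", 1)[0]:
            raise ValueError(f"unpaired reads: {id1!r} vs {id2!r}")
        yield rid, s1, q1, s2, q2


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based pipeline: FASTQ pair + reference FASTA -> lookup table TSV,
    metadata JSON, and report bundle in ``cfg.output_dir``."""
    for p in (cfg.fastq1, cfg.fastq2, cfg.reference_fasta):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    ref_id, ref_seq = _read_reference(cfg.reference_fasta)
    result = assess_read_pairs(
        list(_paired_reads(cfg.fastq1, cfg.fastq2)),
        ref_id, ref_seq,
        spec=cfg.spec, flanks=cfg.flanks, aln=cfg.alignment,
        tol_bp=cfg.tol_bp, min_phred=cfg.min_phred, clustering=cfg.clustering,
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(cfg), "seed": cfg.seed,
             "config": cfg.to_dict()}
    result.table.metadata.update(stamp)
    result.table.metadata["counters"] = result.counters
    result.table.to_tsv(outdir / "lookup_table.tsv",
                        outdir / "lookup_table.meta.json")
    write_report(result.table, outdir, ref_len=len(ref_seq), stamp=stamp)
    if result.post_cluster_table is not None:
        result.post_cluster_table.metadata.update(stamp)
        result.post_cluster_table.to_tsv(
            outdir / "lookup_table.clustered.tsv",
            outdir / "lookup_table.clustered.meta.json",
        )
    return result


def report(table: LookupTable, truth: LibraryTruth | None = None,
           ref_len: int | None = None) -> dict:
    """Report bundle for a lookup table (plus truth confusion when known).

    Contents: barcode read-count histogram, consensus fragment-length
    histogram, per-base coverage of consensus fragments, orientation tally
    with a two-sided binomial test, and the purity summary.  With ``truth``
    supplied, adds confusion counts: barcodes whose consensus matches their
    true fragment (correct), mismatches (chimeric), and truth barcodes
    absent from the table (lost).
    """
    from scipy import stats

    records = table.records()
    if not records:
        raise ValueError("empty lookup table")
    count_hist = Counter(r.total_count for r in records)
    length_hist = Counter(r.consensus.end - r.consensus.start for r in records)
    n_plus = sum(1 for r in records if r.consensus.strand == "+")
    n_minus = len(records) - n_plus
    orient_p = float(stats.binomtest(n_plus, len(records), 0.5).pvalue)
    L = ref_len or max(r.consensus.end for r in records)
    coverage = np.zeros(L, dtype=np.int64)
    for r in records:
        coverage[r.consensus.start : r.consensus.end] += 1
    out = {
        "n_barcodes": len(records),
        "singlet_count": table.metadata.get("singlet_count", 0),
        "barcode_count_hist": dict(sorted(count_hist.items())),
        "fragment_length_hist": dict(sorted(length_hist.items())),
        "orientation": {"plus": n_plus, "minus": n_minus,
                        "binom_pvalue": orient_p},
        "coverage": coverage,
        "purity": purity_distribution(table),
    }
    if truth is not None:
        by_barcode = {c.barcode: c for c in truth.clones}
        correct = chimeric = 0
        for r in records:
            c = by_barcode.get(r.barcode)
            if c is None:
                continue
            same = (
                r.consensus.start == c.fragment.source_start
                and r.consensus.end == c.fragment.source_end
                and r.consensus.strand == c.orientation
            )
            correct += same
            chimeric += not same
        lost = len(by_barcode) - sum(1 for b in by_barcode if b in table)
        out["confusion"] = {"correct": correct, "chimeric": chimeric,
                            "lost": lost}
    return out


def write_report(table: LookupTable, outdir: str | Path,
                 truth: LibraryTruth | None = None,
                 ref_len: int | None = None, stamp: dict | None = None) -> dict:
    """Write the report bundle as TSV/JSON/bedGraph files; returns it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep = report(table, truth=truth, ref_len=ref_len)
    pd.Series(rep["barcode_count_hist"], name="n_barcodes").rename_axis(
        "read_count").to_csv(outdir / "barcode_count_hist.tsv", sep="\t")
    pd.Series(rep["fragment_length_hist"], name="n_barcodes").rename_axis(
        "fragment_length").to_csv(outdir / "fragment_length_hist.tsv", sep="\t")
    cov = rep["coverage"]
    ref_id = table.records()[0].consensus.ref_id
    with open(outdir / "coverage.bedgraph", "w") as fh:
        start = 0
        for i in range(1, len(cov) + 1):
            if i == len(cov) or cov[i] != cov[start]:
                fh.write(f"{ref_id}\t{start}\t{i}\t{int(cov[start])}\n")
                start = i
    summary = {k: rep[k] for k in
               ("n_barcodes", "singlet_count", "orientation", "purity")}
    if "confusion" in rep:
        summary["confusion"] = rep["confusion"]
    if stamp:
        summary["config_hash"] = stamp.get("config_hash")
        summary["seed"] = stamp.get("seed")
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return rep
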