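"""Synthetic barcoded plasmid library and paired-end read generator.

Builds a ground-truthed library (one unique barcode per clone, a genomic
fragment in a random insertion orientation) and emits paired reads: read 1
carries ``5'-flank | barcode | 3'-flank``, read 2 the fragment in its
insertion orientation.  Per-clone read counts are Poisson with optional
singlet inflation (extra one-read barcodes bearing a sequencing error, as
seen in real barcode-count histograms).  Two distinct chimera mechanisms are
modelled, because real libraries separate them experimentally:

* plasmid-level heterodimers (:func:`inject_heterodimers`) -- a re-ligation
  artefact that re-pairs a clone's barcode with another clone's fragment
  *before* any sequencing, and
* read-level template switching (``chimera_rate``) -- a PCR artefact that
  links a read's fragment to the barcode of a different clone; compartmental
  (emulsion) PCR is represented simply as a lower rate.

Every read carries truth tags (which clone's barcode, which clone's
fragment, whether switched) sufficient to recompute any downstream purity
statistic independently of the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .barcode import BarcodeSpec, design_diversity, generate_unique_barcodes
from .extraction import FlankDefinition
from .fragmentation import Fragment, revcomp

__all__ = [
    "Clone",
    "LibraryTruth",
    "ReadSimConfig",
    "ReadPair",
    "build_library",
    "simulate_reads",
    "inject_heterodimers",
    "mutate_sequence",
    "write_fastq_pair",
    "write_truth_table",
]


@dataclass(frozen=True)
class Clone:
    """One barcoded plasmid: barcode, fragment, and insertion orientation.

    Orientation '+' is the cis insertion (fragment read in reference sense),
    '-' the trans insertion (reverse complement).
    """

    barcode: str
    fragment: Fragment
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")

    @property
    def strand(self) -> str:
        """Strand of the aligned fragment as seen by the assessment pipeline."""
        return self.orientation

    def read2_sequence(self) -> str:
        seq = self.fragment.sequence
        return seq if self.orientation == "+" else revcomp(seq)


@dataclass
class LibraryTruth:
    """Ground truth of a simulated library: the true lookup table."""

    clones: list[Clone]
    reference_id: str

    def __post_init__(self) -> None:
        barcodes = [c.barcode for c in self.clones]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicated barcodes in library truth")

    def __len__(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing-run model.

    ``mean_depth`` is the Poisson mean of reads per clone (real libraries
    need about 10x the clone count to observe most barcodes).
    ``singlet_inflation`` is the per-clone probability of one extra read
    whose barcode carries a forced substitution error -- the mechanism that
    inflates the singlet bin of barcode-count histograms.  Error rates are
    per base; correct bases are emitted at ``qual_correct`` phred, error
    bases at ``qual_error`` so that phred filtering is informative.
    ``chimera_rate`` is the probability that a read's barcode is replaced by
    that of a uniformly chosen *other* clone (template switching).
    """

    mean_depth: float = 10.0
    singlet_inflation: float = 0.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    qual_correct: int = 37
    qual_error: int = 12
    chimera_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("sub_rate", "ins_rate", "del_rate", "chimera_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.singlet_inflation < 0:
            raise ValueError("singlet_inflation must be >= 0")


@dataclass
class ReadPair:
    """One emitted read pair plus its truth tags."""

    read_id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]
    barcode_clone: int   # clone whose barcode the read carries
    fragment_clone: int  # clone whose fragment the read carries
    chimeric: bool


def build_library(
    fragments: Sequence[Fragment],
    n_clones: int,
    spec: BarcodeSpec,
    rng: np.random.Generator,
) -> LibraryTruth:
    """Assemble ``n_clones`` clones from a fragment pool.

    Barcodes are unique by rejection sampling (each barcode labels exactly
    one clone); fragments are drawn uniformly with replacement; insertion
    orientation is uniform, since blunt/dA-tailed ligation has no
    directional bias.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not fragments:
        raise ValueError("empty fragment pool")
    if n_clones > design_diversity(spec):
        raise ValueError("barcode space exhausted: n_clones exceeds diversity")
    barcodes = generate_unique_barcodes(n_clones, spec, rng)
    frag_idx = rng.integers(0, len(fragments), size=n_clones)
    orientations = rng.integers(0, 2, size=n_clones)
    clones = [
        Clone(barcodes[i], fragments[frag_idx[i]], "+-"[orientations[i]])
        for i in range(n_clones)
    ]
    return LibraryTruth(clones=clones, reference_id="ref")


def mutate_sequence(
    seq: str,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Apply per-base substitution/indel errors and emit phred qualities.

    Each template base is deleted with ``del_rate``; surviving bases are
    substituted with ``sub_rate``; after each emitted base a random base is
    inserted with ``ins_rate``.  Correct bases get ``qual_correct``, error
    bases ``qual_error``.
    """
    if cfg.sub_rate == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0:
        return seq, [cfg.qual_correct] * len(seq)
    bases = "ACGT"
    out: list[str] = []
    quals: list[int] = []
    n = len(seq)
    draws = rng.random((n, 3))
    for i, b in enumerate(seq):
        if draws[i, 0] < cfg.del_rate:
            continue
        if draws[i, 1] < cfg.sub_rate:
            b = bases[(bases.index(b) + rng.integers(1, 4)) % 4] if b in bases \
                else bases[rng.integers(0, 4)]
            out.append(b)
            quals.append(cfg.qual_error)
        else:
            out.append(b)
            quals.append(cfg.qual_correct)
        if draws[i, 2] < cfg.ins_rate:
            out.append(bases[rng.integers(0, 4)])
            quals.append(cfg.qual_error)
    return "".join(out), quals


def _forced_barcode_error(barcode: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(barcode)))
    bases = "ACGT"
    old = barcode[pos]
    new = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4] if old in bases \
        else "A"
    return barcode[:pos] + new + barcode[pos + 1 :]


def simulate_reads(
    truth: LibraryTruth,
    cfg: ReadSimConfig,
    flanks: FlankDefinition | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Emit tagged read pairs for every clone of ``truth``.

    Per clone the read count is Poisson(``mean_depth``); with probability
    ``chimera_rate`` a read's barcode is swapped for that of another clone
    (template switching, tagged); with probability ``singlet_inflation`` the
    clone contributes one extra read whose barcode carries a forced
    low-quality substitution.
    """
    if not truth.clones:
        raise ValueError("empty library")
    if flanks is None:
        flanks = FlankDefinition()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(truth.clones)
    pairs: list[ReadPair] = []
    depths = rng.poisson(cfg.mean_depth, size=n)
    for ci, clone in enumerate(truth.clones):
        for k in range(depths[ci]):
            bc_clone = ci
            chimeric = False
            if cfg.chimera_rate > 0 and n > 1 and rng.random() < cfg.chimera_rate:
                bc_clone = int(rng.integers(0, n - 1))
                if bc_clone >= ci:
                    bc_clone += 1
                chimeric = True
            barcode = truth.clones[bc_clone].barcode
            seq1, qual1 = mutate_sequence(
                flanks.flank5 + barcode + flanks.flank3, cfg, rng
            )
            seq2, qual2 = mutate_sequence(clone.read2_sequence(), cfg, rng)
            pairs.append(
                ReadPair(f"r{ci:06d}.{k}", seq1, qual1, seq2, qual2,
                         barcode_clone=bc_clone, fragment_clone=ci,
                         chimeric=chimeric)
            )
        if cfg.singlet_inflation > 0 and rng.random() < min(cfg.singlet_inflation, 1.0):
            barcode = _forced_barcode_error(clone.barcode, rng)
            seq1 = flanks.flank5 + barcode + flanks.flank3
            qual1 = [cfg.qual_correct] * len(flanks.flank5) \
                + [cfg.qual_error] * len(barcode) \
                + [cfg.qual_correct] * len(flanks.flank3)
            seq2 = clone.read2_sequence()
            pairs.append(
                ReadPair(f"r{ci:06d}.s", seq1, qual1,
                         seq2, [cfg.qual_correct] * len(seq2),
                         barcode_clone=ci, fragment_clone=ci, chimeric=False)
            )
    return pairs


def inject_heterodimers(
    truth: LibraryTruth, rate: float, rng: np.random.Generator
) -> LibraryTruth:
    """Re-pair barcodes and fragments at the plasmid level.

    Models the heterodimer artefact of restriction/re-ligation truncation:
    each clone is affected with probability ``rate``; affected clones have
    their fragments (and orientations) permuted cyclically so that none
    keeps its own (a derangement for any two or more affected clones).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0 or len(truth.clones) < 2:
        return truth
    affected = np.flatnonzero(rng.random(len(truth.clones)) < rate)
    if affected.size < 2:
        return truth
    clones = list(truth.clones)
    rotated = np.roll(affected, 1)
    prev = {i: clones[i] for i in affected}
    for dst, src in zip(affected, rotated):
        clones[dst] = Clone(prev[dst].barcode, prev[src].fragment,
                            prev[src].orientation)
    return LibraryTruth(clones=clones, reference_id=truth.reference_id)


def _phred_str(quals: Sequence[int]) -> str:
    return "".join(chr(min(q, 93) + 33) for q in quals)


def write_fastq_pair(
    pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    """Write the simulated pairs as two FASTQ files (read 1 = barcode side)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{_phred_str(p.qual1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{_phred_str(p.qual2)}\n")


def write_truth_table(truth: LibraryTruth, path: str | Path) -> None:
    """Write the ground-truth lookup table as TSV."""
    with open(path, "w") as fh:
        fh.write("clone_id\tbarcode\tref_id\tstart\tend\tstrand\n")
        for i, c in enumerate(truth.clones):
            fh.write(
                f"{i}\t{c.barcode}\t{truth.reference_id}\t"
                f"{c.fragment.source_start}\t{c.fragment.source_end}\t"
                f"{c.orientation}\n"
            )
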