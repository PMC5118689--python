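"""Simulation of dUTP-PCR / UDG-NaOH fragmentation of a template.

During PCR with a dUTP/dTTP mixture, each T position of the product
incorporates uracil with a probability set by the dUTP fraction (and the
polymerase's relative incorporation efficiency).  Uracil-DNA-glycosylase
excises every incorporated uracil and alkaline treatment breaks the strand
at the resulting abasic sites, so cleavage sites are sequence-dependent but
statistically predictable: a per-T Bernoulli process.  The size distribution
of the resulting fragments is therefore tunable through the dUTP fraction.

Model choices
-------------
* Single-strand cut model: only T positions of the given strand are
  considered; opposing-strand nick pairing is not modelled.
* A cut at T position ``i`` excises the base: the flanking fragments are
  ``[start, i)`` and ``[i+1, end)``.  Fragment lengths of one replicate plus
  the number of cut bases therefore sum to the template length.
* Fragments shorter than ``min_fragment_len`` are discarded, emulating the
  bead-based size cut (default 50 nt) applied before ligation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FragmentationConfig",
    "Fragment",
    "cleavage_probability",
    "fragment_template",
    "predicted_length_distribution",
    "fragments_to_bed",
    "fragments_to_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentationConfig:
    """Parameters of the uracil-excision fragmentation reaction.

    Parameters
    ----------
    dutp_fraction
        Fraction of dUTP among dUTP+dTTP in the PCR mix, in [0, 1].
    incorporation_ratio
        Efficiency of dUTP incorporation relative to dTTP (1.0 = neutral).
        Proof-reading polymerases incorporate dUTP somewhat less readily.
    min_fragment_len
        Fragments shorter than this are discarded (bead size cut), default 50.
    seed
        Optional seed recorded with outputs; callers normally pass an
        explicit ``numpy`` Generator instead.
    """

    dutp_fraction: float
    incorporation_ratio: float = 1.0
    min_fragment_len: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dutp_fraction <= 1.0):
            raise ValueError("dutp_fraction must be in [0, 1]")
        if self.incorporation_ratio <= 0:
            raise ValueError("incorporation_ratio must be > 0")
        if self.min_fragment_len < 0:
            raise ValueError("min_fragment_len must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Fragment:
    """A fragment cut from a template; coordinates are 0-based half-open."""

    sequence: str
    source_start: int
    source_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.source_start < self.source_end):
            raise ValueError("need 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.sequence) != self.source_end - self.source_start:
            raise ValueError("sequence length does not match coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_probability(config: FragmentationConfig, base: str) -> float:
    """Probability that a template position of ``base`` is cleaved.

    A T position incorporates uracil with probability
    ``f*r / (f*r + (1-f))`` where ``f`` is the dUTP fraction and ``r`` the
    relative incorporation efficiency; every incorporated uracil is excised
    and cleaved.  Non-T positions are never cleaved.
    """
    if base not in "ACGT":
        raise ValueError(f"invalid base {base!r}")
    if base != "T":
        return 0.0
    f, r = config.dutp_fraction, config.incorporation_ratio
    denom = f * r + (1.0 - f)
    if denom == 0.0:  # f == 1 handled below anyway; guard r pathologies
        return 1.0
    return (f * r) / denom


def fragment_template(
    template: str,
    config: FragmentationConfig,
    rng: np.random.Generator | None = None,
    return_cuts: bool = False,
):
    """One fragmentation replicate of ``template``.

    Every T is cleaved independently with :func:`cleavage_probability`; the
    cut base is excised and maximal uncut intervals of length >=
    ``min_fragment_len`` (and >= 1) are returned as plus-strand fragments.

    With ``return_cuts=True`` returns ``(fragments, cut_positions)`` so that
    callers can verify length conservation including excised bases.
    """
    if not template:
        raise ValueError("empty template")
    if rng is None:
        rng = config.rng()
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    t_pos = np.flatnonzero(arr == ord("T"))
    p = cleavage_probability(config, "T")
    cuts = t_pos[rng.random(t_pos.size) < p] if t_pos.size else t_pos
    bounds = np.concatenate(([-1], cuts, [len(template)]))
    fragments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        start, end = int(a) + 1, int(b)
        if end - start >= max(1, config.min_fragment_len):
            fragments.append(Fragment(template[start:end], start, end, "+"))
    if return_cuts:
        return fragments, cuts
    return fragments


def fragment_lengths(
    template: str,
    config: FragmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fragment lengths of one replicate, without materialising sequences.

    Same cut process as :func:`fragment_template`; used for fast
    distribution studies over many replicates.
    """
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    t_pos = np.flatnonzero(arr == ord("T"))
    p = cleavage_probability(config, "T")
    cuts = t_pos[rng.random(t_pos.size) < p] if t_pos.size else t_pos
    bounds = np.concatenate(([-1], cuts, [len(template)]))
    lengths = np.diff(bounds) - 1  # each left bound is an excised base (or -1)
    return lengths[lengths >= max(1, config.min_fragment_len)]


def predicted_length_distribution(
    template: str,
    config: FragmentationConfig,
    n_reps: int,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Monte-Carlo fragment-length distribution over ``n_reps`` replicates.

    Returns a Series indexed by fragment length whose values are densities
    (unit-width bins summing to 1).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = config.rng()
    counts: dict[int, int] = {}
    for _ in range(n_reps):
        for frag in fragment_template(template, config, rng):
            counts[len(frag)] = counts.get(len(frag), 0) + 1
    total = sum(counts.values())
    ser = pd.Series(counts, dtype=float).sort_index() / max(total, 1)
    ser.index.name = "length"
    ser.name = "density"
    return ser


def fragments_to_bed(
    fragments: list[Fragment], ref_id: str, path: str | Path
) -> None:
    """Write fragments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{ref_id}\t{f.source_start}\t{f.source_end}\t"
                     f"frag{i:06d}\t0\t{f.strand}\n")


def fragments_to_fasta(fragments: list[Fragment], path: str | Path) -> None:
    """Write fragment sequences as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(f.sequence),
            id=f"frag{i:06d}",
            description=f"{f.source_start}-{f.source_end}({f.strand})",
        )
        for i, f in enumerate(fragments)
    ]
    seqio_write(records, str(path), "fasta")
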