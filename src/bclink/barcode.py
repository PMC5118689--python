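"""Degenerate molecular barcode design, generation and design-level analytics.

A plasmid library barcode is a short degenerate DNA tag synthesised from a
pattern of IUPAC ambiguity codes.  The default design cycles the codes
V (not T), H (not G), D (not C), B (not A) five times -- written
``(VHDB)x5`` -- giving 20-nt barcodes, 3^20 (about 3.5 billion) possible
sequences, and a hard guarantee that no homopolymer longer than three bases
can occur inside the barcode.  Cycling exclusion matters because
insertion/deletion sequencing errors concentrate on homopolymer runs.

The module exposes the design as a :class:`BarcodeSpec`, sampling and
validation against it, and exact combinatorial analytics (diversity,
worst-case homopolymer run) used as design checks.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IUPAC_CODES",
    "BarcodeSpec",
    "Barcode",
    "expand_pattern",
    "generate_barcode",
    "generate_unique_barcodes",
    "validate_barcode",
    "passes_length_filter",
    "design_diversity",
    "max_homopolymer_run",
    "base_composition_logo",
]

#: IUPAC nucleotide ambiguity codes -> set of concrete bases allowed.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_REPEAT_RE = re.compile(r"^\((?P<unit>[A-Z]+)\)[xX](?P<n>\d+)$")


def expand_pattern(pattern: str) -> str:
    """Expand a shorthand like ``(VHDB)x5`` into ``VHDBVHDB...``.

    Plain patterns are returned unchanged (upper-cased).
    """
    pattern = pattern.strip().upper()
    m = _REPEAT_RE.match(pattern)
    if m:
        return m.group("unit") * int(m.group("n"))
    return pattern


class BarcodeDesignError(ValueError):
    """Raised for invalid degenerate-pattern configuration."""


@dataclass(frozen=True)
class BarcodeSpec:
    """A degenerate barcode design plus the accepted observed-length window.

    Parameters
    ----------
    pattern
        IUPAC ambiguity string, one code per barcode position.  Shorthand
        ``(UNIT)xN`` is expanded.  Default is the ``(VHDB)x5`` design.
    min_len, max_len
        Inclusive bounds of the observed-length filter applied to extracted
        barcodes (default 18..22; sequenced barcodes deviating from the
        nominal 20 nt are most often 19 nt and still usable).
    """

    pattern: str = "VHDB" * 5
    min_len: int = 18
    max_len: int = 22

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", expand_pattern(self.pattern))
        bad = sorted({c for c in self.pattern if c not in IUPAC_CODES})
        if bad:
            raise BarcodeDesignError(f"unknown IUPAC ambiguity code(s): {bad}")
        if not self.pattern:
            raise BarcodeDesignError("empty barcode pattern")
        if not (self.min_len <= len(self.pattern) <= self.max_len):
            raise BarcodeDesignError(
                f"pattern length {len(self.pattern)} outside "
                f"[{self.min_len}, {self.max_len}]"
            )

    @property
    def alphabets(self) -> tuple[str, ...]:
        """Allowed concrete bases per position."""
        return tuple(IUPAC_CODES[c] for c in self.pattern)


@dataclass
class Barcode:
    """A concrete observed barcode, optionally with per-base phred scores."""

    sequence: str
    qualities: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"non-DNA characters in barcode {self.sequence!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length does not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


def _position_weights(
    alphabet: str, weights: Mapping[str, float] | None
) -> np.ndarray | None:
    if weights is None:
        return None
    w = np.array([float(weights.get(b, 1.0)) for b in alphabet])
    if (w < 0).any() or w.sum() == 0:
        raise BarcodeDesignError("per-base weights must be non-negative, not all zero")
    return w / w.sum()


def generate_barcode(
    spec: BarcodeSpec,
    rng: np.random.Generator,
    weights: Mapping[str, float] | None = None,
) -> Barcode:
    """Draw one barcode conforming to ``spec``.

    Each position is sampled from its allowed alphabet, uniformly by default.
    ``weights`` maps bases to relative sampling weights (renormalised within
    each position's alphabet) to emulate synthesis skew.
    """
    seq = []
    for alphabet in spec.alphabets:
        p = _position_weights(alphabet, weights)
        seq.append(alphabet[rng.choice(len(alphabet), p=p)])
    return Barcode("".join(seq))


def generate_unique_barcodes(
    n: int,
    spec: BarcodeSpec,
    rng: np.random.Generator,
    weights: Mapping[str, float] | None = None,
) -> list[str]:
    """Draw ``n`` distinct barcode sequences by rejection sampling.

    Mirrors single-use barcoding where a one-cycle extension guarantees each
    barcode labels exactly one clone.  Raises if ``n`` exceeds the design
    diversity (pigeonhole).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > design_diversity(spec):
        raise BarcodeDesignError(
            f"cannot draw {n} unique barcodes from a design of diversity "
            f"{design_diversity(spec)}"
        )
    alphabets = spec.alphabets
    probs = [_position_weights(a, weights) for a in alphabets]
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = max(1024, n - len(out))
        # column-wise vectorised draw, one column per barcode position
        cols = [
            rng.choice(np.frombuffer(a.encode(), dtype="S1"), size=batch, p=p)
            for a, p in zip(alphabets, probs)
        ]
        for raw in np.stack(cols, axis=1):
            s = raw.tobytes().decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def validate_barcode(seq: str, spec: BarcodeSpec) -> bool:
    """True iff ``seq`` has the pattern's length and every base is allowed."""
    if len(seq) != len(spec.pattern):
        return False
    return all(b in alphabet for b, alphabet in zip(seq, spec.alphabets))


def passes_length_filter(seq: str, spec: BarcodeSpec) -> bool:
    """Observed-length filter (default 18 <= len <= 22)."""
    return spec.min_len <= len(seq) <= spec.max_len


def design_diversity(spec: BarcodeSpec) -> int:
    """Number of distinct sequences the design can produce.

    Product of per-position alphabet sizes; 3**20 for ``(VHDB)x5``.
    """
    out = 1
    for alphabet in spec.alphabets:
        out *= len(alphabet)
    return out


def max_homopolymer_run(spec: BarcodeSpec) -> int:
    """Longest same-base run realisable by *any* conforming sequence.

    Exact dynamic program over position alphabets: ``run[b]`` is the longest
    run of base ``b`` ending at the current position over all conforming
    sequences; positions are independent, so extending greedily is exact.
    """
    run = {b: 0 for b in "ACGT"}
    best = 0
    for alphabet in spec.alphabets:
        run = {b: (run[b] + 1 if b in alphabet else 0) for b in "ACGT"}
        best = max(best, max(run.values()))
    return best


def base_composition_logo(barcodes: Iterable[Barcode | str]) -> pd.DataFrame:
    """Per-position base frequencies over *unique* barcode sequences.

    Each unique sequence counts once regardless of read count, so PCR or
    sequencing depth bias does not enter the logo.  Returns a DataFrame
    indexed by 0-based position with columns A, C, G, T; ragged lengths are
    tallied per position over the sequences long enough to reach it.
    """
    uniq = {b.sequence if isinstance(b, Barcode) else str(b) for b in barcodes}
    uniq.discard("")
    if not uniq:
        raise ValueError("no barcodes supplied")
    width = max(len(s) for s in uniq)
    counts = np.zeros((width, 4))
    cols = {b: i for i, b in enumerate("ACGT")}
    for s in uniq:
        for pos, b in enumerate(s):
            if b in cols:
                counts[pos, cols[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(counts / totals, columns=list("ACGT")).rename_axis("position")
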