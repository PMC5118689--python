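# bclink

Assessment toolkit for **barcoded plasmid libraries** — the libraries used
to map genetic function *in vivo* by linking every genomic fragment cloned
into a viral (AAV/LV) expression vector to a short degenerate DNA barcode.
Once a plasmid library is sequenced and a barcode → fragment **lookup
table** is built, cheap barcode-only sequencing of RNA/DNA from tissue is
enough to read out the function of every fragment.  The weak point of the
whole strategy is the lookup table itself: re-ligation heterodimers, PCR
template switching and sequencing errors all attach barcodes to the wrong
fragments.  `bclink` quantifies that failure mode and validates the
barcode-clustering step needed to count true barcodes.

## What it computes

**Purity.**  For each barcode observed in ≥ 2 reads, reads are grouped,
identical aligned ranges are counted, and the most abundant range is the
consensus.  Reads whose range falls within ±20 bp of the consensus on both
endpoints (same strand) count toward it:

    purity = (reads supporting the consensus fragment) / (all reads of the barcode)

Purity is 1 exactly when a barcode points at a single fragment; chimeras and
false clustering drag it toward 0.  The map *barcode → (consensus range,
purity)* is the lookup table.

**Barcode design analytics.**  The default design is `(VHDB)x5`: IUPAC
codes V (not T), H (not G), D (not C), B (not A) cycled five times.  The
package computes its diversity exactly (3^20 ≈ 3.5 × 10⁹ sequences) and
proves by exact search that no conforming barcode contains a homopolymer
longer than 3 nt.

**Clustering validation.**  Two clustering algorithms over Levenshtein
distance — greedy *sphere* clustering and *message passing* (count transfer
to the nearest higher-count neighbour, ambiguous ties discarded) — are run
on observed barcode counts, and the post-clustering purity distribution is
the readout: a false merge of two real barcodes is visible as a purity drop
because the merged cluster points at two different fragments.

**Ground-truthed simulation.**  A library simulator supplies test data:
dUTP/UDG fragmentation (per-T Bernoulli cleavage with probability
`f·r / (f·r + 1 − f)` for dUTP fraction `f`), unique `(VHDB)x5` barcodes,
Poisson read depth with singlet inflation, substitution/indel errors with
phred qualities, and chimeras at both the plasmid (heterodimer) and read
(template switching) level — each read carries truth tags.

## Worked example

```python
import numpy as np
import bclink as bl

rng = np.random.default_rng(42)
reference = "".join(rng.choice(list("ACGT"), size=600))

# fragment the reference (dUTP 4%, bead-style >=50 nt size cut)
fcfg = bl.FragmentationConfig(dutp_fraction=0.04, min_fragment_len=50)
pool = []
for _ in range(100):
    pool.extend(bl.fragment_template(reference, fcfg, rng))
print(f"fragment pool: {len(pool)} fragments, "
      f"mean length {np.mean([len(f) for f in pool]):.1f} nt")

# build a 500-clone library and sequence it at 10x with 30% template switching
truth = bl.build_library(pool, 500, bl.BarcodeSpec(), rng)
reads = bl.simulate_reads(
    truth, bl.ReadSimConfig(mean_depth=10, chimera_rate=0.3), rng=rng)
print(f"simulated {len(reads)} read pairs for {len(truth)} clones")

result = bl.assess_read_pairs(
    [(r.read_id, r.seq1, r.qual1, r.seq2, r.qual2) for r in reads],
    "ref", reference)
s = result.purity_summary
print(f"lookup table: {len(result.table)} barcodes "
      f"({result.counters['singlets']} singlets set aside)")
print(f"purity: mean {s['mean']:.3f}, median {s['median']:.3f}, "
      f"q25 {s['q25']:.3f}")
```

Output:

```
fragment pool: 399 fragments, mean length 131.8 nt
simulated 5048 read pairs for 500 clones
lookup table: 500 barcodes (0 singlets set aside)
purity: mean 0.701, median 0.700, q25 0.600
```

With 30 % of reads template-switched, mean purity lands at ≈ 0.70 — the
unswitched fraction — which is exactly how the purity beanplot of a real
library exposes its chimera burden.  Re-running with `chimera_rate=0`
returns every barcode at purity 1.000 and a lookup table identical to the
simulator's truth table.

## Layout

```
src/bclink/
  barcode.py        degenerate design, generation, diversity/homopolymer analytics
  fragmentation.py  dUTP/UDG cut model and size distributions
  simulate.py       library construction, read simulation, chimeras, truth tags
  extraction.py     flank matching, length and phred filtration
  alignment.py      seed-and-extend unique alignment to the reference
  reduce.py         consensus + purity, the lookup table
  clustering.py     sphere and message-passing clustering, purity validation
  pipeline.py       end-to-end workflow, reports, provenance stamps
  cli.py            command-line interface
docs/methods.md     model assumptions, parameters, design choices, limitations
```
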