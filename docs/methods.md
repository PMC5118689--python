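# Methods

This note documents the models implemented in `bclink`, the assumptions
behind them, the parameters that matter, and the design decisions taken
where the underlying procedure admitted more than one faithful reading.

## The assessment problem

A barcoded plasmid library couples each cloned genomic fragment to a
degenerate DNA barcode.  Downstream experiments read only barcodes, so the
entire interpretive weight rests on a lookup table built from paired-end
sequencing of the plasmid library: read 1 covers the barcode between two
constant vector flanks, read 2 covers the fragment.  The table is
trustworthy only if each barcode points at exactly one fragment; `bclink`
measures departures from that ideal (the purity parameter) and validates
the clustering needed to collapse sequencing-error barcodes onto real ones.

## Barcode model

* Design: a string of IUPAC ambiguity codes, default `(VHDB)x5` (20 nt).
  Each position's allowed alphabet has 3 bases, giving 3^20 ≈ 3.5 × 10⁹
  sequences, and consecutive positions always share exactly two bases, so
  the longest realisable homopolymer is 3 nt.  Both quantities are computed
  exactly: diversity as the product of alphabet sizes, the homopolymer
  bound by a dynamic program over position alphabets (positions are
  independent, so greedy run extension is exact); the test suite
  cross-checks the DP against exhaustive enumeration on small patterns.
* Sampling is uniform within each position's alphabet.  Synthesis chemistry
  can skew base usage (real logos show G/T over-representation); an
  optional per-base weight table reproduces such skew, but it is not part
  of the design and defaults to off.
* Barcodes are unique within a simulated library, enforced by rejection
  sampling — the simulated analogue of single-use barcoding by one-cycle
  PCR extension.  Requesting more barcodes than the design diversity is an
  error (pigeonhole).
* Observed-length filter: extracted barcodes must satisfy
  18 ≤ length ≤ 22.  Synthesis of long degenerate oligos cannot guarantee
  exact length; deviating barcodes are most often one base short, and the
  window keeps them while rejecting junk inserts.

## Fragmentation model

PCR in a dUTP/dTTP mix incorporates uracil at T positions; uracil-DNA
glycosylase plus alkali then cleaves every incorporated uracil.  The
implementation models this as an independent Bernoulli cut at each T with

    p = f·r / (f·r + (1 − f))

where `f` is the dUTP fraction and `r` the relative incorporation
efficiency of the polymerase (default 1.0, exposed because proof-reading
polymerases incorporate dUTP less readily; no attempt is made to estimate
it).  Choices and consequences:

* **Single-strand cuts.**  Only the given strand's T positions are cut;
  opposing-strand nick pairing is not modelled.  This is the resolution at
  which fragment-size distributions are predictable from sequence, which is
  all the downstream simulation needs.
* **Excision convention.**  A cut at position *i* removes the base:
  fragments are `[start, i)` and `[i+1, end)`.  Conservation therefore
  reads: fragment lengths + number of cut bases = template length, and the
  tests assert it in that form.
* **Size cut.**  Fragments shorter than `min_fragment_len` (default 50 nt,
  emulating bead purification before ligation) are discarded.
* On a homogeneous (poly-T) template, inter-cut spacing is geometric and
  the conditional mean fragment length is 1/p; on a mixed template it is
  ≈ 1/(p·f_T) for T density f_T.  Both are verified by Monte-Carlo within
  three standard errors.  For the synthetic libraries the default dUTP
  fraction is 0.04, which on a random (f_T ≈ 0.25) template centres the
  retained fragment distribution near 100–130 nt above the 50 nt cut —
  the regime a well-made library sits in.

## Library and read simulation

* A clone = (unique barcode, fragment drawn uniformly with replacement
  from the fragment pool, insertion orientation uniform on {+, −}).
  Uniform orientation reflects the absence of directional bias in
  blunt/dA-tailed ligation and is checked by binomial test.
* Read 1 is `flank5 + barcode + flank3`; read 2 is the fragment in its
  insertion orientation.  The default flanks are fixed 12-mers standing in
  for the constant vector regions; they are configuration, not biology.
* Read depth per clone is Poisson(`mean_depth`, default 10 — the depth
  rule of thumb for observing essentially all clones).  `singlet_inflation`
  adds, per clone, with that probability, one extra read whose barcode
  carries a forced low-quality substitution: these reads create the
  inflated singleton bin seen in real barcode-count histograms and are
  what the singlet exclusion rule exists for.
* Errors: per-base deletion, substitution, insertion (in that order per
  position), each at its own rate.  Correct bases are emitted at phred 37,
  error bases at phred 12, so phred filtration is informative without
  simulating a full quality model — the only property the filtration
  experiments need is that errors are enriched at low phred.
* Chimeras are modelled at two distinct levels because real libraries
  separate them experimentally (PCR-free long-read sequencing sees clean
  plasmids while amplicon sequencing of the same library does not):
  * `inject_heterodimers(rate)` permutes fragments among affected clones
    *before* sequencing (cyclic shift ⇒ derangement of the affected set) —
    the re-ligation artefact of digestion-based truncation;
  * `chimera_rate` swaps a read's barcode for that of a uniformly chosen
    other clone at read level — PCR template switching.  Emulsion PCR is
    represented solely as a lower value of this rate.  Partner choice is
    uniform; no partner bias is modelled.
* Every read carries truth tags (barcode clone, fragment clone, switched
  flag).  The tags are sufficient to recompute purity without the
  pipeline, which is the oracle-equivalence surface used in testing: at
  chimera rate c and depth d, expected mean purity is ≈ (1 − c) plus the
  small self-switch share, and the per-barcode values must match the
  tag-based recomputation exactly.

## Extraction

* Flank matching is substitution-only (Hamming), leftmost match wins,
  default tolerance 1 mismatch per flank.  Indel-tolerant flank matching
  is deliberately omitted: the flanks are short, and indels inside them
  are far rarer than substitutions; reads whose flanks cannot be found are
  counted as `no_flank`, never silently dropped.
* Phred filtration inside the barcode region defaults to the
  minimum-over-bases reading (a single base below threshold fails the
  read); a mean-based alternative is available via `mode="mean"`.  The
  strict reading was chosen as the default because it is the conservative
  interpretation and makes the filter monotone read-by-read.
* The fragment-side mate is trimmed of any detected flank read-through
  (either flank, either orientation) and is never length-filtered.

## Alignment

A self-contained seed-and-extend aligner replaces an external short-read
aligner so the pipeline is deterministic and dependency-free at desk
scale; an adapter for externally produced BED/SAM coordinates exists at
the CLI level (the `reduce` subcommand consumes any BED6).

* Exact k-mer seeds (k = 15) on both strands propose candidate diagonals;
  candidates are scored ungapped first (vectorised Hamming) and by an
  affine-gap fit alignment (global in the fragment, free ends in a
  reference window, match +1, mismatch −1, gap open −2, gap extend −1)
  only when the ungapped score fails the threshold.
* Acceptance threshold: score ≥ (1 − 2·`max_mismatch_rate`)·length
  (default rate 0.1), which for ungapped alignments is exactly a
  mismatch-rate ceiling.
* **Uniqueness filter:** if two distinct (start, end, strand) placements
  tie the best score, the fragment is discarded.  Repeat-derived fragments
  therefore never enter the lookup table.  The tests verify the aligner
  against brute-force all-offset alignment on error-free and substituted
  fragments, including the repeat/tie case.
* Fragments shorter than `min_len` (default 20 nt) are not aligned.

## Reduction: consensus and purity

* Reads are grouped by exact barcode string (case-normalised).  Groups of
  size 1 are singlets: reported, excluded from purity distributions.
* Within a group, identical ranges (start, end, strand) are counted; the
  most abundant is the consensus.  Non-identical ranges with both
  endpoints within ±`tol_bp` (default 20) of the consensus **on the same
  strand** add to the consensus count; purity = consensus count / group
  size.  Strand is part of fragment identity throughout: a fragment in the
  opposite orientation is a different library member.
* Tie-break for equal counts: lexicographically smallest
  (ref_id, start, end, strand) — deterministic and documented; '+' sorts
  before '−'.
* The ±tol window applies to each endpoint independently (the literal
  reading of "start/end position ± 20 bp").  Purity is reported at full
  precision; the 101-bin histogram on [0, 1] exists only for beanplot-style
  reporting.

## Clustering

* `levenshtein(a, b, cap)` is capped unit-cost edit distance; values above
  the cap are reported as cap + 1.  It is backed by the edlib C library
  with a banded-DP pure-Python fallback, and both are tested against an
  independent full-DP oracle (plus symmetry/triangle properties).
* **Sphere clustering.**  Sequences are processed in canonical order
  (count descending, then lexicographic).  A sequence is claimed by the
  nearest centroid within `max_dist` having a *strictly greater* count; if
  no centroid qualifies it becomes a centroid itself; if two centroids tie
  at the minimal distance at the moment of claiming, the sequence is
  discarded as ambiguous.  Claim evaluation happens at the claimed
  sequence's turn in the scan, so a centroid formed later (with equal
  count) participates in tie detection — this is what makes equal-count
  near-duplicates independent centroids rather than members of each other.
* **Message passing.**  Each sequence selects a parent: the nearest
  strictly-higher-count neighbour within `max_dist`.  Among equal-distance
  candidates the highest count wins; only a residual tie (equal distance
  *and* equal count between distinct candidates) discards the sequence.
  Counts then chain transitively to the surviving roots, which are the
  centroids; descendants of a discarded node are discarded with it, so
  count conservation holds exactly.  The tie rule is deliberately one
  notch more permissive than "discard on any distance tie": inside an
  error halo, a one-error read is frequently equidistant from its true
  barcode and from a sibling error, and discarding it would make the
  nominal case ambiguous rather than the pathological one.  No claim of
  bit-level equivalence to any published implementation is made; the
  validation harness is algorithm-agnostic by design.
* Candidate pairs are prefiltered by a pigeonhole chunk index (sequences
  split into `max_dist + 1` fixed-length chunks, indexed at slot offsets
  shifted by ±`max_dist`): any pair within the radius shares an index key,
  so the filter is lossless; every candidate is verified by exact
  distance.  Inputs of ≤ 512 sequences use brute force outright.  Both
  paths are exercised in tests.  Ratio-gating of parent/child counts is
  not applied.
* **Validation readout.**  Reads are relabelled by their barcode's
  centroid (discarded barcodes' reads dropped), the reduction re-runs, and
  the post-cluster purity distribution is returned.  Merging two real
  barcodes produces a cluster whose purity is the count-weighted share of
  its dominant fragment, which is how false clustering is detected without
  knowing the truth.

## Test and simulation scale

The simulation-based acceptance properties use: 1 000-clone libraries at
10× depth over 5 seeds × chimera rates {0, 0.3, 0.9} for truth-tag oracle
equivalence (base-call noise is off in these runs — the property under
test is the bookkeeping of the reduction, and the zero-noise bijection
check requires it); a 5 000-barcode library at 10× with substitution rate
0.011 (chosen so the raw unique-barcode count inflates ≈ 3×) for
clustering recovery, with message passing evaluated at Levenshtein radius
3 and sphere at radii 0 and 4; 10 000 replicates for the fragment-size
law; and ≥ 200 randomised cases per conservation/monotonicity invariant.
References are random 600 bp (assessment) and 3 000 bp (clustering pool)
sequences.  At five-digit barcode counts the clustering harness is the
intended envelope; ten-million-barcode runs are out of scope.

## What the simulator does not capture

Polymerase amplification-efficiency bias at high dUTP, cycle-resolved PCR
kinetics, emulsion micelle occupancy statistics, platform-specific error
profiles (flow-order indel structure, cluster crosstalk), adapter/index
demultiplexing, and chimera partner bias.  Passing tests therefore show
that the assessment machinery is correct and self-consistent under a
realistic error/chimera model — not that any particular real library will
reach a given purity.  On real data the purity distribution additionally
absorbs alignment ambiguity from genomic repeats (here suppressed by the
uniqueness filter and random references).
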