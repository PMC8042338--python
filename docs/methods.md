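# Methods

## Duplex model

A binding site is a gapless, antiparallel pairing of a miRNA (18–26 nt)
with an mRNA window of the same length; window position *k* (5′→3′) pairs
miRNA position *L−1−k*. Hydrogen bonds per opposed pair are G–C = 3,
A–U = 2, G–U = 1, A–C = 1, everything else (including any pair with N) 0.
The two non-canonical pairs are the load-bearing assumption: they let a
purine↔purine or pyrimidine↔pyrimidine substitution inside a canonical
pair retain one bond instead of opening a bubble, so duplexes degrade
gracefully under transition-type divergence. There is no position
weighting, no seed-region emphasis, and no loop/bulge model: this is a
bond-counting approximation, not nearest-neighbour thermodynamics, and it
deliberately trades energetic realism for exactness and auditability.
RNA secondary-structure accessibility of the target is likewise outside
the model.

ΔG = −e_hb · Σ bonds, with e_hb = 2.1 kJ/mol per bond by default. The
constant only sets the kJ/mol scale of reports — it places GC-rich
~22-mers in the −100…−140 kJ/mol range typical of reported efficient
sites — and is configurable (`e_hb_kj_per_bond`); every threshold that
matters operates on the ratio ΔG/ΔGm = 100·bonds/max_bonds, which cancels
e_hb exactly (asserted as a property test). ΔGm uses the pure
Watson–Crick maximum (G/C contribute 3, A/U contribute 2 per miRNA base);
a miRNA containing N has no defined ΔGm and is rejected, while N in the
subject merely scores 0 bonds. Inter-base distances (A–C 1.04 nm, G–C and
A–U 1.03 nm, G–U 1.02 nm) are carried as documented constants; no
geometry is computed.

Report ratios are rounded half-away-from-zero to integers for display
only; all comparisons use unrounded values with a 1e-9 slack that makes
float thresholding coincide with exact integer arithmetic for integer
thresholds.

## Site calling

Every window of every transcript is scored (vectorized over a 5×5 bond
matrix; a pure-Python per-window loop serves as the independent oracle in
tests). Two tiers: ratio ≥ 85 % is reported, ≥ 90 % is flagged
*efficient*. The two tiers reconcile a strict efficiency criterion with
the practice of tabulating slightly weaker sites (85–89 %) alongside.
Site length equals miRNA length; overlapping windows of one miRNA are all
retained. Coordinates are 1-based inclusive from the transcript's first
nucleotide. Region labels follow the start position (start ≤ utr5_end →
5′UTR; ≤ cds_end → CDS; else 3′UTR), with a `boundary_spanning` flag
preserving the information when a site crosses a boundary; transcripts
with `utr5_end = cds_end = 0` are a single unannotated region.

Polysites are maximal runs of one miRNA's starts with consecutive gaps
≤ `polysite_max_gap` (default 3 nt, the tandem-repeat spacing regime);
singleton runs are valid. The start-phase histogram (start mod 3, per
region) exposes reading-frame-locked runs.

## Clusters, compaction, offsets

Clusters are connected components of interval overlap (closed intervals,
≥ 1 shared position) over one transcript's sites, computed by a sorted
sweep and cross-checked in tests against a quadratic union-find closure.
`total_site_length` counts every start with its full miRNA length
(multiplicity); compaction = total_site_length / span_length, reported to
one decimal. The denominator defaults to the realized union span;
`compaction_stats(cluster, span=...)` accepts an externally stated
interval because published cluster bounds are sometimes narrative rather
than the exact union of tabulated sites, and the two can differ by a few
nucleotides. The worked examples pin membership of a published cluster by
the objective rule "a site belongs iff its interval lies wholly inside
the published cluster interval".

Offset patterns report, per miRNA pair and gene, the start difference of
the nearest pair of sites (ties toward the smaller first start), and a
`constant` flag when all genes agree. Nearest matching is the right
notion for pairs with a single co-occurrence per gene; when a gene
carries many interleaved sites of both miRNAs, a nearer cross-pair can
mask a recurring offset — which is why constancy should be asserted over
the genes where the pairing is unambiguous.

## Ortholog conservation

Conserved flanks are exact-match oligonucleotides (≤ `max_len`, default
10): the longest suffix of the sequence 5′ of the cluster interval, and
the longest prefix of the 3′ side, present in every species' segment.
Exact matching reflects that published flanks are printed as exact
oligonucleotides; there are no degenerate positions. Cluster shrinkage
is the inter-flank distance per species, using first occurrences — a
known limitation when a flank recurs upstream of its true position.

Substitution classification aligns each species to the reference with
global dynamic programming (biopython's PairwiseAligner) under fixed
small-integer scores: match +2, mismatch −1, linear gaps −4. The gap
penalty is deliberately stiff: with a cheaper gap (−2), a compensating
gap pair outscores two substitution mismatches, and measured on synthetic
substitution-only ortholog pairs at 8 % divergence roughly a quarter of
alignments acquired spurious indel columns (and occasionally spurious
transversion calls); at −4 a gap pair must rescue at least three
substitutions, and none appeared in 360 measured pairs. Parameters
remain configurable through `AlignmentParams`. Aligned mismatches are
classified as purine transitions (A↔G), pyrimidine transitions (C↔U) or
transversions; gap columns count as indels. Alignment optimality is
tested against a brute-force recursion on short strings. Only pairwise
alignment to the reference is supported — no multiple alignment, no
phylogeny, no dN/dS.

Cross-species re-scoring reports each species' best window ratio for a
miRNA within its homologous segment, banded ≥ 90 / 85–90 / 80–85 / < 80;
segments shorter than the miRNA are marked not evaluable. CDS clusters
can be translated (standard code, stops as `*`, trailing partial codon
dropped) to inspect the encoded oligopeptide.

## Expression context and markers

Expression is two-class on RPKM with the breakpoint at 10 (high
inclusive); the boundary side is a convention, chosen because published
groupings split "below 10" from high-expression bands without treating
equality. Associations aggregate one miRNA's sites on one gene,
represented by the largest-|ΔG| site (ties: higher ratio, then earlier
start). An association is a candidate diagnostic marker when |ΔG| is
strictly above `marker_dg_cutoff` (default 130 kJ/mol) or when it has at
least `multisite_min` sites (default 5): repeated sites buffer the
interaction against point mutations, so multiplicity substitutes for
single-site strength. `pearson_r` (scipy) is provided for
expression–expression correlations with explicit degenerate-input errors.

## Synthetic data

The generator emulates the regimes the analysis assumes, under one NumPy
generator seeded from a single integer (identical configs give
byte-identical artifacts):

- **Transcripts**: 5′UTR 100–300 nt (GC fraction 0.60 — clusters
  concentrate in GC-enriched 5′UTRs), CDS 300–1500 nt triplet-rounded,
  3′UTR 300–4000 nt at GC 0.45.
- **Single sites**: the window starts as the exact reverse complement and
  is degraded by transitions to a target ratio (a G-C pair loses 2 bonds,
  an A-U pair 1, so any integer bond total is reachable); when an odd
  bond deficit meets an all-G/C window, the residual bond of an earlier
  edit is zeroed instead. Achieved ratios land within ±1.5 points of the
  target or the generator raises rather than silently missing.
- **Clusters**: member miRNAs are *derived* from their overlapping
  windows (reverse complement, then transitions applied to the miRNA with
  re-scoring and overshoot reversion), because overlapping windows cannot
  be edited independently. Default: nine miRNAs with starts spread over
  10 nt, target ratios 88–100 %.
- **Polysites**: a period-p miRNA paired with a tandem repeat of its
  complement makes every planted start (spacing p) score exactly 100 %;
  one phase-breaking base is written on each side of the block. Shoulder
  windows one repeat unit outside the block still genuinely score ~90 %,
  so polysite round-trips group the full-complement (ratio 100) sites.
  Default: 13 starts at 2-nt spacing.
- **Offset pairs**: one composite block of length offset+L is planted in
  several genes and both miRNAs are derived from its two ends, so the
  same constant offset (defaults 6, 74, 99 nt) recurs per gene — the
  repeat-derived mechanism that produces such offsets in real UTRs.
- **Orthologs**: i.i.d. per-position substitutions outside preserved
  flank oligonucleotides at `sub_rate` (default 0.05), transitions with
  probability `transition_fraction` (default 0.8, matching the observed
  predominance of within-class changes; 1.0 in round-trip tests).
- **RPKM**: log-normal (ln-mean 1.25, ln-sd 1.1) clipped to
  [0.1, 322.5], with 20 % of genes forced into the 43.1–322.5 band to
  mirror a low/high expression split.

What the generator does **not** emulate: base composition biases beyond a
single GC fraction, repeat families other than the planted ones, real
UTR/CDS sequence structure, indel divergence between orthologs, and any
expression dynamics. Passing round-trip tests therefore demonstrates the
correctness of the algorithms on data with the assumed structure, not the
biological accuracy of the duplex model on real transcripts.

## Problem sizes and determinism

The test suite and the acceptance script use 1,000 (miRNA, ≤ 2 kb
transcript) pairs for the scanner/oracle identity (with strong sites
planted in half so the comparison is exercised on non-empty lists),
four 12-gene cohorts (≥ 160 plantings) for recovery, ten 6-species
ortholog sets for the conservation round trip, and 1,000 random duplexes
for the invariance properties — sizes at which every check runs in
seconds while the counts are large enough for the rates asserted. All
randomness flows from explicit integer seeds; pipeline data outputs are
byte-deterministic, and the run manifest additionally records a
wall-clock timestamp (excluded from determinism comparisons).

## Known limitations

- The energy scale is a single-constant approximation; absolute ΔG values
  should be read as bond counts in kJ/mol clothing.
- Published worked-example tables carry per-row value ranges for
  multi-start rows; the curated tables store one representative ΔG/ratio
  per start, which the cluster/offset/polysite arithmetic never uses.
- Flank location uses first occurrences; a flank recurring within a
  segment can shift the inter-flank length.
- Offset detection with nearest-pair matching can be masked by
  interleaved extra sites (see above).
- The host-gene/target-gene expression correlation is exposed as an
  operation (`pearson_r`) but no corpus to run it on ships with the
  package.
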