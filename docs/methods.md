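# Methods

## Target-site model

A miRNA:target duplex is modeled as a fitting alignment: the whole miRNA
is consumed, the transcript is free at both ends, and at most one
single-nucleotide bulge (on either strand) is allowed — a band width of 1
around the ungapped diagonal. Pair states are Watson–Crick MATCH (A:U,
G:C), G:U wobble, MISMATCH, and the two bulge states. The penalty score is

    S = Σ penalties,  MATCH 0, G:U 0.5, MISMATCH 1, bulge 1,

with mismatch and G:U penalties doubled when the miRNA position lies in
the core segment (positions 2–13 from the 5' end). Sites with S ≤ 4 are
reported. An `N` on the transcript side scores as MISMATCH; miRNAs
containing `N` are rejected on input.

Design choices made where the convention is genuinely open:

* **Core boundaries.** 2–13 is the classical plant-target scoring core;
  it is configurable (`ScoringScheme.core_range`) since published studies
  rarely state exact boundaries.
* **Bulges are not doubled in the core** by default — the doubling rule is
  stated for mismatches and G:U pairs; a flag
  (`double_bulges_in_core`) enables doubling for comparison.
* **Bulges are forbidden opposite miRNA positions 9–12** so the slicer
  position (the base paired to miRNA nt 10) is always defined. A
  transcript-side bulge takes the miRNA position of the next paired
  nucleotide for bookkeeping and may not sit at a duplex terminus.
* **Cleavage convention.** The reported cleavage site is the transcript
  base paired to miRNA nucleotide 10; for an ungapped site with range end
  E this is E − 9. Published tables also contain 22-nt alignment ranges
  whose printed sites imply E − 10; those are consistent with a bulged
  placement or a 22-nt miRNA numbering and are not modeled — the package
  derives the site from the pairing map, never from range arithmetic.

## Site search

The scan anchors each candidate on the transcript base paired to the
miRNA 5' end and runs a banded dynamic program over (miRNA position,
bulge status) with band width 1, yielding the minimal penalty per anchor
in O(L) per position. Anchors within the cutoff are reconstructed by
explicit enumeration of the ≤ 2L legal pairings at that anchor, ordered
deterministically by (score, bulge count, start, structural key).
Overlapping placements are collapsed greedily to the best-scoring one
(ties: fewest bulges, then leftmost start). The test suite holds the scan
to exact equivalence with a brute-force enumeration over all anchors and
all ≤ 1-bulge placements on synthetic transcripts.

## Degradome validation

Tags are matched exactly, full length, on the transcript sense strand;
every occurrence contributes the tag's full abundance at its 5' position
(no fractional splitting of multi-mapped tags — simplest reproducible
convention, configurable upstream by filtering). Tags shorter than 15 nt
(e.g. truncated at a transcript end) are unmappably ambiguous and are
skipped. A predicted site becomes a cleavage event when the tag count at
its expected cleavage position reaches `min_reads` (default 1; the
categories already down-weight singleton noise). The three-tier category
rule — I at the transcript maximum, II strictly between the median of
occupied positions and the maximum, III otherwise — follows the
established degradome-classification scheme; raw counts are used
throughout since no normalization basis is published for the tables the
package reproduces.

t-signatures are the transcript window p−15 … p+14 around a mapped 5'
end (30 nt untruncated, focal base 16th); windows hitting a boundary are
truncated and flagged.

## Microarray analysis

Per spot, the background mean is subtracted and negative values clamp to
0. A channel is detectable when the mean corrected signal exceeds 3× the
background SD and the spot CV (replicate SD / mean) is below 0.5. A probe
enters the differential analysis when at least one channel is detectable
and all corrected spot intensities are positive (logs require it) — the
cross-channel rule is the package's own choice, as published criteria are
stated per signal.

Normalization is applied per replicate spot pair: M = log2(B/A) and
A-value = ½·log2(A·B) are computed per spot, one LOWESS curve (tricube
weights, span 0.4, 3 bisquare robustifying iterations; statsmodels) is
fitted to all spots pooled, and the fitted bias is subtracted from each
spot's M with A-values preserved exactly. Normalizing per spot rather
than per probe mean keeps replicate pairs intact for the paired t-test.
Span and iteration count are exposed since no values are published.

The paired two-tailed t-test runs on d = log2(B) − log2(A) per spot pair
with n−1 df; the degenerate sd(d)=0 case returns p=1 when mean(d)=0,
else 0. Calls apply thresholds to the log2 ratio rounded half away from
zero to 2 decimals, so printed-table semantics (a printed 1.00 passes
"≥ 1") are reproducible. Two named presets exist — `methods` (p < 0.05,
3-fold) and `results` (p < 0.01, 2-fold) — because published criteria
differ between sections; no multiple-testing correction is applied by
default (matching the original analysis), and Benjamini–Hochberg can be
applied downstream from the returned p-values.

## qPCR

Pure 2^−ΔΔCt with amplification efficiency fixed at 2. Technical
replicates within an experiment are averaged first; the point estimate
uses mean Ct across experiments, while per-experiment ratios provide the
reported SD (matching the three-independent-experiments error-bar
convention). ΔΔCt 0 yields exactly 1.0; the reciprocal identity
ratio(a,b)·ratio(b,a) = 1 holds exactly in exact arithmetic and to one
ulp in floating point for fractional ΔΔCt.

## Synthetic data

Generators are seeded (numpy `Generator`); one master seed fans out to
per-stage streams via `SeedSequence.spawn` in fixed index order, and all
outputs are bit-reproducible per seed.

* **Transcriptomes**: i.i.d. bases at a target GC (default 0.45, typical
  of plant transcript GC), lengths uniform in a range.
* **Implanted sites**: the reverse complement of the miRNA is written at
  a chosen start, then edits realize exactly the requested pair states;
  the expected score is computed with the same scoring scheme the
  analysis uses, the expected cleavage from the pairing map. Edits at
  duplex termini can make a shifted one-bulge alignment score below the
  planted one; truth-recovery tests therefore use interior edits.
* **Degradome libraries**: one tag (default 20 nt, a typical
  enzyme-defined tag length) per planted site at the cleavage position
  with `reads_per_site` abundance (default 20), plus
  Poisson(0.01/nt × length) background tags of count 1 at uniform
  positions; tags running past a transcript end are shortened and
  flagged. Background positions have no positional-decay structure —
  sufficient for testing the category rule, not a model of real
  degradation gradients.
* **Microarray**: log-normal base intensities (log2 I ~ N(10, 1.5)),
  planted ±log2FC on the first `n_diff` probes, optional dye bias as a
  constant or a function of the A-value, per-spot log-normal noise
  (default SD 0.15 in log2 units), and an exact additive background
  offset so noiseless settings reproduce planted ratios exactly.
* **qPCR**: Ct_target = Ct_ref + ΔCt_calibrator − log2(ratio) + noise per
  independent experiment (default noise SD 0.05 cycles, triplicate).

What passing these tests shows — and does not. Synthetic transcripts are
i.i.d.; real transcripts have composition structure, repeats and paralogs
that make exact tag mapping more ambiguous than simulated. Simulated
chip noise is homoscedastic in log scale; real chips show
intensity-dependent variance beyond the dye bias modeled. Recovery rates
on synthetic data therefore bound idealized, not field, performance.

## Problem sizes and numerics

Tests run the search on 300–500-nt transcripts (where brute-force oracle
equivalence is checked exhaustively), degradome recovery on 50 transcripts
of 800–1,200 nt over 20 seeds, and chip recovery on 500 probes × 3
replicate pairs — sizes chosen so the full suite exercises every rule
while remaining a desk-scale run. Score comparisons are exact (penalties
are multiples of 0.5, represented exactly in binary floating point).
LOWESS requires ≥ 10 probes and raises with advice to enlarge the span
when the window is under-filled. Degenerate inputs (empty profiles,
zero-variance t-tests, non-positive signals) raise or follow the
documented conventions rather than propagating NaNs.
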