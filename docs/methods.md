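# Methods

## Peak-calling model

The caller assumes strand-specific per-base pileup depth for two biological
replicates of a tagged ChIP experiment and (optionally) two replicates of an
untagged control, all over a single circular-or-linear bacterial genome
small enough for dense vectors (≤ ~5 Mb). Coordinates are 1-based inclusive
throughout the library; bedGraph and BED conversions happen only at file
boundaries.

**Normalization.** All strands of a dataset are rescaled by one factor
`target_reads / total_reads` (target 100 million reads). Whether to
normalize per strand or per dataset is a genuine choice; the per-dataset
factor was chosen so the plus/minus shape of a binding site is preserved
exactly.

**Threshold selection.** For each strand, every integer pair
(T₁, T₂) ∈ [t_min, t_max]² (defaults 1 and 1000) is evaluated. With
O(T₁, T₂) the number of positions where replicate 1 ≥ T₁ **and** replicate
2 ≥ T₂ (comparisons are ≥), and p_i the marginal exceedance fraction of
replicate i, the empirical FDR under the no-enrichment null is

    FDR(T1, T2) = G · p1 · p2 / O        (+∞ when O = 0).

The independence null — the expected joint count if neither replicate is
enriched anywhere and the replicates are unrelated — is the closed-form
default; an alternative estimator that averages O over random circular
shifts of replicate 2 is available in `estimate_fdr(method="circular")` as a
cross-check. "True-positive positions" are estimated as O·(1 − FDR); among
pairs with FDR < 0.01 the pair maximizing this is selected, ties resolved
toward smaller T₁ + T₂ and then smaller T₁ (the least stringent of the
equally good pairs). The whole grid is evaluated at once via a joint
histogram of floored depths and a 2-D suffix cumulative sum, which is exact
for integer thresholds and keeps the 10⁶-cell scan at ~10 ms per strand.
The grid search runs independently per strand; the selection is position-
wise, not region-wise.

**Region calling and strand pairing.** Maximal jointly-enriched runs are
extracted per strand; runs separated by ≤ `merge_gap` (default 20 bp,
0 restores strict runs) are merged, and each region's summit is the
leftmost position maximizing the summed replicate depth. Plus- and
minus-strand regions are paired greedily by nearest summit subject to
plus summit ≤ minus summit and summit distance ≤ `pair_distance` (default
100 bp); each region is used at most once, unpaired regions are dropped, and
the peak center is the floor midpoint of the two summits. The plus-before-
minus requirement encodes the read asymmetry of single-end ChIP fragments
around a point-source binding site.

**FAT scoring.** Per replicate, FAT_i = (maximum depth inside the peak
region across strands) / T_i, maximized over strands when thresholds differ
between strands. The reported score is the mean of the two replicate
values rounded half-up to an integer, matching the convention of reporting
integer peak strengths; raw per-replicate values are retained.

**Control exclusion.** The selected thresholds are rescaled by
control_total / tagged_total per replicate and applied to the raw-scale
control coverage (equivalent to normalizing the control and reusing the
thresholds); control peaks are called with the identical machinery, and any
tagged peak whose center lies within 50 bp (inclusive) of a control peak
center is excluded.

Scale invariance holds by construction: multiplying depths and thresholds
by the same positive constant changes neither the FDR surface nor the
called regions.

## Motif localization

Oriented offsets are `peak − motif` for plus-strand motifs and
`motif − peak` for minus-strand motifs, so positive always means upstream in
the motif's direction. Medians of even-sized sets are the mean of the
central pair. Sites with |offset − median| > 25 nt are flagged as
non-canonically localized; the threshold is configurable and the default is
the value that isolates exactly the two outliers of the packaged fixture.
The "center" of an even-length motif window is the left-of-middle base
(index 13 of a 28-mer). The PWM scanner is deliberately minimal plumbing
(log-odds against a uniform background, both strands, ties to the leftmost
position then plus strand); motif discovery is out of scope.

The packaged 52-site fixture stores each motif's genomic strand resolved
geometrically under the upstream-localization convention (minus iff the
motif center exceeds the peak center), since the printed motif sequences are
given in motif orientation without strand. Both the all-sites median
(26.5 nt) and the median excluding the two flagged sites (25.5 nt) are
reported by the analysis, as it is not knowable which set a summary median
of ~25 nt was computed over.

## Regulon classification

A site is intragenic iff its center lies inside a gene's closed interval
(nearest midpoint on overlap); orientation is sense iff the site's motif
strand matches the host gene. Sites link to every gene whose start codon
lies within `association_window` (default 300 bp, the only
promoter-distance constant the underlying study states) downstream on
either side — divergent pairs give two links — and intragenic sites link to
their host gene as well. Significance is q ≤ 0.01 and fold ≥ 2, where fold
is (max + 1)/(min + 1); the pseudocount of 1 keeps fully collapsed targets
(normalized expression 0) finite while barely moving moderate values.
Genes then partition exactly into direct (significant + bound), indirect
(significant only), bound-unregulated (bound only) and unaffected. Operons
are consumed as an input table and reduced to their first gene for
expression lookup; operon inference is out of scope. Magnitude comparisons
use |log₂ fold| with an exact Mann-Whitney test for small untied samples
(asymptotic with tie correction otherwise) and Kruskal-Wallis for more than
two groups.

## qPCR quantification

Technical replicates are summarized by the mean Ct (median available),
ΔCt = Ct_target − Ct_reference per sample, raw abundance = base^(−ΔCt) with
base 1.9 by default (90% amplification efficiency; 2.0 restores the classic
2^(−ΔΔCt)), and outputs are divided by the mean raw abundance of the
calibrator samples, whose mean is therefore exactly 1. No-RT controls are
validated against a Ct floor (default 30 cycles) and excluded from
quantification. Outputs are shift-invariant under per-sample loading
differences and strictly decreasing in ΔCt.

## Synthetic data

The generator emulates the *statistical structure* the pipeline assumes,
not raw sequencing: triangular sub-peaks of half-width 50 bp on each
strand, summits separated by `strand_offset` (50 bp) and centered on spiked
sites at least `2·strand_offset + 2·half_width` apart; per-position Poisson
background (default mean 0.5); site heights Gamma-distributed around
`site_enrichment` and shared between replicates up to
`replicate_correlation` (0.9), with summits jittered ±5 bp per replicate;
artifacts built identically but present in tagged *and* control data.
Coverage is emitted near the normalized depth scale with per-dataset
library sizes drawn uniformly in [0.85, 1.2] × 10⁸ reads, so the 1-1000
integer threshold grid is meaningful after normalization exactly as it is
for real libraries of ~10⁸ reads. Explicit `site_centers` may be supplied
to build scenarios with sites shared between factors (dual regulation).
Defaults — a 200 kb genome, 10 sites, summit depth 100, background 0.5 —
are the study conditions of the test suite and acceptance script; they keep
a 200-simulation null calibration under a minute on one CPU.

The annotation generator draws ~1 kb lognormal gene lengths until the
coding target is met and splits the remainder into Dirichlet-sized gaps, so
the realized intergenic fraction is within rounding of the configured 0.11.
Expression tables plant fold changes of ≥ 100 (direct activated, collapsing
to 0-1 counts), ~6-15× increases (direct repressed), 2.2-4× (indirect) and
< 2× with q > 0.01 (unregulated); q-values are emitted calibrated rather
than computed, since the differential-expression model itself is consumed,
not reimplemented. Ct tables invert the quantification formula exactly,
plus Gaussian technical noise (default SD 0.05 cycles).

What passing tests therefore show: the caller recovers well-separated,
strongly enriched (~100× background) sites with ≤ half-a-strand-offset
center error and rejects pure noise at the configured FDR; they do not show
robustness to fragment-length variation, GC or mappability bias, copy-number
structure, or overlapping/composite peaks, none of which the generator
emulates.

## Known limitations

- The independence null is anti-conservative if replicate backgrounds are
  correlated (e.g. shared mappability artifacts); the circular-shift
  estimator is provided for checking, and the untagged control catches
  shared artifacts downstream.
- Greedy nearest-summit pairing is not globally optimal for dense clusters
  of adjacent sites; sites closer than the pairing distance can steal each
  other's strand regions.
- The threshold grid is integer-valued on the normalized scale; depths far
  outside [1, 1000] (heavily over- or under-sequenced libraries relative to
  the 10⁸-read target) would need a rescaled grid.
- The fixture's motif strands are resolved geometrically (see above); a
  genome-sequence resolution could in principle disagree for sites with
  near-zero offset.
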