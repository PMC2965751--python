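# Methods

## The analysis this package implements

`chiptile` reconstructs, as tested library code, the standard analysis
stack for ChIP-chip tiling-array occupancy data from a compact genome
(budding yeast is the motivating case): per-probe log2(IP/control) ratios
from a whole-genome array (~44k 60-mer probes, one probe every ~275 bp
± 100 bp) are turned into per-gene occupancy summaries, binding-class
clusters, metagene profiles and occupancy-vs-occupancy trend curves.
The stages, in pipeline order:

1. **Replicate combination.** Biological replicates of one experiment are
   median-centered per array and combined as a per-probe weighted average.
   The weights default to the inverse variance of each replicate's
   non-missing values (uniform fallback if any replicate has zero
   variance), renormalized per probe over the replicates actually
   measured there, so a probe is missing only when missing everywhere.
   User-supplied weights are accepted. The intent of inverse-variance
   weighting is to down-weight noisy arrays; it is not a probe-level
   error model, which raw two-color data would require upstream.
2. **Z-score standardization.** The combined track is standardized,
   z_i = (x_i − mean)/sd over all non-missing probes of the experiment
   (population sd). Different antibodies immunoprecipitate with very
   different efficiencies; standardization removes that scale so
   experiments can be compared and clustered together. Any positive
   rescaling of a track yields an identical Z-track (this invariance is
   tested). A median/MAD variant exists behind `robust=True`; it returns
   a plain track because median-0 data is not mean-0. Combination
   precedes standardization; for acetylation-minus-histone and
   mutant-minus-wild-type maps, `subtract_tracks` differences the log2
   tracks first and the difference is then standardized (the reverse
   order is a one-line change at the call site).
3. **Promoter/ORF summaries.** The promoter of a gene is the upstream
   region of length min(250 bp, floor(IG/2)) abutting its 5' boundary,
   where IG is the intergenic gap to the nearest neighboring annotation
   boundary (strand-aware; first/last genes measure to the chromosome
   edge, unbounded when the edge is unknown). The half-IG cap with floor
   division makes neighboring promoters provably disjoint, so no probe is
   double-counted; this is asserted rather than repaired. A probe belongs
   to a region iff its midpoint lies inside it ("no interpolation": a
   probe contributes fully or not at all), and the summary is the median
   Z of the contributing probes — missing, never zero, when there are
   none. Genes shorter than 500 bp are excluded from analysis, but the
   full annotation still defines the intergenic gaps (anatomy should not
   change because a short gene is unreportable). Length bins for
   stratified profiles are [750, 1500), [1500, 3000], (3000, ∞): the top
   bin is strictly ">3000", which forces 3000 into the middle bin, and
   the lower boundary ties go upward.
4. **SOM clustering.** Genes × (promoter Z, ORF Z per experiment)
   feature matrices are clustered with a classic one-dimensional Kohonen
   self-organizing map: codebook initialized from k distinct data rows
   (seeded), shuffled presentation each epoch, best-matching node by
   Euclidean distance, Gaussian neighborhood update with learning rate
   decaying linearly 0.05 → 0.005 and radius k/2 → 0.5 over 100 epochs.
   These hyperparameters follow the classical Kohonen regime and are all
   overridable; the seed is mandatory in the CLI. Only complete-case
   genes are clustered — a gene with any missing summary is dropped, not
   imputed. Cluster labels are arbitrary: every comparison in the tests
   uses the adjusted Rand index, never label identity.
5. **Metagene profiles.** Signal is mapped onto the 5' and 3' gene
   boundaries in 50 bp windows covering each half-gene plus the adjacent
   half-IG (positions strictly before length/2 belong to the 5' arm),
   and the arms reach min(500 bp, floor(IG/2)) into the intergenic
   regions so adjacent genes never share a probe. Aggregation is
   two-stage — probe values are averaged per gene per bin, then the
   across-genes mean (median optional) is taken — so probe-dense genes
   do not dominate. A centered 300 bp (6-bin) moving average smooths the
   curve, ignoring empty bins and shrinking at the arm ends; smoothing
   happens after aggregation, and per-bin gene counts propagate as the
   window minimum. The 500 bp default IG extent is a display choice, not
   a modeling claim.
6. **Trends.** Pearson correlation (scipy, over complete cases) and a
   sliding-median curve: genes sorted by the x feature (ties broken by
   gene id for determinism), windows of 300 consecutive genes, step 1,
   each emitting (median x, median y). Derived per-gene features are
   differences of summary columns (on the Z scale a difference plays the
   role of a log ratio); "transcribed" genes are those with polymerase
   ORF median Z strictly above 0, i.e. above-average occupancy.

## The synthetic-data generator

Because the real deposited arrays are not assumed available, every stage
is validated against a simulator whose defaults *are* the study
conditions: probe spacing 275 ± 100 bp (uniform jitter), 60-mer probes,
two biological replicates with efficiencies (1.0, 1.6), additive Gaussian
noise of sd 0.3 in log2-ratio units, 2% missing probes (the plausible
middle of a 1–5% failure range), log-normal gene lengths (median
~1400 bp, log-sd 0.6, clipped to [300, 6000] bp so the 500 bp filter and
all three length bins are exercised), and uniform intergenic gaps of
150–900 bp on two chromosomes. The noise and efficiency levels were
chosen once as representative of a decent two-color array experiment:
noise sd 0.3 against planted amplitudes of 1.5–2.0 gives per-probe
signal-to-noise of ~5–7, and a 1.6× efficiency spread is the kind of
difference Z-scoring exists to absorb.

Each gene carries one occupancy archetype: `promoter_only` (plateau 2.0
over the operational promoter), `promoter_orf` (promoter 2.0 plus uniform
ORF 1.5), `unbound` (zero), and `orf_ramp` (linear 0 → 1.5 ramp toward
the 3' end) in proportions 0.3/0.3/0.3/0.1. Signal decays exponentially
(length 150–200 bp) from the region boundaries into the gene-proximal
half-IGs and is zero elsewhere; the truth function is evaluated at probe
midpoints, which at 60 bp probes on a 275 bp grid differs negligibly from
footprint averaging while keeping the truth exactly invertible. Three
factors reuse the archetype assignment with factor-specific parameter
tables, playing the roles of a promoter+ORF deacetylase complex, its
ORF-restricted form, and elongating polymerase.

What the simulator deliberately does not model: probe sequence and Tm
effects, dye bias and spatial artifacts, nucleosome-level structure,
cryptic transcription, and overlapping genes. Passing tests therefore
demonstrate the *computational* correctness of the pipeline (geometry,
standardization, aggregation, recovery of well-separated planted
structure), not robustness to every artifact of real arrays. Mutant
conditions are expressible only as archetype re-assignment between
simulated factors, since no quantitative mutant effect model is assumed.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere in memory; GFF3 (1-based
  inclusive) is converted only at the file boundary. Overlapping genes
  are rejected at load: the half-IG rule is undefined for them.
- Missing values are NaN sentinels in memory and omitted rows in
  bedGraph; floats are printed with `repr` and re-read with round-trip
  parsing, so all I/O is lossless for non-missing data. Because written
  tracks drop missing probes, `align_to_union` re-grids replicates read
  from disk, turning absent probes back into NaN (genuinely conflicting
  intervals still error).
- The replicate-combination error test compares against truth with
  centering off and unit efficiencies: median-centering subtracts a
  signal-dependent offset from every track, which would bias any
  MSE-to-truth comparison identically for combined and single tracks
  without changing the ranking logic being tested.
- Z-scoring a constant track, clustering with missing values or k > n,
  profiling an empty gene set, and trend windows larger than the data
  all raise explicit validation errors rather than degrading silently.
- Zero-length promoters (abutting genes) are legal, flagged, and
  summarize to missing.

## Problem sizes

The packaged study uses 300 genes on two chromosomes (~5,000 probes) and
the property checks use 12–300 genes per replicate draw, 20 seeded runs
for clustering and replicate-combination expectations, and 50 draws of
n = 3000 for correlation recovery — sizes at which the planted effects
are comfortably detectable and the full suite runs in well under a
minute. The full pipeline on the packaged study completes in a few
seconds; all outputs are deterministic given the config and seed.

## Known limitations

- The SOM grid geometry and epoch count used by the original desktop
  clustering software are not public; at real-data scale, cluster
  boundaries may be sensitive to these hyperparameters. They are
  exposed, seeded and documented rather than guessed at.
- Inverse-variance replicate weights use total (signal + noise) variance;
  with very different true-signal variances across replicates this is a
  heuristic, not an optimal estimator.
- The promoter rule assigns each probe to at most one promoter by
  construction; annotations with overlapping genes must be resolved
  upstream.
- No GO enrichment, no genome-browser rendering, no binary track
  formats.
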