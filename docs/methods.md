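# Methods

This note documents the models, defaults and numerical choices behind each
analysis, what the synthetic generators do and do not emulate, and the
design decisions taken where conventions were genuinely open.

## Coordinates and formats

All genomic coordinates are 0-based half-open, internally and in bedgraph
(chrom, start, end, value).  Interval strings printed 1-based inclusive
(the convention of genome browsers and methods sections) are converted on
input via `GenomicInterval.from_one_based`.  Bedgraph reading rejects
overlapping records and malformed lines with their line number; writing
merges adjacent equal-value runs and omits zero-coverage runs.

## Spike-in ChIP normalization

Each sample culture contains a constant admixture of a spike strain whose
single *ade6*⁺ copy sits in pericentric heterochromatin, so the H3K9me2
ChIP signal over the *ade6* locus is a constant reference across samples.
The per-sample scale factor is S = c / (m_spike − m_ref) with c = 10 and
m_spike, m_ref the median per-base depths over the spike locus and the
adjacent euchromatic interval (defaults: chr III 1316291–1318035 and
1304000–1380000, 1-based).  Notes:

- The published reference interval *encloses* the spike locus (~2% of its
  length).  The median is insensitive to that overlap, so the interval is
  used as given; `exclude_spike_from_reference=True` removes the overlap
  for users who prefer a disjoint reference.
- S is undefined (and an error) when m_spike ≤ m_ref: that indicates a
  failed spike rather than a quantity to propagate silently.
- Normalization is multiplication by S only; no input-chromatin
  normalization is applied anywhere, by design.
- The formula is homogeneous of degree −1 in depth, so normalized tracks
  are invariant to rescaling all raw depths (sequencing depth cancels);
  this invariance is tested to 1e-9 relative tolerance.

Ribbon profiles use 250 bp windows.  The window step is configurable
(default 25 bp for smooth "sliding" ribbons; set step = window for
non-overlapping windows).  Per isolate, each window is summarized by the
mean per-base normalized depth (a per-isolate median is offered); the
across-isolate median, minimum and maximum of those summaries form the
ribbon.  Window means use cumulative sums, so profiling is linear in
region length.

Coverage computation treats every reported alignment location with full
weight (repetitive regions may contribute several reported hits per read);
it conserves total aligned bases exactly.

## Nuclear zoning assay

The nucleus is an ideal sphere of radius R (ellipsoids are out of scope).
Three concentric shells of equal volume are bounded by r₁ = R(2/3)^⅓ and
r₂ = R(1/3)^⅓; Zone I is the outermost shell, with depth
R(1 − (2/3)^⅓) ≈ 0.2200 µm at R = 1.74 µm.  A uniformly random locus lands
in Zone I with probability exactly 1/3, the null expectation of the assay.

- Boundary ties are assigned to the more peripheral zone (conservative
  toward Zone-I scoring).
- Loci measured up to 2% outside R are clamped to the surface
  (segmentation jitter); beyond that the observation is rejected.
- Cell-cycle stage comes from the nucleate count: binucleate = early/mid
  S phase, mononucleate = late S/G2; other counts are unclassifiable.
- Enrichment testing defaults to a one-sample two-tailed t-test on the
  per-cell Zone-I indicator pooled across replicates.  With a fixed null
  proportion this is an approximation; the exact binomial test (two-sided
  by tail doubling, capped at 1) is offered and is the recommended
  alternative, and is substituted automatically (with a note) when the
  indicator vector has zero variance.  The exact per-replicate test units
  used historically for such tables are not standardized, so both counts
  per replicate (n₁, n₂) and the pooled test are reported.
- Analysis operates on 3D coordinates; zones are volumetric.

## FRAP

Normalization: y(t) = (roi(t) − background(t)) / (pre_roi −
pre_background), background being an equal-size region beside the nucleus,
so the pre-bleach reference is 1.0.  Subtracting background from the
pre-bleach denominator keeps the series on a 0–1 scale; a "literal" mode
dividing by the raw pre-bleach ROI is provided.  No correction for
photobleaching during acquisition is applied.

Fitting: Y(t) = Y0 + (P − Y0)(1 − e^(−kt)) by bounded trust-region least
squares with k ∈ (1e-6, 1e3) s⁻¹.  Initialization is deterministic: Y0
from the first point, P from the mean of the last quartile, k from a
log-linear regression of (P̂ − y)/(P̂ − Ŷ0).  Reported quantities: k,
half-life ln2/k (the identity T½·k = ln 2 holds exactly), mobile fraction
P, and R² = 1 − SSres/SStot.  A flat series is flagged immobile (P = Y0)
with no R² rather than force-fitted; an estimate pinned at the rate bounds
is reported as an error.  No weighting or Y0 constraint is applied;
commercial fitters may differ in those respects.

## Dot detection and colocalization

Dots are connected components of pixels above a constant intensity
threshold (the same level across all images of an experiment) with at
least `min_size` pixels; centroids are intensity-weighted.  Matching is
one-to-one, greedy by ascending inter-centroid distance with a cutoff
(default 0.25 µm, below the ~300 nm lateral resolution of conventional
wide-field imaging); it is symmetric in channel order.  The nuclear
boundary is estimated from the diffuse nucleoplasmic fluorescence:
Gaussian smoothing, a bimodal intensity split minimizing intra-class
variance (Otsu — deterministic and parameter-free), largest component,
then a least-squares (Kåsa) circle fit to the boundary pixels; multiple
nucleus-sized components are flagged.  Analysis is 2D per z-plane.
Pearson colocalization is the plain correlation of (optionally masked)
pixel intensities.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume; all are bit-reproducible given a seed.

- **ChIP coverage**: expected depth per base is baseline × domain
  multiplier, with an additive spike contribution of baseline ×
  spike multiplier × mix fraction over the spike locus (culture fraction is
  assumed proportional to read fraction — a modeling choice, since mixing
  is by volume).  Defaults: baseline 10 reads/bp; multipliers euchromatin
  1, subtelomere 6, mat 6, pericentromere 8, spike 20; mix fraction 0.25
  (one part spike in four parts total); counts negative-binomial with
  variance μ + 0.05 μ² (Poisson at overdispersion 0).  The toy genome is
  280 kb across three chromosomes with one domain of each class — large
  enough for stable medians, small enough to simulate in well under a
  second.  No read-level FASTQ simulation or sequencing error model.
- **Nuclei**: loci are uniform in the sphere, or with probability
  `peripheral_bias` uniform within the outermost equal-volume shell, so
  the expected Zone-I fraction is bias + (1 − bias)/3.  Stage labels are
  generated directly from `stage_mix`; cells alternate between two
  replicates.
- **FRAP**: the normalized model curve plus Gaussian noise is embedded in
  raw ROI/background sums consistent with the normalization contract
  (constant background equal to the pre-bleach background).  Defaults
  emulate a fast-recovering NE protein: half-life 5.03 s, plateau 0.85,
  Y0 0.2, images every 2 s for 60 timepoints, 13 cells, noise sd 0.05.
- **Images**: two channels of Gaussian foci over a uniform nucleoplasmic
  disk with a Gaussian-profile envelope rim and Gaussian background noise.
  Optics are idealized (pure Gaussian PSF, no depth attenuation, no
  structured noise), so detection performance on these images bounds, but
  does not measure, performance on real micrographs.

Because the generators realize exactly the models the estimators assume,
passing tests demonstrate correctness of the computations and calibration
of the statistics under those models — not robustness to the artifacts of
real data (mappability, chromatin-state mosaicism, uneven illumination,
nuclear shape deviations).

## Problem sizes

Default analysis/test problem sizes — 280 kb genome, 3 isolates per
genotype, 10⁵ Monte-Carlo samples, 50-seed repetitions for power and
recovery checks, 96×96 px images — were chosen so the full suite runs in
well under a minute on one core while keeping Monte-Carlo standard errors
an order of magnitude below the tolerances being asserted.
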