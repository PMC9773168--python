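# Methods

## Strain metric

Circumferential strain on one short-axis slice is the fractional change of
the endocardial perimeter relative to end diastole, `ε_n = (L_n − L_0)/L_0`,
with frame 0 taken as end diastole. Perimeters are polygonal arc lengths of
the closed contour (no spline smoothing); because the metric is a ratio of
lengths it is invariant to rigid motion and — under uniform scaling of the
contour by `k` — equals `k − 1` regardless of cross-sectional shape, which
is why circular phantom sections suffice to validate it.

Slices are ordered base → apex (enforced by file metadata, never inferred)
and split into three regions: each region receives `⌊n/3⌋` slices and
remainder slices go to the base first, then the mid-ventricle, so 6→(2,2,2),
7→(3,2,2), 8→(3,3,2), 9→(3,3,3), 10→(4,3,3). Any rule respecting the
2–4 per-region bounds over 6–10 total slices is admissible; base-first was
chosen because basal slices are the largest and least affected by apical
truncation, and the rule is deterministic.

The reported regional value (ACS/MCS/BCS) is the minimum (most negative)
point of the frame-wise **mean curve** of the region's slices, ×100. The
alternative — mean of per-slice minima — is available via
`peak_of_mean=False`; for synchronous contraction the two coincide, and
under dyssynchrony the default is the attenuated (less negative) one, which
matches how a single regional curve would be read. GCS applies the same
construction to all slices, so for synchronous motion
`GCS = (n_b·BCS + n_m·MCS + n_a·ACS)/n` holds to machine precision.
The temporal peak rather than a fixed end-systolic frame is reported; for
the phantom's synchronous activation the two are identical.

## Volumes and indices

Cavity volume is slice summation: enclosed polygonal area × slice spacing,
summed. Spacing is thickness + gap = 10 mm, with each slice's area extruded
over the full spacing (the standard convention for gapped stacks). EDV is
the volume at frame 0 and ESV the cycle minimum. The pipeline computes
volumes from the contours themselves rather than consuming externally
supplied values, so volume and strain always refer to the same geometry.
BSA defaults to Du Bois (`0.007184·W^0.425·H^0.725`), the dominant
convention in CMR indexing; Mosteller is available because the underlying
convention in population reference studies is not standardised.

## Phantom generator

The generator defines the study conditions; its defaults are the published
group-level characteristics of a large population CMR cohort (healthy and
unhealthy columns of three age bands: means/SDs of age, heart rate, BMI,
weight, EDV, ACS, MCS, BCS).

**Geometry.** The cavity is a prolate semi-ellipsoid truncated at its
equatorial base plane, long semi-axis `a = n_slices × spacing`. Slice
planes sit at through-slice midpoints `z_s = (s+½)·spacing`, making the
slice sum a midpoint-rule quadrature of the analytic volume `⅔πR²a`; since
the squared radius profile is quadratic in `z`, the relative quadrature
error is `1/(8n²)` (≈0.2% at 8 slices) and shrinks with slice count. The
equatorial radius is solved so the *polygonal* slice-sum EDV equals the
subject's EDV draw exactly (the regular-n-gon area factor
`n·sin(2π/n)/(2π)` is accounted for), so jitter-free EDV recovery is exact.

**Motion.** Each slice is a material ring contracting as
`R_s(t) = R_s(0)·(1 − c_s·w(t))` with a raised-cosine activation `w` rising
0→1 by the end-systolic frame (40% of the cycle — a typical systolic
interval; configurable) and returning to 0 at the last frame. 25 frames
cover roughly one cycle at 31.56 ms resolution and ~60 bpm. Perimeter
linearity under uniform scaling makes the jitter-free peak slice strain
equal −c_s to machine precision — exact ground truth. Through-plane motion
is deliberately not modelled: it is a known confound of short-axis strain,
and omitting it is what makes the ground truth exact. Consequently, passing
recovery tests demonstrate the correctness of the measurement chain, not
robustness to long-axis shortening, papillary muscles or segmentation bias
in real images.

**Contraction sampling.** Per-region contraction fractions are
`c = −strain/100` draws from the configured regional strain normals,
truncated to strains in (−95, −5)% to keep the ring geometry non-degenerate
(`contraction_mode="regional"`, the default, so each configured regional
mean is recovered). A `"uniform"` mode draws a single `c` for all regions
when a homogeneous ventricle is wanted. Disease effects are explicit knobs —
a dilatation factor multiplying all end-diastolic radii and a contraction
deficit multiplying one region's `c` by (1 − deficit) — but default to
neutral because the unhealthy distribution columns already encode larger
EDV and weaker strain.

**Noise.** Contour jitter is zero-mean Gaussian *radial* perturbation with
pointwise SD 0.2 mm, band-limited to the 8 lowest Fourier modes around the
ring. Segmentation errors in practice are spatially smooth boundary
displacements; modelling them as independent per-vertex noise would
systematically lengthen the polygonal perimeter (≈ `σ²n²/(πr)` per
contour), biasing strain toward zero by ~2 strain-points at these settings,
whereas the band-limited model is unbiased to ≈0.1%. The correlation
structure among EDV, strain and body size defaults to independence; no
published joint structure was available to parameterise it.

**Reproducibility.** All randomness derives from one master seed via named
`SeedSequence` substreams (one per subject, split into attribute and cine
streams), so a cohort is byte-reproducible from config + seed.

## Cohort assembly

Inclusion mirrors the study rules: age 45–74, BMI 18.5–30 kg/m², no
diabetes, never-smokers, qualifying ethnicity; each exclusion is tagged
with its first failing rule. Age bands are closed and fractional ages are
floored (integer-year reporting). Stratification yields the 12 sex ×
age-band × health cells, with *unhealthy* defined by any of STEMI, NSTEMI
or heart-failure flags. Healthy cells are randomly downsampled to a fixed
size (default 100) without replacement; smaller cells pass through whole
with a warning.

Outlier removal is a single pass per group: first, volumes beyond 4× the
group median are dropped as data-entry errors; then any individual with any
analysis variable outside mean ± 2.7 SD (n−1 denominator) within the group
is removed whole. Within-group scope was chosen because group summaries are
the analysis unit; statistics are not recomputed after removals (no
re-iteration). Groups of fewer than 3 are skipped. Missing entries reduce a
variable's per-group n in summaries rather than failing.

## Statistical battery

* Initial **Student's t-tests** (pooled variance, not Welch) on all-healthy
  vs all-unhealthy and all-male vs all-female for each of the nine
  variables, α = 0.05.
* A per-variable **one-way ANOVA** over the 12 cells. Contrasts run only if
  the omnibus p ≤ 0.05.
* **17 planned contrasts** (within-sex age comparisons among healthy cells,
  sex-matched comparisons per band, age-matched healthy/unhealthy
  comparisons, and lumped unions). Lumped sides use equal ±1/k weights per
  constituent cell — the standard planned-contrast convention; per-cell-n
  weighting is a config option. The contrast SE uses the omnibus pooled
  within-group MSE with its within-group df (the classical ANOVA contrast);
  a touched-cells-only variant is available. The decision threshold is the
  *rounded* 0.05/17 = 0.003, reproducing the familywise rule as applied;
  the unrounded value is recoverable from `bonferroni_alpha` arguments.
* **Bootstrap**: percentile method, case resampling within each cell, 1000
  resamples by default, fully seeded. Bootstrap CIs accompany — never
  replace — the parametric p-values.
* **Pearson correlations** of each variable with age and BSA within the
  four lumped sex × health groups, p via the t-transform, with a flag when
  the bootstrap CI contradicts the parametric significance call.

Degenerate inputs are handled explicitly: zero pooled variance yields t = 0
and p = 1 for equal means and an infinite, flagged statistic otherwise;
per-test failures are collected as errors without aborting the batch.

## Problem sizes and numerical choices

The default synthetic composition mirrors the source selection (100 per
healthy cell; unhealthy cells at their observed sizes, 347 subjects total).
Validation suites use smaller cohorts chosen for statistical sufficiency:
parameter recovery at n ≈ 200 (3-SE criterion), null-calibration of the
gated battery at 2000 simulation replicates with 12 cells of 12, and
bootstrap coverage at 300–400 outer replicates of n = 100. Truncated-normal
draws use rejection sampling with a deterministic clamp after 10⁴ misses.
Contours are stored open (no repeated seam point), coordinates rounded to
10⁻⁶ mm on serialisation.

## Limitations

The phantom has circular (optionally elliptical) sections, synchronous
activation, no through-plane motion, no papillary muscles and no
strain–volume correlation; it validates the measurement and inference
chain, not image segmentation. No area-based apical slice exclusion is
applied. Infarct localisation is out of scope.
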