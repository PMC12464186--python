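# Methods

This note records the models, conventions and design decisions behind
the package, and what the synthetic validation does and does not show.

## OCTA vessel quantification

**Pipeline.** Each en-face angiogram passes, in order: quality gate →
multiscale Frangi vesselness → Otsu global threshold → strict
binarization (`value > threshold`) → optional morphological closing →
perimeter extraction and homotopic skeletonization (with optional spur
pruning) → branch decomposition → the nine indices. The stage order and
every convention below is fixed so that a rerun on identical input is
bit-identical.

**Frangi enhancement.** The vesselness at a pixel is the maximum over
the configured Gaussian scales of the Hessian-eigenvalue measure
(`skimage.filters.frangi`, blob sensitivity 0.5, contrast constant
defaulting to half the maximum Hessian norm per scale). The scikit-image
implementation in use scores bright and dark ridges identically, so the
bright-on-dark polarity is enforced per scale from the sign of the
dominant Hessian eigenvalue: a bright tubular structure has negative
curvature across its axis, and pixels whose dominant eigenvalue is
non-negative are zeroed. A constant image yields an all-zero response by
construction. Default scales are 1–4 px; the recovery experiments use
1.5–3 px, matched to the rendered capillary calibre of 3 px (the filter
scale should bracket the vessel radius; scales well above it produce
side-lobe responses beside sharp vessels).

**Thresholding and closing.** Otsu's threshold maximizes between-class
variance over a 256-bin histogram of the vesselness map; binarization is
strict, which fixes the integer reproducibility of all pixel-count
identities. The vesselness measure systematically dips where branches
meet (a junction is locally blob-like, not tubular), which can drop a
one-pixel band below the global threshold and disconnect the network. A
morphological closing with a 3×3 structuring element (`closing_radius`
= 1, configurable, 0 disables) restores this connectivity; it cannot
merge distinct vessels farther than two pixels apart.

**Perimeter.** A vessel pixel belongs to the perimeter iff it has at
least one 4-connected background neighbour, with the image border
counting as background. This is a pixel count, not a geometric contour
length: on a digital disk of radius 100 the resulting isoperimetric
quotient VCI is ≈ 0.81 rather than 1, because boundary-pixel counts
undercount the smooth circumference (a digital line at angle θ has
≈ L·max(|cos θ|, |sin θ|) pixels). The same applies to TVL, which is
defined as the skeleton pixel count to keep VDI = area/length an exact
integer identity.

**Skeleton morphometry.** Node classification on the skeleton uses
8-connectivity. Endpoints are pixels with exactly one true neighbour.
Junctions are pixels with degree ≥ 3 **and** at least three maximal runs
of true pixels around their cyclic 8-neighbour ring (crossing-number
refinement): the corner pixel of an L-bend has three neighbours but two
runs and is a path pixel. Adjacent junction pixels merge into a single
branchpoint (flood fill), so thick crossings count once. Branches are
walked deterministically from node to node, preferring orthogonal over
diagonal steps and lexicographically smaller pixels; this makes an
L-shaped 10-right/10-down path a single branch of geodesic length
exactly 20 (through the corner pixel) and Euclidean length 10√2.
Geodesic length weighs orthogonal steps 1 and diagonal steps √2;
pure cycles and isolated pixels are loop branches with zero Euclidean
length and are excluded from the tortuosity mean (the excluded count is
reported). AVL is TVL divided by the number of branches — the only
interpretation of "average vessel length" consistent with the branch
decomposition; alternatives are not provided.

**Spur pruning.** Thinning thick junctions leaves short terminal spurs,
and thresholding can leave small disconnected flecks. With
`min_branch_length > 0`, terminal branches shorter than the threshold
that hang off a junction are removed (keeping the junction pixel), as
are isolated fragments shorter than the threshold; junction-to-junction
connectors and genuine cycles are never pruned. The library default is 0
(off); the recovery experiments use 6 px.

## Synthetic angiograms

`generate_vascular_tree` grows binary branching trees on a cell grid
(one tree per cell, so trees never interact and density sweeps are
strictly additive). Branch headings are jittered within ±12° of an image
axis and children snap to the axis perpendicular to the parent's nearest
axis, so jitter never accumulates with depth; this keeps the skeleton
pixel count an essentially unbiased estimate of true arc length (the
undercount of oblique digital lines stays below ~3%). Tortuosity is a
sinusoidal perturbation along the branch normal with an integer number
of cycles, leaving both endpoints — and hence the recorded topology —
unchanged while increasing arc length in closed form. Candidate branches
that would leave their cell or come within a clearance (2·diameter +
6 px) of existing vessels are dropped, and the recorded ground truth
always reflects exactly what was grown.

`render_octa_image` rasterizes the centerlines with a flat-top
cross-profile `exp(−ln 2 · (d/r)⁴)` (d = distance to the centerline,
r = stroke radius): the half-maximum contour coincides exactly with the
crisp boolean raster used as area ground truth, while the ≈1 px soft
shoulder emulates the point-spread blur of real angiograms. This matters
scientifically: Hessian-based filters assume smooth ridge profiles and
behave pathologically on hard-edged bars (edge ripples, double
responses). Speckle is multiplicative Gaussian noise clipped to the
8-bit range — a deliberate simplification of OCT speckle statistics,
adequate for testing robustness of thresholding and averaging but not a
physical speckle model.

What passing these tests shows: the pipeline conventions are internally
consistent, the estimators hit exact topological and analytic targets in
their design regime (capillary-scale vessels, adequate contrast,
moderate noise). What they do not show: performance on real OCTA with
projection artifacts, motion lines, signal falloff, or a foveal
avascular zone — none of which the generator emulates.

## Lens opacimetry

Edge detection binarizes each B-scan (Otsu by default; a fixed threshold
can be configured) and takes the first and last foreground row per
column; columns without foreground (e.g. dropout artifacts) are marked
missing. Each surface is fitted by least squares with a quartic in the
lateral coordinate; samples whose residual against the *original* data
exceeds 3 × (1.4826 × median absolute residual) are replaced by their
fitted value and the fit repeats (at most 10 rounds, all constants
configurable). Replacement is implemented as exclusion from the refit —
an on-curve point leaves the least-squares optimum unchanged, and
judging deviation against the original samples at every round lets the
fit de-bias instead of anchoring to its first, contaminated solution. A
sub-millipixel floor on the robust scale keeps numerical rounding noise
from being flagged on clean data. With the multiplier set to infinity
the procedure reduces exactly to plain least squares.

The lens mask is the set of pixels strictly between the two fitted
curves over the contiguous central span of columns where both surfaces
were detected and the fitted anterior lies above the posterior — the
quartics are never extrapolated beyond their data, and near the lens
equator (where the surfaces meet) crossing fits are trimmed rather than
fatal. Whole-lens opacity is the mean intensity over the mask; nuclear
opacity is the mean over the intersection of the mask with an ellipse
centred at the mask centroid, semi-axes 25% of the lens lateral extent
and 30% of the central thickness (the clinical workflow's manual ROI
correction is replaced by these explicit parameters). Per eye, both
opacities are the arithmetic mean over the 15-scan radial series; no
inter-scan normalization is applied — averaging is the only mechanism
used against scan-to-scan intensity variation. A scan that cannot be
segmented aborts the eye and names the failing scan index.

## Cohort simulation

The cohort generator draws one row per eye with metric trajectories over
four visits (baseline T0 and three follow-ups), IOP per visit, surgical
parameters (CDE, phaco time, fluid volume) and lens/nuclear opacity.
Default per-metric visit means and between-eye SDs encode the study
conditions this package targets: a 46-eye cataract cohort whose
perfusion indices jump between T0 and the first postoperative week and
plateau thereafter, nuclear opacity 36.7 ± 13.7 PIU, whole-lens opacity
43.9 ± 6.3 PIU, CDE 2.9 ± 1.8 %s, IOP drifting from 16.1 to 13.0 mmHg.

The link between opacity and perfusion change is a bivariate-normal
construction: with opacity z-score z, the change at the configured
follow-up (default T3) is Δμ + σc(ρ z + √(1−ρ²) ε), so the population
Pearson correlation equals the target ρ exactly; σc defaults to half the
between-eye SD. ρ = ±1 uses a deterministic linear map of z (slope σc,
or 1 if σc = 0), and a target strictly between 0 and 1 with zero change
noise is rejected as infeasible. The change is computed from the
realized (0–255-clipped) opacity so the configured correlation is exact
in the stored variable. Intermediate visits get their own mean offsets
plus independent noise at a quarter of the between-eye SD. Subject
offsets at baseline induce the compound-symmetric within-subject
covariance under which the repeated-measures ANOVA's type-I error is
calibrated.

## Cohort statistics

The one-way within-subject ANOVA uses the textbook decomposition
(SS_time over column means, SS_subject over row means, SS_error as the
interaction); F = MS_time/MS_error with (k−1), (n−1)(k−1) degrees of
freedom. Mauchly's W is computed from the eigenvalues of the covariance
of orthonormal (Helmert) contrasts with the standard chi-square
approximation; when it rejects at the test's alpha (per metric, k ≥ 3),
both degrees of freedom are scaled by the Greenhouse–Geisser ε
(clamped to [1/(k−1), 1]). A design with no within-subject variation
returns F = 0, p = 1, and a singular contrast covariance disables the
sphericity machinery rather than failing. Shapiro–Wilk normality is
reported as a diagnostic only and gates nothing.

The correlation screen relates per-eye metric changes (configurable
delta, default T3 − T0; the alternative T1 − T0 is a parameter away) to
the six predictors via Pearson's r with the two-sided t-test p-value.
Raw p-values at α = 0.05 carry the significance flag, matching the
reporting style of the clinical tables this mirrors; a Holm-adjusted
column is emitted alongside for transparency but does not drive the
flag. Cells with fewer than three complete pairs or a constant variable
are marked unavailable, with n reported; eyes missing a needed value are
dropped from that cell only (complete-case per cell).

## Study pipeline

`simulate_study` writes a study tree (`eyes/<id>/<visit>/<plexus>.png`,
`eyes/<id>/lens/scan-NN.png`, `clinical.csv`) with JSON ground-truth
sidecars; rendered tree density follows each eye's target vessel density
monotonically, so image-level analysis inherits the configured
opacity–change correlation. `run_study` consumes the same layout,
applies the quality gate, quantifies every angiogram, measures the
radial lens series, assembles the longitudinal table (measured opacity
superseding the clinical column) and writes the summary tables plus a
structured event log (missing images, gate rejections, segmentation
failures). Outputs embed a configuration hash and are byte-identical
across reruns.

## Problem sizes and numerical choices

Validation runs at desk scale by choice: 300×300 px angiograms with
trees of 1–7 branch levels, 160–192 px B-scans, cohorts of 46 eyes
(type-I calibration over 1000 replicates) and 200 eyes (correlation
recovery, where the Fisher-z interval is usefully narrow). End-to-end
image-level tests use 128 px images and a handful of eyes; the
cohort-level statistics always run at full study size. Known
limitations: pixel-count length metrics undercount oblique structures
(by design, documented above); the speckle model is not physical; the
generator's vessels do not branch at acute angles or cross, so the
pipeline's behaviour on anastomotic capillary meshes is exercised only
through the loop-handling paths; and the opacity–perfusion link in the
simulator is linear-Gaussian, so the correlation screen is validated
for monotone linear association only.
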