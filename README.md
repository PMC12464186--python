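# ocumetrics

Quantitative analysis of ocular OCT imaging around cataract surgery:
**en-face OCT-angiography (OCTA) macular-perfusion metrics**, **AS-OCT
crystalline-lens opacimetry**, and the **longitudinal cohort statistics**
that relate preoperative lens opacity to postoperative perfusion change.
Because clinical OCT images of this kind are generally not shareable, the
package ships first-class synthetic generators — vascular trees,
lens B-scans and longitudinal cohorts — with analytically known ground
truth, so every stage of the pipeline is validated end-to-end against
exact targets.

It is written for researchers in ophthalmic imaging who want a tested,
scriptable re-implementation of the usual custom MATLAB workflow for
angiogram binarization and vessel morphometry, plus densitometric lens
grading and the standard repeated-measures statistics.

## The metrics

From a grayscale en-face angiogram *I(x, y)* the pipeline computes a
vessel map *A* (Frangi vesselness → Otsu threshold → binarization), a
skeleton *S* (homotopic thinning) and a perimeter map *P* (vessel pixels
with a 4-connected background neighbour). Nine indices follow:

| index | definition | meaning |
|---|---|---|
| VAD | ΣA / ΣI | vessel area density |
| VDI | ΣA / ΣS | vessel diameter index (dilation) |
| VPI | ΣP / ΣA | vessel perimeter index (dropout) |
| BVT | mean over branches of geodesic / Euclidean length | tortuosity |
| VCI | (ΣP)² / (4π ΣA) | vessel complexity |
| BP, EP | branchpoint / endpoint counts on *S* | network topology |
| TVL | ΣS (skeleton pixel count) | total vessel length |
| AVL | TVL / branch count | average vessel length |

All ratio definitions are exact integer identities on the pixel counts.
Branches are node-to-node skeleton segments (8-connectivity; geodesic
steps weigh 1 orthogonally and √2 diagonally); loops are excluded from
BVT. Images below the device quality-index gate (default 30) are
rejected.

Lens opacity is densitometric: each AS-OCT B-scan is thresholded, the
anterior and posterior lens surfaces are fitted with fourth-order
polynomials with robust correction of deviating edge samples, and the
mean pixel intensity (0–255, "PIU") between the fitted surfaces is the
whole-lens opacity; an elliptical ROI centred on the segmented lens
yields the nuclear opacity. Both are averaged over a radial series of 15
B-scans per eye. Cumulative dissipated energy is
CDE (%s) = mean phaco power (%) × phaco time (s).

Cohort statistics: per metric and plexus a one-way repeated-measures
ANOVA across the four visits (Mauchly sphericity test,
Greenhouse–Geisser correction when rejected), and a Pearson screen of
metric changes against lens opacity, nuclear opacity, CDE, IOP change,
phaco time and irrigation fluid volume.

## Worked example

```python
from ocumetrics import generate_vascular_tree, render_octa_image, quantify, QuantConfig

tree = generate_vascular_tree(depth=3, seed=7)          # known topology
image = render_octa_image(tree, quality_index=35)        # clean angiogram
config = QuantConfig(frangi_scales=(1.5, 2.0, 2.5, 3.0), min_branch_length=6.0)
metrics = quantify(image, config)
print(tree.true_counts, round(tree.true_centerline_length, 1))
print(metrics.bp, metrics.ep, metrics.tvl)
```

prints

```
{'bp': 3, 'ep': 5} 378.9
3 5 376
```

— the pipeline recovers the generated tree's 3 branchpoints and 5
endpoints exactly, and its skeleton length (376 px) sits within 1% of
the true centerline arc length. The full metric set for this image is
`VAD=0.0172, VDI=4.112, VPI=0.481, BVT=1.047, VCI=28.42, AVL=53.71`.

Lens opacimetry on a synthetic radial series (cortex 44 PIU, nucleus 37
PIU, 15% multiplicative speckle):

```python
from ocumetrics.synthetic import make_lens_scene, generate_lens_series
from ocumetrics.lens import lens_opacity_from_series

scene = make_lens_scene(cortex_intensity=44.0, nucleus_intensity=37.0, speckle_sigma=0.15)
result = lens_opacity_from_series(generate_lens_series(scene, seed=1))
print(round(result.lens_opacity, 2), round(result.nuclear_opacity, 2))
```

prints `42.11 37.83` — within 0.02 PIU of the scene's analytic
area-weighted mean (42.13 PIU).

## Command line

```bash
ocumetrics simulate-study --out study/ --n-eyes 46 --seed 1
ocumetrics run-study --study-root study/ --out-dir results/ --min-branch-length 6
ocumetrics quantify-octa --input images/ --out metrics.csv --min-quality 30
ocumetrics lens-opacity --scans eye01/lens/ --out lens.csv
ocumetrics cohort-stats --cohort cohort.csv --delta T0:T3 --out-dir stats/
```

`run-study` writes per-image metrics, per-eye opacities, the assembled
longitudinal cohort table, a per-visit ANOVA summary table and the
change-vs-predictor correlation table, plus a structured log of
quality-gate rejections and exclusions.

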