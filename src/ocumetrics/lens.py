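"""AS-OCT crystalline-lens opacimetry.

Lens opacity is measured densitometrically from anterior-segment OCT
B-scans: the scan is binarized with a global threshold, the first and
last foreground rows of each column sample the anterior and posterior
lens surfaces, and a fourth-order polynomial is fitted to each surface
with iterative correction of substantially deviating samples (robust to
local segmentation failures from artifacts or signal falloff). The mean
pixel intensity (0-255 scale, "pixel intensity units", PIU) of the
region between the fitted surfaces is the whole-lens opacity; the mean
inside an elliptical region of interest centered on the segmented lens
is the nuclear opacity. Per eye, both are averaged over a radial series
of B-scans (15 by default) to absorb scan-to-scan intensity variation.

Cumulative dissipated energy (CDE) of the phacoemulsification is the
product of average power (%) and phaco time (s), in %s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .images import ASOCTScan
from .octa import DegenerateInputError, otsu_threshold


class SegmentationError(ValueError):
    """Lens segmentation failed on a scan."""


class GeometryError(ValueError):
    """Fitted surfaces violate the lens geometry."""


MISSING = -1  # per-column marker for "no foreground in this column"


@dataclass
class SurfaceFit:
    """Quartic fit of one lens surface: depth (row) as a function of the
    lateral coordinate (column), in pixels."""

    coeffs: np.ndarray  # 5 coefficients, highest power first (np.polyval order)
    inlier_count: int
    residual_scale: float
    corrected_points: int
    columns: np.ndarray  # columns the fit used (non-missing samples)
    converged: bool = True

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (5,):
            raise ValueError("a quartic surface fit has exactly 5 coefficients")
        if self.inlier_count < 5:
            raise ValueError("fit must rest on at least 5 samples")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(x, dtype=float))


@dataclass
class LensMask:
    """Boolean lens region: pixels strictly between the fitted surfaces."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class EllipseROI:
    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (a, b) pixels
    rotation: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        cx, cy = self.center
        a, b = self.semi_axes
        xs = np.arange(w, dtype=float)[None, :] - cx
        ys = np.arange(h, dtype=float)[:, None] - cy
        ct, st = math.cos(self.rotation), math.sin(self.rotation)
        u = xs * ct + ys * st
        v = -xs * st + ys * ct
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass
class LensOpacityResult:
    """Whole-lens and nuclear opacity of one eye, in PIU (0-255)."""

    lens_opacity: float
    nuclear_opacity: float
    per_scan_lens: list[float]
    per_scan_nucleus: list[float]
    corrected_points: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.lens_opacity, self.nuclear_opacity):
            if not 0.0 <= v <= 255.0:
                raise ValueError("opacity must lie in [0, 255]")
        if abs(self.lens_opacity - float(np.mean(self.per_scan_lens))) > 1e-9:
            raise ValueError("lens_opacity must equal the mean of per-scan values")


@dataclass
class LensConfig:
    """Opacimetry tunables.

    threshold : fixed binarization threshold, or None for Otsu per scan.
    deviation_k : samples beyond ``deviation_k`` robust scales (1.4826 x
        median absolute residual) from the quartic are replaced by their
        fitted value and the fit repeated (max ``max_iter`` rounds).
    nucleus_width_frac / nucleus_thickness_frac : semi-axes of the auto
        nuclear ellipse as fractions of the lens lateral extent and of
        the central lens thickness.
    n_scans : required length of the radial series (15 as acquired).
    """

    threshold: float | None = None
    deviation_k: float = 3.0
    max_iter: int = 10
    nucleus_width_frac: float = 0.25
    nucleus_thickness_frac: float = 0.30
    n_scans: int = 15


def detect_lens_edges(scan: ASOCTScan, threshold: float | None = None) -> np.ndarray:
    """Per-column (anterior_y, posterior_y) surface samples.

    Binarizes at ``threshold`` (Otsu when None) and takes, per column,
    the first and last foreground rows. Columns without foreground (for
    instance zeroed artifact columns) carry the MISSING marker.

    Returns an array of shape (width, 2).
    """
    img = scan.pixels
    if threshold is None:
        threshold = otsu_threshold(img)
    fg = img > threshold
    if not fg.any():
        raise SegmentationError("no foreground after thresholding: segmentation failed")
    h, w = fg.shape
    samples = np.full((w, 2), MISSING, dtype=int)
    any_fg = fg.any(axis=0)
    first = np.argmax(fg, axis=0)
    last = h - 1 - np.argmax(fg[::-1], axis=0)
    samples[any_fg, 0] = first[any_fg]
    samples[any_fg, 1] = last[any_fg]
    return samples


def fit_surface_polynomial(
    columns: np.ndarray,
    depths: np.ndarray,
    deviation_k: float = 3.0,
    max_iter: int = 10,
) -> SurfaceFit:
    """Quartic least squares with iterative correction of deviating points.

    Points whose residual exceeds ``deviation_k`` times the robust
    residual scale (1.4826 x median absolute residual) are replaced by
    their fitted value — not dropped, so every column keeps a sample —
    and the fit repeats until no replacements occur or ``max_iter`` is
    reached. ``deviation_k = inf`` reduces to plain least squares.
    """
    x = np.asarray(columns, dtype=float)
    y_orig = np.asarray(depths, dtype=float)
    valid = y_orig != MISSING
    x, y_orig = x[valid], y_orig[valid]
    if len(x) < 5:
        raise DegenerateInputError("quartic fit needs at least 5 surface samples")
    converged = False
    coeffs = np.polyfit(x, y_orig, 4)
    scale = 0.0
    deviating = np.zeros(len(x), dtype=bool)
    for _ in range(max_iter):
        fitted = np.polyval(coeffs, x)
        # deviation is always judged against the original samples, so a
        # replacement is revisited as the fit de-biases
        resid = y_orig - fitted
        scale = 1.4826 * float(np.median(np.abs(resid)))
        if not math.isfinite(deviation_k):
            deviating = np.zeros(len(x), dtype=bool)
            converged = True
            break
        # the sub-millipixel floor keeps numerical rounding noise from
        # being flagged as deviation on noiseless data
        new_deviating = np.abs(resid) > max(deviation_k * scale, 1e-3)
        if (~new_deviating).sum() < 5:
            break  # correction would leave the fit underdetermined
        # a deviating sample takes its fitted value, which is equivalent
        # to refitting without it (an on-curve point leaves the least-
        # squares optimum unchanged) and avoids anchoring the fit to its
        # own bias while the correction is still converging
        coeffs = np.polyfit(x[~new_deviating], y_orig[~new_deviating], 4)
        if (new_deviating == deviating).all():
            deviating = new_deviating
            converged = True
            break
        deviating = new_deviating
    return SurfaceFit(
        coeffs=coeffs,
        inlier_count=len(x),
        residual_scale=scale,
        corrected_points=int(deviating.sum()),
        columns=x.astype(int),
        converged=converged,
    )


def build_lens_mask(
    anterior: SurfaceFit,
    posterior: SurfaceFit,
    shape: tuple[int, int],
    lateral_extent: tuple[int, int] | None = None,
) -> LensMask:
    """Pixels strictly between the fitted surfaces over the extent.

    The lateral extent defaults to the columns both fits rested on
    (no extrapolation of the quartics beyond their data).
    """
    h, w = shape
    if lateral_extent is None:
        common = np.intersect1d(anterior.columns, posterior.columns)
        if common.size == 0:
            raise GeometryError("surface fits share no columns")
        cols = common[(common >= 0) & (common < w)]
    else:
        lo, hi = lateral_extent
        cols = np.arange(max(0, lo), min(w, hi + 1))
    ya = anterior(cols)
    yp = posterior(cols)
    if (ya >= yp).any():
        raise GeometryError("surfaces cross within the lateral extent")
    rows = np.arange(h, dtype=float)[:, None]
    mask = np.zeros((h, w), dtype=bool)
    mask[:, cols] = (rows > ya[None, :]) & (rows < yp[None, :])
    return LensMask(mask)


def mean_opacity(scan: ASOCTScan, mask: LensMask) -> float:
    """Mean pixel intensity (PIU) of the scan over the lens mask."""
    if mask.area == 0:
        raise SegmentationError("empty lens mask")
    return float(scan.pixels[mask.pixels].mean())


def auto_nucleus_roi(mask: LensMask, config: LensConfig | None = None) -> EllipseROI:
    """Ellipse centered at the mask centroid, axes set as configured
    fractions of the lens lateral extent and central thickness."""
    config = config or LensConfig()
    if mask.area == 0:
        raise SegmentationError("empty lens mask")
    rows, cols = np.nonzero(mask.pixels)
    cy, cx = float(rows.mean()), float(cols.mean())
    lateral = float(cols.max() - cols.min() + 1)
    center_col = int(round(cx))
    col_rows = rows[cols == center_col]
    thickness = float(col_rows.max() - col_rows.min() + 1) if col_rows.size else float(
        rows.max() - rows.min() + 1
    )
    return EllipseROI(
        center=(cx, cy),
        semi_axes=(config.nucleus_width_frac * lateral, config.nucleus_thickness_frac * thickness),
        rotation=0.0,
    )


def nucleus_roi(
    scan: ASOCTScan, mask: LensMask, roi: EllipseROI | None = None, config: LensConfig | None = None
) -> float:
    """Mean intensity (PIU) inside ellipse ROI intersected with the lens mask.

    ``roi=None`` places the ellipse automatically at the center of the
    segmented lens (the manual-correction step of the clinical workflow
    is replaced by explicit parameters).
    """
    if roi is None:
        roi = auto_nucleus_roi(mask, config)
    sel = roi.mask(scan.pixels.shape) & mask.pixels
    if not sel.any():
        raise SegmentationError("nuclear ROI does not intersect the lens mask")
    return float(scan.pixels[sel].mean())


def segment_lens(scan: ASOCTScan, config: LensConfig | None = None) -> tuple[SurfaceFit, SurfaceFit, LensMask]:
    """Edge detection + robust quartic fits + mask for one B-scan."""
    config = config or LensConfig()
    samples = detect_lens_edges(scan, config.threshold)
    cols = np.arange(samples.shape[0])
    anterior = fit_surface_polynomial(cols, samples[:, 0], config.deviation_k, config.max_iter)
    posterior = fit_surface_polynomial(cols, samples[:, 1], config.deviation_k, config.max_iter)
    # restrict to the contiguous central span where the fitted lens is
    # open; at the lens equator the two surfaces meet and the quartics
    # may cross just inside the outermost detected columns
    common = np.intersect1d(anterior.columns, posterior.columns)
    open_mask = anterior(common) < posterior(common)
    if not open_mask.any():
        raise GeometryError("fitted surfaces enclose no region")
    runs = np.split(common[open_mask], np.where(np.diff(common[open_mask]) != 1)[0] + 1)
    span = max(runs, key=len)
    mask = build_lens_mask(
        anterior, posterior, scan.pixels.shape, lateral_extent=(int(span[0]), int(span[-1]))
    )
    return anterior, posterior, mask


def lens_opacity_from_series(
    scans: list[ASOCTScan], config: LensConfig | None = None
) -> LensOpacityResult:
    """Whole-lens and nuclear opacity of an eye from its radial series.

    Each scan is segmented independently; the eye-level opacities are
    the arithmetic means of the per-scan values. A scan that cannot be
    segmented aborts the eye with its scan index (the clinical protocol
    repeats the examination in that case).
    """
    config = config or LensConfig()
    if len(scans) != config.n_scans:
        raise ValueError(f"expected a series of {config.n_scans} B-scans, got {len(scans)}")
    per_lens: list[float] = []
    per_nuc: list[float] = []
    corrected: list[int] = []
    for scan in scans:
        try:
            anterior, posterior, mask = segment_lens(scan, config)
            per_lens.append(mean_opacity(scan, mask))
            per_nuc.append(nucleus_roi(scan, mask, None, config))
            corrected.append(anterior.corrected_points + posterior.corrected_points)
        except (SegmentationError, GeometryError, DegenerateInputError) as exc:
            raise SegmentationError(
                f"scan_index {scan.scan_index}: {exc}"
            ) from exc
    return LensOpacityResult(
        lens_opacity=float(np.mean(per_lens)),
        nuclear_opacity=float(np.mean(per_nuc)),
        per_scan_lens=per_lens,
        per_scan_nucleus=per_nuc,
        corrected_points=corrected,
    )


def compute_cde(avg_power: float, phaco_time: float) -> float:
    """Cumulative dissipated energy: average phaco power (%) x time (s), in %s."""
    if avg_power < 0 or phaco_time < 0:
        raise ValueError("power and time must be non-negative")
    return float(avg_power) * float(phaco_time)
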