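"""Synthetic OCTA angiograms, AS-OCT lens B-scans and longitudinal cohorts.

The study design this package analyses — en-face angiograms of three
retinal plexuses at four visits plus a radial AS-OCT series of the
crystalline lens per eye — has no public raw data, so validation runs on
synthetic scenes with analytically known ground truth:

* :func:`generate_vascular_tree` builds branching centerline trees whose
  topology (branchpoint/endpoint counts), arc length and tortuosity are
  recorded exactly; :func:`render_octa_image` rasterizes them as
  bright-vessel-on-dark angiograms with optional multiplicative speckle.
* :func:`generate_lens_bscan` renders a crystalline-lens B-scan bounded
  by two quartic surfaces, with a brighter elliptical nucleus, speckle
  and optional zeroed artifact columns.
* :func:`generate_cohort` draws a longitudinal per-eye table with a
  perfusion jump after surgery and a configurable correlation between
  nuclear opacity and the metric change, via a bivariate-normal
  construction whose population correlation equals the target exactly.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ASOCTScan, EnFaceImage

# --------------------------------------------------------------------------
# cohort condition tables: per (metric, plexus) the four visit means and the
# between-eye SD, emulating the magnitudes of a 46-eye cataract cohort
# --------------------------------------------------------------------------

METRICS = ("vad", "vdi", "vpi", "bvt", "vci", "bp", "tvl", "avl", "ep")
PLEXUSES = ("SVP", "ICP", "DCP")
TIMEPOINTS = ("T0", "T1", "T2", "T3")

#: (mean_T0, mean_T1, mean_T2, mean_T3, between-eye SD)
DEFAULT_METRIC_PARAMS: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("vad", "SVP"): (0.32, 0.34, 0.34, 0.35, 0.04),
    ("vad", "ICP"): (0.22, 0.24, 0.23, 0.24, 0.04),
    ("vad", "DCP"): (0.20, 0.22, 0.22, 0.22, 0.04),
    ("vdi", "SVP"): (3.83, 3.78, 3.77, 3.72, 0.18),
    ("vdi", "ICP"): (3.06, 3.07, 3.07, 3.06, 0.09),
    ("vdi", "DCP"): (2.64, 2.63, 2.64, 2.62, 0.05),
    ("vpi", "SVP"): (0.70, 0.70, 0.70, 0.71, 0.03),
    ("vpi", "ICP"): (0.91, 0.90, 0.90, 0.90, 0.01),
    ("vpi", "DCP"): (0.95, 0.95, 0.95, 0.95, 0.01),
    ("bvt", "SVP"): (1.25, 1.26, 1.26, 1.27, 0.03),
    ("bvt", "ICP"): (1.24, 1.25, 1.25, 1.25, 0.02),
    ("bvt", "DCP"): (1.25, 1.25, 1.25, 1.26, 0.02),
    ("vci", "SVP"): (3151.0, 3305.0, 3369.0, 3474.0, 476.0),
    ("vci", "ICP"): (3528.0, 3807.0, 3797.0, 3918.0, 589.0),
    ("vci", "DCP"): (3584.0, 3968.0, 3930.0, 4047.0, 640.0),
    ("bp", "SVP"): (1142.0, 1329.0, 1355.0, 1408.0, 345.0),
    ("bp", "ICP"): (628.0, 734.0, 714.0, 752.0, 173.0),
    ("bp", "DCP"): (728.0, 900.0, 861.0, 913.0, 220.0),
    ("tvl", "SVP"): (19465.0, 20690.0, 21010.0, 21592.0, 3127.0),
    ("tvl", "ICP"): (15189.0, 16784.0, 16789.0, 17447.0, 3147.0),
    ("tvl", "DCP"): (15278.0, 17505.0, 17367.0, 17989.0, 3305.0),
    ("avl", "SVP"): (14.70, 14.77, 14.79, 14.84, 1.06),
    ("avl", "ICP"): (11.97, 12.51, 12.60, 12.76, 0.97),
    ("avl", "DCP"): (11.23, 11.79, 11.95, 12.03, 0.89),
    ("ep", "SVP"): (1870.0, 1766.0, 1755.0, 1714.0, 306.0),
    ("ep", "ICP"): (3453.0, 3422.0, 3389.0, 3430.0, 292.0),
    ("ep", "DCP"): (4034.0, 4003.0, 3931.0, 3976.0, 382.0),
}

#: IOP (mmHg) mean per visit and SDs
DEFAULT_IOP_MEANS = (16.08, 15.40, 14.29, 12.96)
DEFAULT_IOP_SDS = (3.26, 4.52, 2.44, 2.95)

#: nuclear / whole-lens opacity (PIU), CDE (%s), phaco time (s), fluid (ml)
DEFAULT_NUCLEAR_OPACITY = (36.71, 13.67)
DEFAULT_LENS_OPACITY = (43.92, 6.27)
DEFAULT_CDE = (2.89, 1.80)
DEFAULT_PHACO_TIME = (213.35, 117.81)
DEFAULT_FLUID = (41.91, 12.92)


class ParameterError(ValueError):
    """Invalid or infeasible generator parameters."""


class GeometryError(ValueError):
    """Scene geometry violates a rendering precondition."""


# ==========================================================================
# Vascular trees
# ==========================================================================


@dataclass
class VesselTreeTruth:
    """Exact ground truth for a synthetic vascular network.

    ``branches`` are centerline polylines in (x, y) pixel coordinates;
    ``diameters`` the per-branch stroke widths. ``topology`` lists the
    network nodes with their degree (1 = endpoint, >= 3 = branchpoint).
    """

    branches: list[np.ndarray]
    diameters: list[float]
    topology: list[dict]
    true_counts: dict[str, int]
    true_centerline_length: float
    tortuosity_params: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for poly in self.branches:
            if len(poly) < 2:
                raise ParameterError("every centerline polyline needs >= 2 points")
        for d in self.diameters:
            if d < 1:
                raise ParameterError("stroke diameters must be >= 1 pixel")
        ep = sum(1 for n in self.topology if n["degree"] == 1)
        bp = sum(1 for n in self.topology if n["degree"] >= 3)
        if ep != self.true_counts["ep"] or bp != self.true_counts["bp"]:
            raise ParameterError("true_counts inconsistent with node degrees")

    @property
    def branch_tortuosities(self) -> list[float]:
        """Per-branch arc length / endpoint chord length ratios."""
        out = []
        for poly in self.branches:
            arc = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
            chord = float(np.linalg.norm(poly[-1] - poly[0]))
            out.append(arc / chord if chord > 0 else math.inf)
        return out

    def to_json(self) -> str:
        payload = {
            "branches": [poly.tolist() for poly in self.branches],
            "diameters": list(self.diameters),
            "topology": [
                {"xy": list(map(float, n["xy"])), "degree": int(n["degree"])}
                for n in self.topology
            ],
            "true_counts": {k: int(v) for k, v in self.true_counts.items()},
            "true_centerline_length": float(self.true_centerline_length),
            "tortuosity_params": [list(map(float, t)) for t in self.tortuosity_params],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "VesselTreeTruth":
        d = json.loads(text)
        return cls(
            branches=[np.asarray(p, dtype=float) for p in d["branches"]],
            diameters=[float(x) for x in d["diameters"]],
            topology=[{"xy": tuple(n["xy"]), "degree": int(n["degree"])} for n in d["topology"]],
            true_counts={k: int(v) for k, v in d["true_counts"].items()},
            true_centerline_length=float(d["true_centerline_length"]),
            tortuosity_params=[tuple(t) for t in d["tortuosity_params"]],
        )


def _branch_polyline(
    start: np.ndarray,
    heading: float,
    length: float,
    amplitude: float,
    cycles: float,
    step: float = 0.5,
) -> np.ndarray:
    """Straight segment with a sinusoidal normal perturbation.

    Integer ``cycles`` keep both endpoints exactly on the straight chord,
    so node positions (and hence the topology) are unaffected by the
    tortuosity injection.
    """
    n = max(2, int(math.ceil(length / step)) + 1)
    s = np.linspace(0.0, length, n)
    u = np.array([math.cos(heading), math.sin(heading)])
    nvec = np.array([-u[1], u[0]])
    pts = start[None, :] + s[:, None] * u[None, :]
    if amplitude > 0:
        pts = pts + (amplitude * np.sin(2 * math.pi * cycles * s / length))[:, None] * nvec[None, :]
    return pts


def _min_dist_to_points(poly: np.ndarray, cloud: np.ndarray) -> float:
    if cloud.size == 0:
        return math.inf
    # chunk to bound memory on large clouds
    best = math.inf
    for i in range(0, len(poly), 256):
        seg = poly[i : i + 256]
        d = np.linalg.norm(seg[:, None, :] - cloud[None, :, :], axis=2)
        best = min(best, float(d.min()))
    return best


def generate_vascular_tree(
    depth: int = 3,
    n_trees: int = 1,
    canvas_size: tuple[int, int] = (300, 300),
    diameter: float = 3.0,
    trunk_frac: float = 0.30,
    length_decay: float = 0.68,
    tortuosity_amplitude: float = 0.0,
    tortuosity_cycles: float = 2.0,
    heading_jitter_deg: float = 12.0,
    clearance: float | None = None,
    grid_cells: int | None = None,
    seed: int = 0,
) -> VesselTreeTruth:
    """Grow one or more binary branching trees with exact ground truth.

    Each tree starts from a trunk whose heading is a jittered image axis;
    children leave perpendicular to their parent, so branch headings stay
    within ``heading_jitter_deg`` of an axis. Candidate branches that
    would leave their allotted cell or collide with existing vessels are
    dropped (the recorded topology always matches what is grown).

    Parameters
    ----------
    depth : levels of branching; 1 gives a single unbranched trunk.
    n_trees : number of independent trees, laid out on a grid of cells.
    diameter : stroke width in pixels applied to every branch.
    tortuosity_amplitude : sinusoidal normal perturbation amplitude (px).
    tortuosity_cycles : whole sine cycles per branch.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    if n_trees < 1:
        raise ParameterError("n_trees must be >= 1")
    if diameter < 1:
        raise ParameterError("diameter must be >= 1 pixel")
    if tortuosity_amplitude < 0:
        raise ParameterError("tortuosity_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = canvas_size
    # a fixed grid_cells makes density sweeps strictly additive: trees
    # 1..k are identical whatever n_trees is, each new tree adds vessels
    ncells = grid_cells if grid_cells is not None else int(math.ceil(math.sqrt(n_trees)))
    if ncells**2 < n_trees:
        raise ParameterError("grid_cells**2 must be >= n_trees")
    cell_w, cell_h = w / ncells, h / ncells
    margin = max(4.0, diameter + 2.0)
    if clearance is None:
        # keep strokes far enough apart that multiscale enhancement cannot
        # bridge the gap between unrelated branches
        clearance = 2.0 * diameter + 6.0
    jit = math.radians(heading_jitter_deg)

    branches: list[np.ndarray] = []
    diameters: list[float] = []
    tort_params: list[tuple[float, float]] = []
    node_children: list[int] = []  # surviving children per branch-end node
    node_pos: list[tuple[float, float]] = []
    root_pts: list[tuple[float, float]] = []
    cloud = np.empty((0, 2))

    def in_cell(pts: np.ndarray, cell: tuple[float, float, float, float]) -> bool:
        x0, y0, x1, y1 = cell
        return bool(
            (pts[:, 0] >= x0 + margin).all()
            and (pts[:, 0] <= x1 - margin).all()
            and (pts[:, 1] >= y0 + margin).all()
            and (pts[:, 1] <= y1 - margin).all()
        )

    for t in range(n_trees):
        cx_cell, cy_cell = t % ncells, t // ncells
        cell = (cx_cell * cell_w, cy_cell * cell_h, (cx_cell + 1) * cell_w, (cy_cell + 1) * cell_h)
        trunk_len = trunk_frac * min(cell_w, cell_h)
        axis = rng.integers(0, 4) * math.pi / 2
        heading = axis + rng.uniform(-jit, jit)
        root = np.array(
            [
                cell[0] + cell_w / 2 - trunk_len * math.cos(heading) / 2,
                cell[1] + cell_h / 2 - trunk_len * math.sin(heading) / 2,
            ]
        )
        # queue of (start, heading, level)
        queue = [(root, heading, 0)]
        root_pts.append((float(root[0]), float(root[1])))
        while queue:
            start, hdg, level = queue.pop(0)
            length = trunk_len * (length_decay**level)
            amp = min(tortuosity_amplitude, 0.25 * length)
            placed = None
            for attempt in range(4):
                trial_hdg = hdg if attempt == 0 else hdg + rng.uniform(-jit, jit)
                trial_len = length if attempt < 2 else 0.65 * length
                poly = _branch_polyline(start, trial_hdg, trial_len, amp, tortuosity_cycles)
                if not in_cell(poly, cell):
                    continue
                # ignore own attachment zone when testing for collisions
                far = poly[np.linalg.norm(poly - start[None, :], axis=1) > 1.8 * clearance]
                if far.size and _min_dist_to_points(far, cloud) < clearance:
                    continue
                placed = poly
                break
            if placed is None:
                node_children.append(0)
                node_pos.append((float(start[0]), float(start[1])))
                continue
            branches.append(placed)
            diameters.append(float(diameter))
            tort_params.append((float(amp), float(tortuosity_cycles)))
            cloud = np.vstack([cloud, placed[:: max(1, len(placed) // 64)]])
            end = placed[-1]
            end_hdg = math.atan2(
                placed[-1][1] - placed[-2][1], placed[-1][0] - placed[-2][0]
            )
            n_kids = 0
            if level + 1 < depth:
                # snap children to the axis perpendicular to the parent's
                # nearest axis so jitter never accumulates across levels:
                # every branch stays within the jitter band of an image axis
                parent_axis = round(end_hdg / (math.pi / 2)) * (math.pi / 2)
                for sign in (+1, -1):
                    child_hdg = parent_axis + sign * (math.pi / 2) + rng.uniform(-jit, jit)
                    queue.append((end.copy(), child_hdg, level + 1))
                    n_kids += 1
            node_children.append(n_kids)
            node_pos.append((float(end[0]), float(end[1])))

    if not branches:
        raise ParameterError("no branch could be placed; canvas too small for parameters")

    # Reconstruct node degrees: a branch end with c surviving children has
    # degree 1 + c (parent side counts 1); roots have degree 1 at the base.
    # Children that were dropped at placement never enter the tree, so the
    # recorded child counts reflect the grown network.  We recover child
    # survival by matching branch starts to recorded end positions.
    end_pos = [tuple(np.round(b[-1], 6)) for b in branches]
    start_pos = [tuple(np.round(b[0], 6)) for b in branches]
    starts_at: dict[tuple[float, float], int] = {}
    for sp in start_pos:
        starts_at[sp] = starts_at.get(sp, 0) + 1

    topology: list[dict] = []
    for rp in root_pts:
        key = tuple(np.round(np.asarray(rp), 6))
        if key in start_pos:  # root base of a placed trunk
            topology.append({"xy": rp, "degree": 1})
    for i, epos in enumerate(end_pos):
        c = starts_at.get(epos, 0)
        topology.append({"xy": epos, "degree": 1 + c})

    ep = sum(1 for n in topology if n["degree"] == 1)
    bp = sum(1 for n in topology if n["degree"] >= 3)
    total_len = float(
        sum(np.sum(np.linalg.norm(np.diff(b, axis=0), axis=1)) for b in branches)
    )
    return VesselTreeTruth(
        branches=branches,
        diameters=diameters,
        topology=topology,
        true_counts={"bp": bp, "ep": ep},
        true_centerline_length=total_len,
        tortuosity_params=tort_params,
    )


def _normalized_distance_field(
    tree: VesselTreeTruth, size: tuple[int, int], pad: float = 4.0
) -> np.ndarray:
    """Per-pixel minimum over branches of (distance to centerline) / (stroke
    radius). Values <= 1 lie inside a stroke; background is +inf beyond
    ``pad`` pixels of any stroke edge."""
    h, w = size
    u = np.full((h, w), np.inf)
    for poly, diam in zip(tree.branches, tree.diameters):
        r = diam / 2.0
        for a, b in zip(poly[:-1], poly[1:]):
            x0 = max(0, int(math.floor(min(a[0], b[0]) - r - pad)))
            x1 = min(w - 1, int(math.ceil(max(a[0], b[0]) + r + pad)))
            y0 = max(0, int(math.floor(min(a[1], b[1]) - r - pad)))
            y1 = min(h - 1, int(math.ceil(max(a[1], b[1]) + r + pad)))
            if x1 < x0 or y1 < y0:
                continue
            xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
            p = np.stack([xs, ys], axis=-1).astype(float)
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                d = np.linalg.norm(p - a, axis=-1)
            else:
                t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
                proj = a[None, None, :] + t[..., None] * ab[None, None, :]
                d = np.linalg.norm(p - proj, axis=-1)
            patch = u[y0 : y1 + 1, x0 : x1 + 1]
            np.minimum(patch, d / r, out=patch)
    return u


def rasterize_tree(tree: VesselTreeTruth, size: tuple[int, int]) -> np.ndarray:
    """Crisp boolean raster: pixel true iff its center lies within half a
    stroke width of a centerline (the soft stroke profile cut at its
    half-maximum contour)."""
    return _normalized_distance_field(tree, size) <= 1.0


def render_octa_image(
    tree: VesselTreeTruth,
    size: tuple[int, int] = (300, 300),
    background: float = 20.0,
    vessel_intensity: float = 200.0,
    speckle_sigma: float = 0.0,
    background_sigma: float = 0.0,
    edge_exponent: float = 4.0,
    seed: int = 0,
    quality_index: float | None = None,
    plexus_label: str = "unlabeled",
    mm_per_pixel: float | None = 0.01,
) -> EnFaceImage:
    """Rasterize a vascular tree as a bright-on-dark en-face angiogram.

    Strokes carry a flat-top cross-profile
    ``exp(-ln 2 * (d / r)**edge_exponent)`` (d = distance to the
    centerline, r = stroke radius): the half-maximum contour coincides
    exactly with the crisp :func:`rasterize_tree` mask, while the
    point-spread-like soft shoulder (about one pixel wide) emulates the
    optical blur of real angiograms — Hessian-based enhancement behaves
    pathologically on hard-edged bars. With noise disabled every
    centerline pixel takes ``vessel_intensity`` and far background
    ``background``. Speckle is multiplicative Gaussian (sigma relative
    to 1), clipped to the 8-bit range.
    """
    h, w = size
    for poly in tree.branches:
        if (
            (poly[:, 0] < 0).any()
            or (poly[:, 0] > w - 1).any()
            or (poly[:, 1] < 0).any()
            or (poly[:, 1] > h - 1).any()
        ):
            raise GeometryError("tree polyline outside the canvas")
    u = _normalized_distance_field(tree, size)
    profile = np.zeros((h, w))
    finite = np.isfinite(u)
    profile[finite] = np.exp(-math.log(2.0) * u[finite] ** edge_exponent)
    img = float(background) + (float(vessel_intensity) - float(background)) * profile
    if speckle_sigma > 0 or background_sigma > 0:
        rng = np.random.default_rng(seed)
        if speckle_sigma > 0:
            img = img * (1.0 + speckle_sigma * rng.standard_normal(img.shape))
        if background_sigma > 0:
            img = img + background_sigma * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 255.0)
    return EnFaceImage(
        pixels=img,
        mm_per_pixel=mm_per_pixel,
        quality_index=quality_index,
        plexus_label=plexus_label,
    )


# ==========================================================================
# Lens B-scans
# ==========================================================================


@dataclass
class LensSceneTruth:
    """Analytic description of a crystalline-lens B-scan.

    ``anterior_coeffs`` / ``posterior_coeffs`` are the five coefficients
    (highest power first, :func:`numpy.polyval` order) of quartic depth
    profiles ``y(x)`` in pixel coordinates; the lens is the region
    strictly between them. The nucleus is an optional brighter ellipse.
    """

    anterior_coeffs: np.ndarray
    posterior_coeffs: np.ndarray
    cortex_intensity: float = 40.0
    nucleus_intensity: float | None = 60.0
    nucleus_ellipse: tuple[tuple[float, float], tuple[float, float], float] | None = None
    speckle_sigma: float = 0.0
    artifact_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.anterior_coeffs = np.asarray(self.anterior_coeffs, dtype=float)
        self.posterior_coeffs = np.asarray(self.posterior_coeffs, dtype=float)
        if self.anterior_coeffs.shape != (5,) or self.posterior_coeffs.shape != (5,):
            raise ParameterError("surface coefficients must be 5-vectors (quartic)")
        if not 0 <= self.cortex_intensity <= 255:
            raise ParameterError("cortex_intensity must lie in [0, 255]")
        if self.nucleus_intensity is not None and not 0 <= self.nucleus_intensity <= 255:
            raise ParameterError("nucleus_intensity must lie in [0, 255]")

    def anterior(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.anterior_coeffs, np.asarray(x, dtype=float))

    def posterior(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.posterior_coeffs, np.asarray(x, dtype=float))

    def region_masks(self, size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(lens_mask, nucleus_mask) on pixel centers, strict inequalities."""
        h, w = size
        cols = np.arange(w, dtype=float)
        ya, yp = self.anterior(cols), self.posterior(cols)
        rows = np.arange(h, dtype=float)[:, None]
        lens = (rows > ya[None, :]) & (rows < yp[None, :])
        nuc = np.zeros_like(lens)
        if self.nucleus_ellipse is not None and self.nucleus_intensity is not None:
            (cx, cy), (a, b), rot = self.nucleus_ellipse
            if a <= 0 or b <= 0:
                raise ParameterError("nucleus semi-axes must be positive")
            xs = np.arange(w, dtype=float)[None, :] - cx
            ys = rows - cy
            ct, st = math.cos(rot), math.sin(rot)
            u = xs * ct + ys * st
            v = -xs * st + ys * ct
            nuc = ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & lens
        return lens, nuc

    def mixture_mean(self, size: tuple[int, int]) -> float:
        """Area-weighted mean lens intensity implied by the geometry."""
        lens, nuc = self.region_masks(size)
        n_lens, n_nuc = int(lens.sum()), int(nuc.sum())
        if n_lens == 0:
            raise GeometryError("surfaces enclose no pixels")
        nuc_val = self.nucleus_intensity if self.nucleus_intensity is not None else self.cortex_intensity
        return (self.cortex_intensity * (n_lens - n_nuc) + nuc_val * n_nuc) / n_lens


def make_lens_scene(
    size: tuple[int, int] = (192, 256),
    cortex_intensity: float = 40.0,
    nucleus_intensity: float | None = 60.0,
    nucleus_frac: tuple[float, float] = (0.55, 0.5),
    anterior_depth_frac: float = 0.30,
    posterior_depth_frac: float = 0.78,
    curvature_frac: float = 0.12,
    quartic_frac: float = 0.03,
    speckle_sigma: float = 0.0,
    artifact_columns: tuple[int, ...] = (),
) -> LensSceneTruth:
    """Convenience constructor for a plausible lentoid scene.

    The anterior surface bows upward (toward shallower rows) and the
    posterior downward, each a quartic in the lateral coordinate; the
    two meet near the image edges so the enclosed region is a lentoid.
    """
    h, w = size
    cx = (w - 1) / 2.0
    ya_c = anterior_depth_frac * h
    yp_c = posterior_depth_frac * h
    half = w / 2.0
    k2 = curvature_frac * h / half**2
    k4 = quartic_frac * h / half**4
    # polynomial in x expanded around center: y = yc +/- (k2 (x-cx)^2 + k4 (x-cx)^4)
    def expand(yc: float, s: float) -> np.ndarray:
        # s=+1 opens downward in row coordinates (anterior), s=-1 upward
        p = np.polynomial.polynomial.Polynomial([0, 0, s * k2, 0, s * k4])
        shifted = p(np.polynomial.polynomial.Polynomial([-cx, 1]))
        c = shifted.coef
        c = np.pad(c, (0, 5 - len(c)))
        coeffs = c[::-1].copy()
        coeffs[-1] += yc
        return coeffs

    anterior = expand(ya_c, +1.0)
    posterior = expand(yp_c, -1.0)
    ellipse = None
    if nucleus_intensity is not None:
        thickness = yp_c - ya_c
        ellipse = ((cx, (ya_c + yp_c) / 2.0), (nucleus_frac[0] * w / 2.0, nucleus_frac[1] * thickness / 2.0), 0.0)
    return LensSceneTruth(
        anterior_coeffs=anterior,
        posterior_coeffs=posterior,
        cortex_intensity=cortex_intensity,
        nucleus_intensity=nucleus_intensity,
        nucleus_ellipse=ellipse,
        speckle_sigma=speckle_sigma,
        artifact_columns=tuple(artifact_columns),
    )


def generate_lens_bscan(
    truth: LensSceneTruth,
    size: tuple[int, int] = (192, 256),
    scan_index: int = 1,
    background: float = 6.0,
    seed: int = 0,
) -> ASOCTScan:
    """Render one AS-OCT B-scan from an analytic lens scene.

    Pixels strictly between the two quartic surfaces take the cortex
    intensity (nucleus intensity inside the nuclear ellipse), everything
    else a dim background; multiplicative speckle is applied when the
    scene requests it, and listed artifact columns are zeroed to emulate
    segmentation-breaking signal dropout.
    """
    h, w = size
    lens, nuc = truth.region_masks(size)
    if not lens.any():
        raise GeometryError("anterior surface does not lie above the posterior surface anywhere")
    cols_with_lens = np.flatnonzero(lens.any(axis=0))
    if len(cols_with_lens) < 10:
        raise GeometryError("lens extent spans fewer than 10 columns")
    img = np.full((h, w), float(background))
    img[lens] = truth.cortex_intensity
    if truth.nucleus_intensity is not None:
        img[nuc] = truth.nucleus_intensity
    if truth.speckle_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img * (1.0 + truth.speckle_sigma * rng.standard_normal(img.shape))
    for c in truth.artifact_columns:
        if 0 <= c < w:
            img[:, c] = 0.0
    img = np.clip(img, 0.0, 255.0)
    return ASOCTScan(pixels=img, scan_index=scan_index)


def generate_lens_series(
    truth: LensSceneTruth,
    n_scans: int = 15,
    size: tuple[int, int] = (192, 256),
    seed: int = 0,
) -> list[ASOCTScan]:
    """A radial series of B-scans from one scene with independent speckle."""
    rng = np.random.default_rng(seed)
    return [
        generate_lens_bscan(
            truth, size=size, scan_index=i + 1, seed=int(rng.integers(0, 2**31 - 1))
        )
        for i in range(n_scans)
    ]


# ==========================================================================
# Longitudinal cohorts
# ==========================================================================


@dataclass
class CohortSimParams:
    """Conditions for a simulated longitudinal cataract-surgery cohort.

    Defaults emulate a 46-eye cohort followed at surgery baseline and
    three postoperative visits, with the perfusion jump concentrated in
    the first interval and a plateau thereafter. ``target_correlation``
    is the population Pearson r between nuclear opacity and the metric
    change at the configured follow-up; ``noise_scale`` sets the SD of
    that change as a fraction of the between-eye SD of the metric.
    """

    n_eyes: int = 46
    timepoints: tuple[str, ...] = TIMEPOINTS
    metric_params: dict = field(default_factory=lambda: dict(DEFAULT_METRIC_PARAMS))
    opacity_mean: float = DEFAULT_NUCLEAR_OPACITY[0]
    opacity_sd: float = DEFAULT_NUCLEAR_OPACITY[1]
    target_correlation: float = 0.35
    noise_scale: float = 0.5
    follow_up: str = "T3"
    visit_noise_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_correlation <= 1.0:
            raise ParameterError("target_correlation must lie in [-1, 1]")
        if self.n_eyes < 4:
            raise ParameterError("n_eyes must be >= 4")
        if self.noise_scale < 0 or self.visit_noise_scale < 0:
            raise ParameterError("noise scales must be >= 0")
        if tuple(self.timepoints) != TIMEPOINTS:
            raise ParameterError(f"timepoints must be {TIMEPOINTS}")
        if self.follow_up not in self.timepoints or self.follow_up == "T0":
            raise ParameterError("follow_up must be one of T1..T3")
        rho = self.target_correlation
        if 0 < abs(rho) < 1 and self.noise_scale == 0:
            raise ParameterError(
                "a correlation strictly between 0 and 1 is infeasible with zero change noise"
            )


def metric_column(metric: str, plexus: str, tp: str) -> str:
    return f"{metric}_{plexus}_{tp}"


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Draw a per-eye longitudinal table with a known opacity-change link.

    The change at the configured follow-up and the nuclear opacity are
    jointly Gaussian by construction: with opacity z-score ``z`` the
    change disturbance is ``sd_c * (rho z + sqrt(1 - rho^2) e)``, so the
    population correlation equals ``rho`` exactly. ``rho = +/-1`` uses a
    deterministic linear map of ``z`` (slope = change SD, or 1 if that
    is zero). One row per eye; deterministic given the seed.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_eyes
    rho = p.target_correlation

    z_op = rng.standard_normal(n)
    nuclear = np.clip(p.opacity_mean + p.opacity_sd * z_op, 0.0, 255.0)
    # the change construction uses the realized (clipped) opacity so the
    # configured correlation is exact in the stored variable
    if p.opacity_sd > 0:
        z_op = (nuclear - p.opacity_mean) / p.opacity_sd
    lens = np.clip(
        DEFAULT_LENS_OPACITY[0]
        + DEFAULT_LENS_OPACITY[1] * (0.6 * z_op + 0.8 * rng.standard_normal(n)),
        0.0,
        255.0,
    )
    cde = np.clip(DEFAULT_CDE[0] + DEFAULT_CDE[1] * rng.standard_normal(n), 0.0, None)
    phaco = np.clip(
        DEFAULT_PHACO_TIME[0] + DEFAULT_PHACO_TIME[1] * rng.standard_normal(n), 0.0, None
    )
    fluid = np.clip(DEFAULT_FLUID[0] + DEFAULT_FLUID[1] * rng.standard_normal(n), 1.0, None)

    data: dict[str, np.ndarray] = {"eye_id": np.array([f"eye{i:03d}" for i in range(n)])}
    degenerate: list[str] = []
    fu_idx = p.timepoints.index(p.follow_up)

    for (metric, plexus), (m0, m1, m2, m3, sd) in p.metric_params.items():
        means = (m0, m1, m2, m3)
        subj = sd * rng.standard_normal(n)
        sd_c = p.noise_scale * sd
        if abs(rho) == 1.0:
            slope = sd_c if sd_c > 0 else 1.0
            change = (means[fu_idx] - m0) + math.copysign(slope, rho) * z_op
        elif rho == 0.0 and sd_c == 0.0:
            change = np.full(n, means[fu_idx] - m0)
            degenerate.append(f"{metric}_{plexus}")
        else:
            eps = rng.standard_normal(n)
            change = (means[fu_idx] - m0) + sd_c * (
                rho * z_op + math.sqrt(1.0 - rho**2) * eps
            )
        t0 = m0 + subj
        values = {0: t0, fu_idx: t0 + change}
        sd_v = p.visit_noise_scale * sd
        for k in range(1, 4):
            if k == fu_idx:
                continue
            values[k] = t0 + (means[k] - m0) + sd_v * rng.standard_normal(n)
        for k, tp in enumerate(p.timepoints):
            data[metric_column(metric, plexus, tp)] = values[k]

    iop_subj = 2.0 * rng.standard_normal(n)
    for k, tp in enumerate(p.timepoints):
        resid_sd = max(0.5, math.sqrt(max(DEFAULT_IOP_SDS[k] ** 2 - 4.0, 0.25)))
        data[f"iop_{tp}"] = DEFAULT_IOP_MEANS[k] + iop_subj + resid_sd * rng.standard_normal(n)

    data["cde"] = cde
    data["phaco_time"] = phaco
    data["fluid"] = fluid
    data["lens_opacity"] = lens
    data["nuclear_opacity"] = nuclear

    frame = pd.DataFrame(data).set_index("eye_id")
    frame.attrs["follow_up"] = p.follow_up
    frame.attrs["degenerate_change_metrics"] = degenerate
    return frame


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(Path(path), index=True)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col="eye_id")
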