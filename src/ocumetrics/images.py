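"""Image containers and lossless grayscale I/O.

Two thin containers carry the pixel grids through the pipeline:
:class:`EnFaceImage` for en-face OCT-angiography projections and
:class:`ASOCTScan` for anterior-segment B-scans of the crystalline lens.
Both hold 8-bit grayscale intensities (0-255) with the field's usual
raster convention: ``y`` is the row index (depth / vertical), ``x`` the
column index (lateral), both 0-based.

Images are read and written as lossless 8-bit grayscale PNG; optional
metadata (device quality index, plexus label, radial scan index) travels
in a JSON sidecar next to the image file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

PLEXUS_LABELS = ("SVP", "ICP", "DCP", "unlabeled")

MIN_IMAGE_DIM = 16


def _validate_grid(pixels: np.ndarray, min_dim: int = MIN_IMAGE_DIM) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale grid, got shape {arr.shape}")
    if arr.shape[0] < min_dim or arr.shape[1] < min_dim:
        raise ValueError(f"image must be at least {min_dim}x{min_dim}, got {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr.astype(np.float64)


@dataclass
class EnFaceImage:
    """En-face OCTA projection of one retinal vascular slab.

    Parameters
    ----------
    pixels : ndarray
        2-D intensity grid, values in [0, 255].
    mm_per_pixel : float, optional
        Physical lateral scale; the nominal field is a 3 x 3 mm square
        centered on the fovea.
    quality_index : float, optional
        Device signal-quality score; scans below the acquisition gate
        (default 30) are rejected by the quantification stage.
    plexus_label : str
        One of SVP, ICP, DCP or "unlabeled".
    """

    pixels: np.ndarray
    mm_per_pixel: float | None = None
    quality_index: float | None = None
    plexus_label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.pixels = _validate_grid(self.pixels)
        if self.plexus_label not in PLEXUS_LABELS:
            raise ValueError(f"plexus_label must be one of {PLEXUS_LABELS}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ASOCTScan:
    """One anterior-segment B-scan from the radial lens series.

    ``scan_index`` is the 1-based position within the radial pattern
    (15 B-scans per eye by default).
    """

    pixels: np.ndarray
    scan_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = _validate_grid(self.pixels)
        if not 1 <= int(self.scan_index):
            raise ValueError("scan_index must be >= 1")
        self.scan_index = int(self.scan_index)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_grayscale_png(path: str | Path, pixels: np.ndarray, metadata: dict | None = None) -> None:
    """Write an 8-bit grayscale PNG plus optional JSON sidecar."""
    path = Path(path)
    arr = np.clip(np.rint(np.asarray(pixels, dtype=np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr, extension=".png")
    if metadata is not None:
        _sidecar_path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    sidecar = _sidecar_path(Path(path))
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def read_enface_png(path: str | Path) -> EnFaceImage:
    """Read an en-face OCTA image; quality index / plexus come from the sidecar."""
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse an accidental RGB export
        arr = arr[..., 0]
    meta = read_sidecar(path)
    return EnFaceImage(
        pixels=arr,
        mm_per_pixel=meta.get("mm_per_pixel"),
        quality_index=meta.get("quality_index"),
        plexus_label=meta.get("plexus_label", "unlabeled"),
    )


def read_asoct_png(path: str | Path, scan_index: int | None = None) -> ASOCTScan:
    """Read one lens B-scan; scan_index from argument, sidecar or filename ``scan-NN``."""
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if scan_index is None:
        meta = read_sidecar(path)
        scan_index = meta.get("scan_index")
    if scan_index is None:
        stem = path.stem
        digits = "".join(ch for ch in stem if ch.isdigit())
        scan_index = int(digits) if digits else 1
    return ASOCTScan(pixels=arr, scan_index=int(scan_index))
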