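import numpy as np
import pytest

from ocumetrics.octa import QuantConfig
from ocumetrics.synthetic import generate_vascular_tree, make_lens_scene, render_octa_image


@pytest.fixture(scope="session")
def recovery_config() -> QuantConfig:
    """Quantification configuration used for ground-truth recovery runs:
    filter scales matched to the rendered capillary calibre (diameter 3 px)
    and spur pruning enabled to absorb thinning artifacts."""
    return QuantConfig(frangi_scales=(1.5, 2.0, 2.5, 3.0), min_branch_length=6.0)


@pytest.fixture(scope="session")
def small_tree():
    return generate_vascular_tree(depth=3, seed=7)


@pytest.fixture(scope="session")
def small_tree_image(small_tree):
    return render_octa_image(small_tree, quality_index=35)


@pytest.fixture(scope="session")
def lens_scene():
    return make_lens_scene(cortex_intensity=40.0, nucleus_intensity=60.0)


def bool_grid(rows: list[str]) -> np.ndarray:
    """Tiny helper: 'X' marks a true pixel."""
    return np.array([[c == "X" for c in row] for row in rows], dtype=bool)
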