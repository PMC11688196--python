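import numpy as np
import pytest

from nisslcolumn import synthetic_cortex as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(seed=0, width=500.0, curvature=0.0, image_id="img_0"):
    """A full seven-layer column at reduced width (keeps tests fast)."""
    return sc.default_column_spec(
        seed=seed, column_width_um=width, curvature_um=curvature,
        image_id=image_id)


@pytest.fixture
def rect_column():
    """Straight (rectangular) reference column: geometry + cells."""
    spec = small_spec(seed=42)
    regions, cells = sc.make_column(spec)
    return spec, regions, cells
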