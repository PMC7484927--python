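import numpy as np
import pytest

from splatquant import StripGenParams, ThresholdSpec, datasets, generate_strip_image


@pytest.fixture(scope="session")
def appendix_summaries():
    return datasets.appendix_group_summaries()


@pytest.fixture(scope="session")
def procedure_metadata():
    return datasets.load_procedure_metadata()


@pytest.fixture
def default_spec():
    return ThresholdSpec()


@pytest.fixture(scope="session")
def speckled_strip():
    """A seed-42 strip at 25% target coverage with default jitter/noise."""
    return generate_strip_image(
        StripGenParams(width_px=200, height_px=1000, target_coverage=0.25, seed=42)
    )


def solid_scan(rgb, shape=(20, 30)):
    """Uniform-colour test image."""
    from splatquant import Scan

    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[...] = rgb
    return Scan(px)


PURE_RED = (255, 0, 0)
PURE_YELLOW = (255, 255, 0)
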