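import numpy as np
import pytest

from histocorr.synthetic import SlideRecord, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Fast 256-px slides with 32-px tiles."""
    return SyntheticSpec(slide_px=256, tile_px=32)


@pytest.fixture(scope="session")
def tiny_cohort(small_spec):
    """3+3 slides shared across read-only tests."""
    records, manifest = generate_cohort(3, 3, small_spec, seed=5)
    return records, manifest


def make_slide(mask: np.ndarray, label: str = "POS",
               slide_id: str = "s0") -> SlideRecord:
    """Wrap an arbitrary binary mask into a minimal slide record."""
    img = np.zeros(mask.shape + (3,), dtype=np.uint8)
    return SlideRecord(slide_id, img, mask.astype(np.uint8), label, "aperio", 0)
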