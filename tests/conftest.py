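import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from perivasc.imaging_core import BinaryMask, FieldImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_field(
    drug: np.ndarray,
    vessel: np.ndarray,
    exclusion: np.ndarray | None = None,
    pixel_pitch_um: float = 1.0196,
) -> FieldImage:
    """Calibrated field around hand-built rasters (area derived from dims)."""
    channels = {"drug": drug.astype(float), "vessel": vessel.astype(float)}
    if exclusion is not None:
        channels["exclusion"] = exclusion.astype(float)
    h, w = drug.shape
    return FieldImage(
        channels=channels,
        pixel_pitch_um=pixel_pitch_um,
        magnification_tag="x100",
        field_area_mm2=h * w * pixel_pitch_um**2 * 1e-6,
        field_id="testfield",
    )


def vessel_mask(data: np.ndarray) -> BinaryMask:
    return BinaryMask(data=data.astype(bool), semantics_tag="vessel")
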