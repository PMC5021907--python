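import numpy as np
import pytest

from endomatch.segmentation import GrayImage
from endomatch.synthetic_ct import (
    BranchSpec,
    EndoleakSpec,
    SyntheticSceneSpec,
    generate_scene,
)


@pytest.fixture
def default_scene():
    """One branch + one endoleak blob at 120 deg, moderate noise."""
    spec = SyntheticSceneSpec(
        endoleak=EndoleakSpec(angle_deg=120.0), noise_sd=7.5, seed=3
    )
    img, truth = generate_scene(spec)
    return GrayImage(img.astype(float), bit_depth=8), truth, spec


@pytest.fixture
def two_branch_scene():
    """Two daughter-branch discs plus an endoleak blob below the left one."""
    spec = SyntheticSceneSpec(
        branches=(
            BranchSpec(center_row=90.0, center_col=90.0, outer_radius=35.0),
            BranchSpec(center_row=90.0, center_col=170.0, outer_radius=35.0),
        ),
        endoleak=EndoleakSpec(
            anchor_branch_index=0, angle_deg=270.0, radial_offset=55.0, radius=10.0
        ),
        noise_sd=5.0,
        seed=7,
    )
    img, truth = generate_scene(spec)
    return GrayImage(img.astype(float), bit_depth=8), truth, spec


def disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
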