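import numpy as np
import pytest

from brainmech import (
    MaskVolume,
    PhantomSpec,
    make_anatomy,
    merge_regions,
    refine_segmentation,
)
from brainmech.phantom import MERGED_LABEL_NAMES, SIX_REGION_MAPPING, VENTRICLE_LABEL

MERGED_NAMES = MERGED_LABEL_NAMES


@pytest.fixture(scope="session")
def small_spec():
    """Coarse 32^3 phantom used by most unit tests (fast)."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        spacing_mm=(5.0, 5.0, 5.0),
        brain_radii_mm=(45.0, 55.0, 40.0),
        ventricle_radii_mm=(8.0, 14.0, 7.0),
    )


@pytest.fixture(scope="session")
def subject(small_spec):
    return make_anatomy(small_spec)


@pytest.fixture(scope="session")
def merged_labels(subject):
    return merge_regions(subject.labels, SIX_REGION_MAPPING, MERGED_NAMES)


@pytest.fixture(scope="session")
def membranes(subject):
    return MaskVolume(
        subject.falx.data | subject.tentorium.data, subject.falx.spacing_mm
    )


@pytest.fixture(scope="session")
def refined(subject, merged_labels, membranes):
    return refine_segmentation(
        merged_labels, merged_labels.mask(VENTRICLE_LABEL), subject.dura, membranes
    )
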