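import numpy as np
import pytest

from erpsource.forward import compute_leadfield
from erpsource.geometry import (
    make_head,
    make_montage,
    make_roi_masks,
    make_source_space,
)
from erpsource.simulate import StudyDesign


@pytest.fixture(scope="session")
def head():
    """Default 4-shell head (brain/CSF/skull/scalp)."""
    return make_head()


@pytest.fixture(scope="session")
def montage64(head):
    return make_montage(head, 64)


@pytest.fixture(scope="session")
def montage16(head):
    return make_montage(head, 16)


@pytest.fixture(scope="session")
def src_tiny(head):
    """Coarse grey-matter grid (~200 points) for fast end-to-end tests."""
    return make_source_space(head, spacing=0.02)


@pytest.fixture(scope="session")
def masks_tiny(src_tiny):
    return make_roi_masks(src_tiny, patch_size=4, seed=0)


@pytest.fixture(scope="session")
def lf_tiny(head, src_tiny, montage16):
    return compute_leadfield(head, src_tiny, montage16, truncation_L=60)


@pytest.fixture(scope="session")
def lf_tiny64(head, src_tiny, montage64):
    return compute_leadfield(head, src_tiny, montage64, truncation_L=60)


@pytest.fixture(scope="session")
def design_small():
    return StudyDesign(n_subjects=3, n_trials_per_condition=12, master_seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
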