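import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hodac import cv_segment, segment
from hodac.phantoms import FIXTURES

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bias_blob():
    """The named bias-field acceptance phantom (128x128 blob, seed 7)."""
    return FIXTURES["bias_blob_128"]()


@pytest.fixture(scope="session")
def clean_disk():
    """Uncorrupted two-level disk phantom (bias 0, noise 0)."""
    return FIXTURES["clean_disk_64"]()


@pytest.fixture(scope="session")
def bias_blob_result(bias_blob):
    """Full-model segmentation of the bias phantom with default parameters."""
    return segment(bias_blob.image)


@pytest.fixture(scope="session")
def bias_blob_cv_result(bias_blob):
    """Chan-Vese means baseline on the same phantom."""
    return cv_segment(bias_blob.image)


@pytest.fixture(scope="session")
def bias_blob_checkerboard_result(bias_blob):
    """Full model started from a checkerboard indicator instead of 0.5."""
    H, W = bias_blob.image.shape
    cb = ((np.add.outer(np.arange(H) // 8, np.arange(W) // 8)) % 2).astype(float)
    return segment(bias_blob.image, phi0=cb)


@pytest.fixture(scope="session")
def clean_disk_result(clean_disk):
    return segment(clean_disk.image)
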