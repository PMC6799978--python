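"""Shared fixtures: small synthetic inputs with known ground truth."""

import numpy as np
import pytest

from hypoquant import RoiSet
from hypoquant.synth import LatentModel, RegionSpec, StackSpec


ANTI = np.array([[1.0, -0.8], [-0.8, 1.0]])


@pytest.fixture
def anti_model():
    """Two-region model with strongly anti-correlated latents."""
    return LatentModel(n_regions=2, latent_corr=ANTI, rate_hz=0.15, seed=7)


@pytest.fixture
def small_stack_spec():
    """A compact stained-stack recipe with one labelled region."""
    shape = (8, 64, 64)
    mask = np.zeros(shape, dtype=bool)
    mask[1:7, 8:56, 8:56] = True
    return StackSpec(shape, [RegionSpec("lLH", mask, density=0.9)],
                     psf_sigma=(1.0, 1.5, 1.5), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_rois(mask, name="lLH", background=None):
    masks = {name: mask}
    if background is not None:
        masks["background"] = background
    return RoiSet(masks)
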