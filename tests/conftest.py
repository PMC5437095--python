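import numpy as np
import pytest

from bpequant.image import BreastMask, FgtMask
from bpequant.phantom import PhantomParams, generate_phantom


def small_phantom_params(**overrides):
    """A fast low-resolution phantom used across the suite."""
    defaults = dict(
        grid_shape=(24, 48, 48),
        spacing_mm=(2.0, 1.0, 1.0),
        breast_half_axes_mm=(16.0, 18.0, 10.0),
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """Zero-noise small phantom: (study, truth)."""
    return generate_phantom(small_phantom_params())


def truth_masks(truth):
    """Ground-truth BreastMask/FgtMask objects per side."""
    breasts = {
        side: BreastMask(truth.breast_mask[side], side, truth.spacing_mm)
        for side in ("left", "right")
    }
    fgts = {side: FgtMask(truth.fgt_mask_side(side), breasts[side]) for side in breasts}
    return breasts, fgts


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
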