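"""Shared fixtures: one small synthetic cohort reused across the suite."""

import numpy as np
import pytest

from ccshape.curves import trace_boundary
from ccshape.lddmm import RegistrationConfig
from ccshape.synthetic import SyntheticConfig, generate_cohort, make_base_cc_shape
from ccshape.template import select_template


@pytest.fixture(scope="session")
def base_slice():
    return make_base_cc_shape()


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(n_per_cell=3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    slices, cov = generate_cohort(small_cfg)
    return slices, cov


@pytest.fixture(scope="session")
def small_curves(small_cohort):
    slices, _ = small_cohort
    return [trace_boundary(s) for s in slices]


@pytest.fixture(scope="session")
def template50(small_curves):
    return select_template(small_curves, k=50)


@pytest.fixture(scope="session")
def fast_reg():
    return RegistrationConfig(max_iters=120)


def random_blob_mask(rng, shape=(48, 48), n_seeds=3, smooth=3.0, frac=0.25):
    """Random smooth simply-connected blob for boundary-tracing tests."""
    from scipy import ndimage

    field = rng.normal(size=shape)
    field = ndimage.gaussian_filter(field, smooth)
    mask = field > np.quantile(field, 1 - frac)
    # largest 8-connected component, holes filled -> simply connected
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return random_blob_mask(rng, shape, n_seeds, smooth, frac)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    mask = lab == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < 16:
        return random_blob_mask(rng, shape, n_seeds, smooth, frac)
    return mask
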