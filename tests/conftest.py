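"""Shared fixtures: small phantoms and synthetic probability-map builders."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from tumorloc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_subject():
    """One deterministic 32^3 phantom: (MultimodalVolume, atlas, labels)."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), n_parcels=8, seed=5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_subject_48():
    """A 48^3 phantom with the full 21-parcel atlas."""
    spec = PhantomSpec(grid_shape=(48, 48, 48), seed=9)
    return generate_phantom(spec)


def make_complementary_maps(labels: np.ndarray, rng: np.random.Generator,
                            jitter: float = 0.008):
    """Two 5-class probability maps with complementary strengths.

    Map A localizes the whole tumor exactly but is uninformative about the
    lesion sub-class; map B carries the exact sub-class identity but
    over-segments the whole tumor (a dilated edema ring).  Jointly the
    10-dim per-voxel features determine the true label; individually each
    map fails on at least one region.
    """
    shape = labels.shape
    lesion = labels != 0

    a = np.zeros((5,) + shape)
    a[0][~lesion] = 0.98
    for c in (1, 2, 4):
        a[c][~lesion] = 0.02 / 3
    a[0][lesion] = 0.02
    for c in (1, 2, 4):
        a[c][lesion] = 0.98 / 3

    over = ndimage.binary_dilation(lesion, iterations=2)
    b_labels = np.where(lesion, labels, np.where(over, 2, 0))
    # confidence 0.9 keeps B's false edema ring below background in the
    # arithmetic mean with A, so the mean-map WT gate stays clean
    b = np.full((5,) + shape, 0.025)
    for c in (0, 1, 2, 4):
        b[c][b_labels == c] = 0.90

    def jittered(p):
        q = p + rng.uniform(0, jitter, size=p.shape)
        return q / q.sum(axis=0, keepdims=True)

    return jittered(a), jittered(b)


@pytest.fixture(scope="session")
def complementary_maps_builder():
    return make_complementary_maps
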