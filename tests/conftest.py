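"""Shared fixtures: one small frozen extractor and reusable phantom inputs.

Everything is generated programmatically at fixture time; nothing is read
from disk except files the tests themselves write into tmp_path.
"""

import numpy as np
import pytest

from slicemap import (BackboneSpec, PhantomSpec, build_extractor, build_feature_map,
                      make_phantom_volume, preprocess_array)


@pytest.fixture(scope="session")
def extractor():
    return build_extractor(BackboneSpec())


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 40 native slices at 64-pixel in-plane matrices."""
    return PhantomSpec(n_per_class=3, native_slices=40, in_plane=64,
                       effect_size=5.0, noise_sd=0.02, slice_jitter=10, seed=11)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return preprocess_array(make_phantom_volume(0, small_spec, subject_seed=1), "subj1")


@pytest.fixture(scope="session")
def small_fmap(extractor, small_stack):
    return build_feature_map(extractor, small_stack)


@pytest.fixture(scope="session")
def tiny_feature_cohort(extractor):
    """(X, y) for 8+8 phantoms with a strong anatomical effect, no noise-free
    shortcut: built through the full slab -> feature-map pipeline."""
    spec = PhantomSpec(n_per_class=8, native_slices=40, in_plane=64,
                       effect_size=10.0, noise_sd=0.02, slice_jitter=10, seed=21)
    X, y = [], []
    for cls in (0, 1):
        for s in range(8):
            vol = make_phantom_volume(cls, spec, subject_seed=500 + 10 * s + cls)
            X.append(build_feature_map(extractor, preprocess_array(vol)).matrix)
            y.append(cls)
    return np.stack(X), np.array(y)
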