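"""Shared fixtures: small seeded phantoms and fast registration parameters.

Unit tests run on 32^3 (or smaller) phantoms so the whole suite stays quick;
the end-to-end acceptance experiments use the 48^3 preset phantoms.
"""

from __future__ import annotations

import numpy as np
import pytest

from fetalicv import (PhantomSpec, RegistrationParams, make_head_phantom,
                      replace_zero_voxels)


def small_spec(**overrides) -> PhantomSpec:
    """A 32^3 head phantom spec with the same chiral features as the presets."""
    kw = dict(semi_axes=(20.0, 25.0, 21.0), spacing=(2.5, 2.5, 2.5),
              grid_shape=(32, 32, 32), lr_asymmetry=0.35, notch_fraction=0.35,
              shell_lr_gradient=0.35, internal_structures=4, seed=7)
    kw.update(overrides)
    return PhantomSpec(**kw)


def tiny_spec(**overrides) -> PhantomSpec:
    """A 24^3 phantom for CLI round trips where speed matters most."""
    kw = dict(semi_axes=(14.0, 17.0, 15.0), spacing=(2.5, 2.5, 2.5),
              grid_shape=(24, 24, 24), lr_asymmetry=0.35, notch_fraction=0.35,
              shell_lr_gradient=0.35, internal_structures=2, seed=3)
    kw.update(overrides)
    return PhantomSpec(**kw)


def fast_params(family: str, **overrides) -> RegistrationParams:
    kw = dict(pyramid_schedule=(2.0, 0.0), max_iterations=15,
              sample_fraction=0.15, seed=0)
    kw.update(overrides)
    return RegistrationParams(family=family, **kw)


@pytest.fixture(scope="session")
def head32():
    """(volume, mask, true_icv) for the standard small test phantom."""
    return make_head_phantom(small_spec())


@pytest.fixture(scope="session")
def head32_clean(head32):
    """Same phantom with sweep padding already replaced (pipeline input)."""
    v, m, icv = head32
    return replace_zero_voxels(v), m, icv


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
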