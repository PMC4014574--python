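"""Shared fixtures: tiny synthetic volumes and a small phantom study."""

from __future__ import annotations

import numpy as np
import pytest

from dtiparc.phantom import (
    ChannelMixture,
    PhantomSpec,
    StructureDef,
    make_ground_truth,
    make_library,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_spec(seed: int = 0) -> PhantomSpec:
    """A 20³ two-structure phantom for fast unit tests."""
    structures = [
        StructureDef(
            1, "blob-a",
            {"kind": "ellipsoid", "center": (7.0, 10.0, 10.0), "radii": (4.0, 4.5, 4.0)},
            fa=ChannelMixture((1.0,), (0.15,), (0.03,)),
            md=ChannelMixture((1.0,), (0.0030,), (0.0002,)),
            ev_axis=(1.0, 1.0, 1.0), ev_sigma=1.0,
        ),
        StructureDef(
            2, "blob-b",
            {"kind": "ellipsoid", "center": (13.0, 10.0, 10.0), "radii": (4.0, 4.0, 4.5)},
            fa=ChannelMixture((1.0,), (0.55,), (0.04,)),
            md=ChannelMixture((1.0,), (0.0007,), (0.0001,)),
            ev_axis=(1.0, 0.0, 0.0), ev_sigma=0.12,
        ),
    ]
    return PhantomSpec(
        shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0), structures=structures,
        deform_magnitude=3.0, deform_smoothness_mm=8.0, seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_truth():
    return make_ground_truth(tiny_spec(0))


@pytest.fixture(scope="session")
def tiny_library():
    return make_library(tiny_spec(0), n_atlases=2, seed=0)
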