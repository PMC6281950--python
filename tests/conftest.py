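"""Shared fixtures: expensive operator builds are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from ecgikit.forward_models import (
    build_dtn_operator,
    build_fem_transfer,
    build_mfs_transfer,
    choose_mfs_sources,
)
from ecgikit.geometry import icosphere
from ecgikit.synthetic_data import HEART_RADIUS_MM, TORSO_RADIUS_MM


@pytest.fixture(scope="session")
def heart():
    return icosphere(HEART_RADIUS_MM, 2, role="heart")


@pytest.fixture(scope="session")
def torso():
    return icosphere(TORSO_RADIUS_MM, 2, role="torso")


@pytest.fixture(scope="session")
def fem_system(heart, torso):
    return build_fem_transfer(heart, torso)


@pytest.fixture(scope="session")
def dtn(heart, torso):
    return build_dtn_operator(heart, torso)


@pytest.fixture(scope="session")
def mfs_system(heart, torso):
    return build_mfs_transfer(
        heart,
        torso,
        inflation=1.5,
        deflation=0.6,
        heart_source_idx=choose_mfs_sources(heart, torso, 2 * torso.n_vertices),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_system(rng, m, n, with_frames=1):
    """Well-scaled random least-squares instance for oracle tests."""
    A = rng.normal(size=(m, n))
    B = rng.normal(size=(m, with_frames))
    return A, (B[:, 0] if with_frames == 1 else B)
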