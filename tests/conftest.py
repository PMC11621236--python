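"""Shared fixtures.

Heavy synthetic-scene computations are session-scoped so that several test
modules (and the acceptance tests) reuse one generated cohort instead of
regenerating it.
"""

from __future__ import annotations

import numpy as np
import pytest

from twdfc.core import WindowSpec
from twdfc.pipeline import parcellate_subjects
from twdfc.synthetic import SceneConfig, build_scene

WINDOW = WindowSpec(length_tp=40, stride_tp=1)


@pytest.fixture(scope="session")
def window():
    return WINDOW


@pytest.fixture(scope="session")
def small_scene():
    """A compact 6-subject scene for unit-level checks."""
    return build_scene(SceneConfig(n_subjects=6, seed=3))


@pytest.fixture(scope="session")
def default_scene():
    """The full 20-subject study scene (seed 1)."""
    return build_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def default_parcellation(default_scene):
    """Left-hemisphere subject partitions + consensus at the planted k."""
    return parcellate_subjects(default_scene, WINDOW, k=4, seed=11, hemi="L")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
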