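"""Shared fixtures: synthetic tiles and a session-scoped reference model."""

from __future__ import annotations

import numpy as np
import pytest

from histoadi.labels import CLASS_LABELS
from histoadi.pipeline import train_synthetic_reference_model
from histoadi.synthetic import default_texture, generate_tile


@pytest.fixture(scope="session")
def tile_factory():
    """tile(label, seed) -> rendered 224x224x3 uint8 tile."""

    def make(label: str, seed: int = 0) -> np.ndarray:
        return generate_tile(default_texture(label, seed=seed))

    return make


@pytest.fixture(scope="session")
def reference_model():
    """A trained reference classifier shared by tests that need one.

    40 tiles per class keeps training under ~15 s; the full-size (200
    per class) training run is exercised in the acceptance suite.
    """
    return train_synthetic_reference_model(tiles_per_class=40, seed=7)


@pytest.fixture(scope="session")
def class_labels():
    return CLASS_LABELS
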