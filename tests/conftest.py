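"""Shared fixtures.

The expensive Monte Carlo photon banks and the trained classifier are
session-scoped so physics tests, pipeline tests and the acceptance suite
share one transport run per configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from trfnirs.classify import train_classifier
from trfnirs.paradigm import BlockDesign, build_timeline
from trfnirs.simulate import generate_training_corpus
from trfnirs.transport import (
    DetectionGeometry,
    OpticalLayerStack,
    run_transport,
)


@pytest.fixture(scope="session")
def design() -> BlockDesign:
    return BlockDesign()


@pytest.fixture(scope="session")
def timeline(design):
    return build_timeline(design)


@pytest.fixture(scope="session")
def geometry() -> DetectionGeometry:
    return DetectionGeometry()


@pytest.fixture(scope="session")
def head_stack() -> OpticalLayerStack:
    """The 10-layer, 0.2 cm-per-layer head model."""
    return OpticalLayerStack()


@pytest.fixture(scope="session")
def deep_homogeneous_stack() -> OpticalLayerStack:
    """Homogeneous semi-infinite medium, layered deep enough (10 x 1 cm)
    that the substrate below the nominal stack carries no sensitivity."""
    return OpticalLayerStack.homogeneous(0.17, 10.0, thickness_cm=1.0)


@pytest.fixture(scope="session")
def homogeneous_bank_1e6(deep_homogeneous_stack, geometry):
    return run_transport(deep_homogeneous_stack, geometry, 1_000_000, seed=101)


@pytest.fixture(scope="session")
def head_banks(head_stack, geometry):
    """One 5e5-photon bank per wavelength for the layered head model."""
    return {
        760.0: run_transport(head_stack, geometry, 500_000, seed=760),
        830.0: run_transport(head_stack, geometry, 500_000, seed=830),
    }


@pytest.fixture(scope="session")
def corpus():
    return generate_training_corpus(seed=7)


@pytest.fixture(scope="session")
def model(corpus, design):
    return train_classifier(corpus, design=design, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
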