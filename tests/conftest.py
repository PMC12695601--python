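"""Shared fixtures: small synthetic scenes and drawn shapes."""

import numpy as np
import pytest

from ciliascope import RGBImage, SceneSpec, generate_scene
from ciliascope.synthetic import fixture_detection_config


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic noise-free scene with its ground truth and config."""
    spec = SceneSpec(seed=11, noise_sd=0.0)
    image, truth = generate_scene(spec)
    return spec, image, truth, fixture_detection_config(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    spec = SceneSpec(seed=21)
    image, truth = generate_scene(spec)
    return spec, image, truth, fixture_detection_config(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def rgb_from_gray(gray, channel=1):
    """Wrap a gray plane into an RGBImage on the requested channel."""
    pixels = np.zeros((*gray.shape, 3))
    pixels[:, :, channel] = gray
    return RGBImage(pixels)
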