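import numpy as np
import pytest

import cyanomd as cm
from cyanomd.synthgen import sample_patterns, sample_population

UNIFORM_PATTERN = cm.MDPatternSpec(0, 0.3, (), (120.0, 110.0, 125.0))


@pytest.fixture(scope="session")
def uniform_pattern():
    """A patch-free pattern: perfectly uniform thylakoid ring."""
    return UNIFORM_PATTERN


def render_single(spec, pattern=UNIFORM_PATTERN, noise_sd=0.0, shape=(128, 128), seed=1):
    """Render one cell and return (image, labels, truth)."""
    return cm.render_image([spec], [pattern], noise_sd=noise_sd, seed=seed, shape=shape)


@pytest.fixture(scope="session")
def single_disk():
    """One noise-free regular cell (2.0 um disk) with its segmented mask."""
    spec = cm.CellShapeSpec("regular", (60, 60), 2.0, 2.0)
    image, labels, truth = render_single(spec)
    masks = cm.segment_cells(image)
    assert len(masks) == 1
    return image, masks[0], truth


@pytest.fixture(scope="session")
def mixed_population():
    """Noise-free 60-cell field spanning all four shape classes, with truth."""
    rng = np.random.default_rng(42)
    specs = sample_population(rng, 60, (768, 768), type_probs=np.array([0.25] * 4))
    pats = sample_patterns(
        rng, specs, np.array([130.0, 110.0, 125.0]), np.array([0.6, 0.8, 0.5]), 0.25
    )
    image, labels, truth = cm.render_image(specs, pats, noise_sd=0.0, seed=7, shape=(768, 768))
    return image, labels, truth


@pytest.fixture(scope="session")
def noisy_field():
    """50-cell field at the default noise level, with ground truth."""
    rng = np.random.default_rng(5)
    specs = sample_population(rng, 50, (640, 640))
    pats = sample_patterns(
        rng, specs, np.array([130.0, 110.0, 125.0]), np.array([0.6, 0.8, 0.5]), 0.25
    )
    image, labels, truth = cm.render_image(specs, pats, noise_sd=6.0, seed=3, shape=(640, 640))
    return image, labels, truth
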