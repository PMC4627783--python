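import numpy as np
import pytest

from uterosnake import OrganShape, PhantomSpec, generate
from uterosnake.pipeline import RunConfig
from uterosnake.snake import SnakeParams


def disk_spec(radius=25, contrast=120, seed=11, **kw):
    """Noise-free disk phantom spec on a 128x128 grid."""
    defaults = dict(
        shape=(128, 128),
        organ=OrganShape(center=(64.0, 64.0), a=radius, b=radius, rotation_deg=0.0),
        organ_mean=80.0 + contrast,
        background_mean=80.0,
        speckle_shape=None,
        edge_blur_sigma=0.0,
        n_specular=0,
        seed=seed,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def disk_case():
    """A clean disk phantom (radius 25, contrast 120)."""
    return generate(disk_spec())


@pytest.fixture(scope="session")
def speckled_case():
    """A default speckled ellipse phantom."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_config():
    """Segmentation protocol for noise-free images: analysis scale matched
    to the sharp edge, tight settle tolerance."""
    return RunConfig(
        snake=SnakeParams(
            gradient_sigma=1.0, coarse_sigmas=(4.0, 2.0), max_iters=2000, tol=0.002
        ),
        do_preprocess=False,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
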