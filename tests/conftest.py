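"""Shared fixtures: small, fast phantom scenes for unit-level checks."""

import numpy as np
import pytest

from icgmargin.phantom_sim import (
    ChamberGeometry,
    ChamberKinetics,
    PhantomConfig,
    generate_phantom,
)


def small_config(seed: int = 0, noise_sd: float = 2.0, **overrides) -> PhantomConfig:
    """A 120×160, 8 s @ 10 fps dual-chamber scene that renders in ~0.1 s."""
    kwargs = dict(
        chambers=[
            (
                ChamberGeometry(kind="rectangle", params=(16, 16, 48, 144)),
                ChamberKinetics(t_arrival=0.8, k_in=1.5, k_out=0.15, amplitude=0.75),
            ),
            (
                ChamberGeometry(kind="rectangle", params=(72, 16, 104, 144)),
                ChamberKinetics(t_arrival=1.2, k_in=0.5, k_out=0.05, amplitude=0.75),
            ),
        ],
        frame_shape=(120, 160),
        frame_rate=10.0,
        duration=8.0,
        rim_width=4.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """(stack, truth) for the default small scene, rendered once per session."""
    return generate_phantom(small_config(seed=0))


@pytest.fixture(scope="session")
def small_phantom_clean():
    """Noise-free render of the small scene."""
    return generate_phantom(small_config(seed=0, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
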