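"""Shared fixtures: small, fast synthetic scenes with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from astrodomain import ChannelSpec, PreprocessParams, QuantParams, SceneConfig

# Preprocessing scaled to the 0.05 um/px test sampling (structures are ~half
# the pixel extent of the 0.049 um/px acquisition default).
FAST_PP = PreprocessParams(
    background_radius_px=25, bandpass_small_px=2.0, bandpass_large_px=20.0
)

# Size filter admitting single diffraction-limited test puncta.
FAST_QUANT = QuantParams(min_area_um2=0.02, max_area_um2=2.0, preprocess=FAST_PP)


def clean_scene_config(
    seed: int,
    field_size_um: float = 25.0,
    pixel_size_um: float = 0.05,
    pre_density: float = 0.4,
    post_density: float = 0.0,
    coloc_fraction: float = 0.0,
    coloc_jitter_um: float = 0.0,
    **kwargs,
) -> SceneConfig:
    """Noise-free, background-free scene for recovery-style tests."""
    return SceneConfig(
        field_size_um=field_size_um,
        pixel_size_um=pixel_size_um,
        channel_specs=(
            ChannelSpec("pre", density_per_um2=pre_density),
            ChannelSpec("post", density_per_um2=post_density),
        ),
        coloc_fraction=coloc_fraction,
        coloc_jitter_um=coloc_jitter_um,
        background_level=0.0,
        noise_sd=0.0,
        blob_density_per_um2=0.0,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
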