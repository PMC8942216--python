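"""Shared fixtures: seeded rngs, small phantom cohorts, corruption presets."""

from dataclasses import replace

import numpy as np
import pytest

from woundmetry.phantom import (
    default_corruption_sampler,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def benign_corruption_sampler(rng, day):
    """Lighting/blur/orientation nuisances only: no occlusion, no extra
    blobs, so a segmenter can in principle recover the true geometry."""
    return replace(
        default_corruption_sampler(rng, day),
        occlusion_fraction=0.0,
        false_component_count=0,
    )


@pytest.fixture(scope="session")
def benign_cohort():
    """2 mice x 8 days, benign corruption, moderate resolution."""
    return generate_cohort(
        2,
        8,
        corruption_sampler=benign_corruption_sampler,
        rng=np.random.default_rng(11),
        mm_per_pixel=0.1,
    )


@pytest.fixture(scope="session")
def full_cohort():
    """4 mice x 16 days with the default corruption mix (the study layout)."""
    return generate_cohort(4, 16, rng=np.random.default_rng(7), mm_per_pixel=0.1)


@pytest.fixture(scope="session")
def crop_cohort_64():
    """Crop-sized (64 px) phantom frames for fast segmenter training."""
    return generate_cohort(
        3,
        8,
        corruption_sampler=benign_corruption_sampler,
        rng=np.random.default_rng(21),
        mm_per_pixel=0.3,
        scale_jitter=0.1,
        frame_shape=(64, 64),
    )
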