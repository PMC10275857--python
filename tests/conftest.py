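"""Shared fixtures: small synthetic fields and datasets, generated on the fly."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from her2fish.simgen import SyntheticSpec, render_fish_image, spec_for_group


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A compact field: fast to render, still multi-nucleus."""
    return SyntheticSpec(
        image_size=(192, 192),
        n_nuclei=(3, 5),
        nucleus_radius=(14, 22),
        her2_spot_radius=(1.5, 2.5),
        cep17_spot_radius=(1.5, 2.5),
    )


@pytest.fixture(scope="session")
def clean_group1_image(small_spec):
    """One rendered amplified-regime field with its ground truth."""
    spec = spec_for_group(1, small_spec)
    return render_fish_image(spec, seed=101)


@pytest.fixture(scope="session")
def blank_image() -> np.ndarray:
    return np.zeros((96, 96, 3), dtype=np.float64)


@pytest.fixture(scope="session")
def noise_free_spec(small_spec) -> SyntheticSpec:
    return dataclasses.replace(small_spec, background_noise=0.0)
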