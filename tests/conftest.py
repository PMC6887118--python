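"""Shared fixtures: noise-free simulation configs and scripted profiles."""

from __future__ import annotations

import numpy as np
import pytest

from axomito.kymo import AxonFrameSeries
from axomito.synthetic import SimConfig, _box_profile


def clean_config(seed: int = 0, **overrides) -> SimConfig:
    """A noise-free, detection-friendly configuration: moderate crowding,
    mitochondria long enough to fission, all auxiliary channels off."""
    kwargs = dict(
        seed=seed, axon_length=100.0, n_mito=5,
        mito_length_dist=(3.0, 0.25), min_mito_length=1.5,
        fission_prob_per_10min=0.6, fusion_prob_per_10min=0.5,
        motility_fractions=(0.7, 0.15, 0.15),
        patch_rate=0.0, drp1_rate_per_mito_per_10min=0.0,
        noise=(0.0, 0.0))
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture
def make_clean_config():
    return clean_config


class ProfileBuilder:
    """Scripted 1-D profile series for event-calling tests."""

    def __init__(self, length_um: float = 30.0, n_frames: int = 60,
                 pixel_size: float = 0.12, frame_interval: float = 3.0,
                 background: float = 5.0, psf_sigma: float = 0.15):
        self.px = pixel_size
        self.sigma = psf_sigma
        self.n = int(round(length_um / pixel_size))
        self.x = (np.arange(self.n) + 0.5) * pixel_size
        self.data = np.full((n_frames, self.n), float(background))
        self.frame_interval = frame_interval

    def add(self, frames, start: float, end: float, intensity: float):
        prof = intensity * _box_profile(self.x, start, end, self.sigma)
        self.data[frames] += prof
        return self

    def series(self, channel: str = "mito") -> AxonFrameSeries:
        return AxonFrameSeries(self.data.copy(), self.px,
                               self.frame_interval, channel=channel)


@pytest.fixture
def profile_builder():
    return ProfileBuilder
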