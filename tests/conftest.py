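"""Shared fixtures: toy phantom volumes and small trained models."""

from __future__ import annotations

import numpy as np
import pytest

from prlquant.phantom import PhantomSpec, Ellipse, generate_volume


def make_toy_spec(seed: int = 0, *, n_bscans: int = 4, n_depth: int = 64,
                  n_ascans: int = 64, thickness: float = 8.0,
                  speckle: float = 0.1, disruption: bool = False) -> PhantomSpec:
    spec = PhantomSpec(
        n_bscans=n_bscans, n_depth=n_depth, n_ascans=n_ascans,
        band_center_row=0.55, band_thickness_px=thickness,
        thickness_amplitude=1.5, center_amplitude=2.0,
        speckle_sigma=speckle, seed=seed,
    )
    if disruption:
        rng = np.random.default_rng(seed + 13)
        spec.disruptions = [Ellipse(
            center_b=float(rng.uniform(0, n_bscans)),
            center_x=float(rng.uniform(0.3, 0.7) * n_ascans),
            radius_b=1.5, radius_x=float(rng.uniform(3, 8)),
        )]
    return spec


def make_toy_pairs(seeds, disruption_every_other: bool = True, **kw):
    """Flatten toy volumes into (B-scan, mask) training pairs."""
    pairs = []
    for j, s in enumerate(seeds):
        vol, truth = generate_volume(
            make_toy_spec(s, disruption=disruption_every_other and j % 2 == 1, **kw)
        )
        for b in range(vol.n_bscans):
            pairs.append((vol.voxels[b], truth.mask.mask[b]))
    return pairs


@pytest.fixture(scope="session")
def toy_volume():
    """One small noisy phantom volume with a disruption, plus its truth."""
    return generate_volume(make_toy_spec(3, disruption=True))


@pytest.fixture(scope="session")
def trained_tiny_unet():
    """A tiny U-Net trained briefly on toy phantoms (shared across tests)."""
    from prlquant.networks import ModelConfig, build_model, train_model

    cfg = ModelConfig(arch_name="unet", depth=3, base_channels=8,
                      max_epochs=12, patience=6, learning_rate=2e-3, seed=5)
    pairs = make_toy_pairs(range(4))
    val = make_toy_pairs([90])
    return train_model(build_model(cfg), pairs, val, cfg)
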