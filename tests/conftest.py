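"""Shared fixtures: phantoms and trained models reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ceustic.frame_io import DEFAULT_REGIONS
from ceustic.segmentation import GroundTruthMaskProvider
from ceustic.synthetic import PerfusionSpec, PhantomConfig, render_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, motionless phantom: exact round-trip truth for TIC checks."""
    cfg = PhantomConfig(
        duration=120.0,
        frame_rate=1.0,
        drift=(0.0, 0.0),
        breathing_amplitude=0.0,
        lesion=PerfusionSpec(120.0, 15.0, 2.0, 30.0, 20.0, 0.0),
        parenchyma=PerfusionSpec(70.0, 20.0, 2.0, 45.0, 15.0, 0.0),
        seed=11,
    )
    return render_phantom(cfg)


@pytest.fixture(scope="session")
def default_phantom():
    """Default study conditions (noise, drift, breathing), short-ish run."""
    return render_phantom(PhantomConfig(duration=120.0, frame_rate=2.0, seed=5))


@pytest.fixture(scope="session")
def lift_phantom():
    """Phantom with a probe lift in the slowly-varying post-peak region."""
    return render_phantom(
        PhantomConfig(duration=120.0, frame_rate=2.0, seed=3, probe_lift=((60.0, 63.0),))
    )


@pytest.fixture()
def gt_provider():
    def make(phantom):
        return GroundTruthMaskProvider(phantom.masks, DEFAULT_REGIONS["b_mode"])

    return make


@pytest.fixture(scope="session")
def trained_unet():
    """Desk-scale U-Net trained once on easy phantom frames (shared, slow)."""
    from ceustic.segmentation import train_unet
    from ceustic.synthetic import segmentation_training_set

    images, masks = segmentation_training_set(64, seed=0)
    provider, history = train_unet(
        images, masks, epochs=20, seed=0, target_val_dice=0.97
    )
    holdout_images, holdout_masks = segmentation_training_set(12, seed=99)
    return {
        "provider": provider,
        "history": history,
        "holdout": (holdout_images, holdout_masks),
    }
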