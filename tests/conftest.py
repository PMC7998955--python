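"""Shared fixtures: small simulated videos, crops and trained classifiers.

Session-scoped so the (comparatively) expensive video simulation and
detection passes run once and are reused across test modules.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icedrop import classify, detect, pipeline, synthdrop

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 20259


@pytest.fixture(scope="session")
def bf_extreme_stacks():
    """Bright-field training videos: all-liquid (warm) and all-frozen (cold)."""
    warm, warm_truth = synthdrop.simulate_video(
        -2.0, 60, "brightfield", p_frozen=0.0, seed=SEED
    )
    cold, cold_truth = synthdrop.simulate_video(
        -11.0, 60, "brightfield", p_frozen=1.0, seed=SEED + 1
    )
    return warm, warm_truth, cold, cold_truth


@pytest.fixture(scope="session")
def bf_extreme_crops(bf_extreme_stacks):
    warm, _, cold, _ = bf_extreme_stacks
    _, liquid = detect.process_stack(warm)
    _, frozen = detect.process_stack(cold)
    return liquid, frozen


@pytest.fixture(scope="session")
def trained_model(bf_extreme_crops):
    liquid, frozen = bf_extreme_crops
    return classify.train_classifier(liquid, frozen, seed=SEED)


@pytest.fixture(scope="session")
def pol_reference_crops():
    """Polarized calibration references from extreme-temperature videos."""
    warm, _ = synthdrop.simulate_video(
        -2.0, 60, "polarized", p_frozen=0.0, seed=SEED + 2
    )
    cold, _ = synthdrop.simulate_video(
        -11.0, 60, "polarized", p_frozen=1.0, seed=SEED + 3
    )
    _, warm_crops = detect.process_stack(warm)
    _, cold_crops = detect.process_stack(cold)
    return pipeline.reference_crops_from_extremes(warm_crops, cold_crops)


@pytest.fixture(scope="session")
def calibrated_thresholds(pol_reference_crops):
    liq, bright, dark = pol_reference_crops
    return classify.calibrate_thresholds(liq, bright, dark if dark else None)


@pytest.fixture(scope="session")
def pol_eval_scene():
    """A polarized mixed-state video with tracks matched to its ground truth."""
    stack, truth = synthdrop.simulate_video(
        -6.5, 120, "polarized", p_frozen=0.5, seed=SEED + 4,
        subtype_mix=(0.5, 0.2, 0.3),
    )
    tracks, crops = detect.process_stack(stack)
    mapping = detect.match_tracks_to_truth(tracks, truth)
    return stack, truth, tracks, crops, mapping


def make_uniform_disk_crop(s_value: float, side: int = 64) -> np.ndarray:
    """A crop whose droplet disk has uniform intensity ``s_value``.

    The area outside the disk is filled with an arbitrary distinct level to
    check that classifiers only look inside the disk mask.
    """
    crop = np.full((side, side), 0.9, dtype=np.float32)
    radius = side / (2.0 * classify.CROP_FACTOR)
    ax = np.arange(side) - (side - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    crop[np.hypot(xx, yy) <= radius] = s_value
    return crop
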