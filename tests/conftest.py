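import numpy as np
import pytest

from vasquant import FishSimParams, generate_fish_image
from vasquant.io import detect_spots


def match_spots(detected_xy, truth_xy, radius=2.0):
    """Optimal one-to-one matching within a radius; returns (tp, n_det, n_true)."""
    from scipy.optimize import linear_sum_assignment

    detected_xy = np.asarray(detected_xy, dtype=float)
    truth_xy = np.asarray(truth_xy, dtype=float)
    if len(detected_xy) == 0 or len(truth_xy) == 0:
        return 0, len(detected_xy), len(truth_xy)
    d = np.linalg.norm(detected_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    cost = np.where(d <= radius, d, 1e6)
    ri, ci = linear_sum_assignment(cost)
    tp = int((cost[ri, ci] < 1e6).sum())
    return tp, len(detected_xy), len(truth_xy)


@pytest.fixture(scope="session")
def fish_scene():
    """One deterministic synthetic FISH projection with its annotations."""
    params = FishSimParams(seed=11)
    stack, annots, truth = generate_fish_image(params)
    return params, stack, annots, truth


@pytest.fixture(scope="session")
def detected(fish_scene):
    params, stack, annots, truth = fish_scene
    spots = detect_spots(stack.channel("FISH"), params.pixel_size,
                         spot_diameter=0.8)
    return spots
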