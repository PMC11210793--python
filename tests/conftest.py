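import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chemotax as ct

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def full_scale_arena():
    """One full-resolution (1,200 dpi) arena with 200 worms plus ground truth."""
    spec = ct.SyntheticArenaSpec(worm_count=200, seed=1)
    img, gt = ct.render_arena(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def located_full_scale(full_scale_arena):
    """Location tables for the full-scale arena (computed once)."""
    _, img, _ = full_scale_arena
    scan = ct.GrayscaleScan(img, dpi=1200, image_id="FIX")
    return ct.locate_worms(scan, wells_per_plate=1)


@pytest.fixture(scope="session")
def multi_plate_scan():
    """Reduced-resolution (150 dpi) scan of two plates x four lanes."""
    scale = 150 / 1200
    specs = [
        ct.SyntheticArenaSpec(
            dpi=150,
            image_width_px=int(3300 * scale),
            image_height_px=int(1100 * scale),
            worm_count=12,
            worm_area_range=(max(6, int(200 * scale**2)), int(900 * scale**2)),
            seed=40 + p,
        )
        for p in range(2)
    ]
    img, truths = ct.render_scan(specs, wells_per_plate=4)
    return img, truths


def match_centroids(found_xy: np.ndarray, true_xy: np.ndarray):
    """Nearest-neighbor distances from each true centroid to a found one."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(found_xy).query(true_xy)
    return d
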