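import numpy as np
import pytest

import vulm
from vulm.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Three small deterministic stacks with ground truth."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_grid():
    return vulm.GridSpec((32, 32, 32))


@pytest.fixture(scope="session")
def mirror_network(small_grid):
    return vulm.generate_vessel_network(
        tuple(small_grid.extent_mm), n_trees=2, mirror=True, seed=7)


def well_separated_truth(grid, n_bubbles, n_volumes, speed_mm_s=0.0,
                         seed=0, min_sep_vox=8.0):
    """Ground truth with bubbles on a jittered lattice, guaranteed apart.

    Bubbles move laterally at ``speed_mm_s``; positions start well inside
    the grid so they remain separated for the whole run.
    """
    import pandas as pd
    rng = np.random.default_rng(seed)
    ext = grid.extent_mm
    sep = min_sep_vox * grid.voxel_size
    # lattice of candidate sites with margin for PSF support and motion
    travel = speed_mm_s / 500.0 * n_volumes
    margin = 4 * grid.voxel_size
    zs = np.arange(margin, ext[0] - margin, sep)
    xs = np.arange(margin, ext[1] - margin - travel, sep)
    ys = np.arange(margin, ext[2] - margin, sep)
    sites = np.array([(z, x, y) for z in zs for x in xs for y in ys])
    assert len(sites) >= n_bubbles, "grid too small for requested bubbles"
    pick = rng.choice(len(sites), size=n_bubbles, replace=False)
    base = sites[pick] + rng.uniform(-0.3, 0.3, (n_bubbles, 3)) \
        * grid.voxel_size
    step = speed_mm_s / 500.0
    rows = []
    for t in range(n_volumes):
        for b in range(n_bubbles):
            rows.append((t, b, base[b, 0], base[b, 1] + t * step,
                         base[b, 2], speed_mm_s, b))
    df = pd.DataFrame(rows, columns=["volume_index", "bubble_id", "z_mm",
                                     "x_mm", "y_mm", "speed_mm_s",
                                     "segment_id"])
    return vulm.MBGroundTruth(df, volume_rate=500.0, n_volumes=n_volumes)
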