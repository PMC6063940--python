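import numpy as np
import pytest

from scutoidsim import lloyd_relax, sample_seeds, build_tube
from scutoidsim.reporting import flip_fixture


@pytest.fixture(scope="session")
def small_relaxed_seeds():
    """CVT-relaxed 40-cell seed set on a 128x1024 periodic domain."""
    return lloyd_relax(sample_seeds(40, 128, 1024, rng=7), iterations=4)


@pytest.fixture(scope="session")
def small_tube(small_relaxed_seeds):
    """40-cell tube at surface ratio 2.5."""
    return build_tube(small_relaxed_seeds, 2.5)


@pytest.fixture(scope="session")
def medium_relaxed_seeds():
    """100-cell CVT seed set: ~4.5 cells around the circumference."""
    return lloyd_relax(sample_seeds(100, 256, 1024, rng=11), iterations=4)


@pytest.fixture(scope="session")
def flip_pair():
    """Hand-built apical/basal rasters containing exactly one diagonal flip."""
    return flip_fixture()


@pytest.fixture(scope="session")
def flip_pair_scaled():
    return flip_fixture(scale=3)


def periodic_brute_labels(seeds):
    """Independent per-pixel periodic nearest-seed oracle (lowest id ties)."""
    w, h = seeds.width_px, seeds.height_px
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    px, py = np.meshgrid(xs, ys)
    best_d = np.full((h, w), np.inf)
    best_i = np.zeros((h, w), dtype=np.int32)
    for i, (sx, sy) in enumerate(seeds.points):
        dx = np.abs(px - sx)
        dx = np.minimum(dx, w - dx)
        d = dx * dx + (py - sy) ** 2
        better = d < best_d - 1e-9
        best_d = np.where(better, d, best_d)
        best_i = np.where(better, i, best_i)
    return best_i
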