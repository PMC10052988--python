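import numpy as np
import pytest

from tileqc import synthetic


@pytest.fixture(scope="session")
def small_slide():
    """80-tile synthetic slide with a 30% poor mixture (session-cached)."""
    return synthetic.generate_slide(
        synthetic.SlideSpec(n_tiles=80, fraction_poor=0.3, seed=11))


@pytest.fixture(scope="session")
def good_tile():
    return synthetic.generate_tile(
        synthetic.TileSpec(nuclear_density=0.25, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def oracle_min_inertia(points: np.ndarray) -> float:
    """Exhaustive 2-cluster within-SS minimization over all bipartitions.

    Independent of any k-means code path: enumerates every nonempty
    bipartition of the points as a bitmask and evaluates the within-cluster
    sum of squares in closed form (SS = Σ|x|² − |Σx|²/n per group).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    masks = np.arange(1, 2 ** n - 1, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(float)
    cnt1 = bits.sum(axis=1)
    cnt0 = n - cnt1
    s1 = bits @ pts
    s0 = pts.sum(axis=0) - s1
    ss = (pts ** 2).sum() - (s1 ** 2).sum(axis=1) / cnt1 - (s0 ** 2).sum(axis=1) / cnt0
    return float(ss.min())
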