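import numpy as np
import pytest

from crystalsizer import CrystalAngles, FitConfig, HexTemplate


@pytest.fixture
def angles():
    return CrystalAngles()


@pytest.fixture
def needle_template():
    """A needle-habit template like the default synthetic crystal."""
    return HexTemplate(
        center=np.array([64.0, 66.0]),
        theta1=15.0,
        dists=np.array([[14.0, 16.0], [34.0, 37.0], [33.0, 35.0]]),
    )


@pytest.fixture
def fast_cfg():
    """Reduced-effort fit configuration for unit tests on small frames."""
    return FitConfig(n_candidates=8, prescreen_iters=60, max_iters=400)


def random_active_template(rng, shape=(128, 128), lo=15.0, hi=40.0):
    """Random template whose six faces are all active (6-vertex polygon)."""
    from crystalsizer import polygon_vertices

    while True:
        t = HexTemplate(
            center=np.array([shape[1] / 2, shape[0] / 2]) + rng.uniform(-4, 4, 2),
            theta1=rng.uniform(0, 180),
            dists=rng.uniform(lo, hi, size=(3, 2)),
        )
        if len(polygon_vertices(t)) == 6:
            return t
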