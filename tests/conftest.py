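import numpy as np
import pytest

from tumorbed import SlideSpec, generate_slide


SQUARE = np.array([[150.0, 150.0], [350.0, 150.0], [350.0, 350.0], [150.0, 350.0]])


@pytest.fixture(scope="session")
def square_slide():
    """512×512 synthetic slide with a single 200-px square tumor."""
    spec = SlideSpec(width_px=512, height_px=512, tumor_polygons=(SQUARE,), seed=3)
    return generate_slide(spec)


@pytest.fixture(scope="session")
def tumor_free_slide():
    spec = SlideSpec(width_px=384, height_px=384, tumor_polygons=(), seed=9)
    return generate_slide(spec)


def random_convex_polys(n_polys, rng, n_points_max=50, radius=(5.0, 200.0)):
    """Random convex polygons (vertex arrays) for geometry oracle tests."""
    from tumorbed.geometry import random_convex_polygon

    polys = []
    for _ in range(n_polys):
        center = rng.uniform(-500, 500, 2)
        rad = rng.uniform(*radius)
        n = int(rng.integers(4, n_points_max + 1))
        polys.append(random_convex_polygon(rng, center, rad, n_points=n))
    return polys
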