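import numpy as np
import pytest

from boxfd.synthetic import ContourSpec, RenderSpec, generate_circle_contour, generate_fractal_contour


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


@pytest.fixture(scope="session")
def circle12():
    """720-vertex circle of radius 12 mm."""
    return generate_circle_contour(12.0, 720)


@pytest.fixture(scope="session")
def rough_contour():
    """A representative rough annulus contour."""
    return generate_fractal_contour(
        ContourSpec(base_radius_mm=12.0, roughness_amplitude=0.05,
                    hurst_exponent=0.4, n_vertices=256, seed=42))


@pytest.fixture(scope="session")
def clean_render():
    return RenderSpec(mm_per_pixel=0.1, image_size_px=(520, 520))


def brute_force_box_count(contour, caliber, origin=(0.0, 0.0)):
    """Independent oracle: test every grid box in the bounding region against
    every segment with shapely (closed boxes; touching counts)."""
    import shapely.geometry as sg

    p, q = contour.segments()
    line = sg.MultiLineString([((a[0], a[1]), (b[0], b[1])) for a, b in zip(p, q)])
    xmin, ymin, xmax, ymax = contour.bounds()
    i0 = int(np.floor((xmin - origin[0]) / caliber)) - 2
    i1 = int(np.floor((xmax - origin[0]) / caliber)) + 2
    j0 = int(np.floor((ymin - origin[1]) / caliber)) - 2
    j1 = int(np.floor((ymax - origin[1]) / caliber)) + 2
    count = 0
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            box = sg.box(origin[0] + i * caliber, origin[1] + j * caliber,
                         origin[0] + (i + 1) * caliber, origin[1] + (j + 1) * caliber)
            if box.intersects(line):
                count += 1
    return count
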