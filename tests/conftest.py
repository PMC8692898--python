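import numpy as np
import pytest

import serialstain as ss


@pytest.fixture(scope="session")
def small_layout():
    """512x512 tissue with two glands; shared by stain/density tests."""
    return ss.make_tissue_layout(512, 512, 2, seed=11)


@pytest.fixture(scope="session")
def small_points(small_layout):
    rates = {"POSTN": {"T": 5e-5, "IF": 1.5e-4, "S": 3e-4}}
    return ss.plant_marker_points(small_layout, rates, seed=12)[0]


@pytest.fixture(scope="session")
def small_slide(small_layout, small_points):
    return ss.render_ihc_image(small_layout, small_points, blob_radius=4, dab_od=0.8)


@pytest.fixture(scope="session")
def small_study():
    """3-section 800x800 study with smooth deformations (~15 px at 500-px scale)."""
    markers = ["POSTN", "CD163", "COL1A1"]
    rates = {m: {"T": 8e-5, "IF": 1.5e-4, "S": 2.5e-4} for m in markers}
    return ss.make_serial_study(
        markers, rates, size=(800, 800), n_glands=2, max_disp=24.0, smoothness=160.0, seed=21
    )


@pytest.fixture(scope="session")
def disjoint_blob_slide():
    """A slide with well-separated planted blobs for exact count recovery."""
    layout = ss.make_tissue_layout(512, 512, 1, seed=31)
    rng = np.random.default_rng(32)
    rr, cc = np.nonzero(layout.tissue_mask)
    pts: list[tuple[float, float]] = []
    order = rng.permutation(len(rr))
    for k in order:
        cand = (float(rr[k]), float(cc[k]))
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 > 30**2 for p in pts):
            pts.append(cand)
        if len(pts) == 25:
            break
    points = ss.MarkerPointSet(marker="CD34", points=np.array(pts))
    slide = ss.render_ihc_image(layout, points, blob_radius=5, dab_od=0.8)
    return layout, points, slide
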