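import numpy as np
import pytest

from immunotopo import celldetect, stainsep, synthcore


@pytest.fixture(scope="session")
def hdab():
    return stainsep.StainVectorSet.hdab_default()


@pytest.fixture(scope="session")
def small_core():
    """One rendered 0.6 mm core at 1 um/px with CD3 at 500/400 cells/mm^2."""
    spec = synthcore.CoreSpec(
        core_diameter_um=600.0,
        pixel_size_um=1.0,
        marker_densities={"CD3": (500.0, 400.0)},
        seed=1,
    )
    images, truth = synthcore.generate_core(spec)
    return spec, images["CD3"], truth


@pytest.fixture(scope="session")
def core_channels(small_core, hdab):
    """(channel OD, deconvolved stain OD, tissue mask) of the small core."""
    _, image, _ = small_core
    od = stainsep.rgb_to_od(image, hdab.background)
    sep = stainsep.deconvolve(od, hdab)
    tissue = celldetect.simple_tissue_detection(od, pixel_size_um=1.0)
    return od, sep, tissue


def match_centroids(true_xy: np.ndarray, det_xy: np.ndarray, radius: float):
    """Hungarian one-to-one matching of point sets within a gating radius.

    Returns (n_matched, precision, recall, f1).
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    if len(true_xy) == 0 or len(det_xy) == 0:
        return 0, 0.0, 0.0, 0.0
    d = cdist(true_xy, det_xy)
    rows, cols = linear_sum_assignment(d)
    tp = int((d[rows, cols] <= radius).sum())
    precision = tp / len(det_xy)
    recall = tp / len(true_xy)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return tp, precision, recall, f1
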