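import numpy as np
import pytest
from scipy.spatial import cKDTree

import evtirf as ev


@pytest.fixture
def panel():
    return ev.MarkerPanel()


@pytest.fixture
def small_imaging():
    # 20 um side -> 200 px field: fast but large enough for robust statistics
    return ev.ImagingConfig(field_area_um2=400.0)


def match_detections(truth_xy: np.ndarray, det_xy: np.ndarray, tol_um: float):
    """Greedy one-to-one matching of detections to truth positions.

    Returns (n_matched, n_truth, n_detected).
    """
    if len(det_xy) == 0 or len(truth_xy) == 0:
        return 0, len(truth_xy), len(det_xy)
    tree = cKDTree(det_xy)
    used: set[int] = set()
    hits = 0
    for p in truth_xy:
        dists, idxs = tree.query(p, k=min(3, len(det_xy)))
        for d, i in zip(np.atleast_1d(dists), np.atleast_1d(idxs)):
            if d <= tol_um and i not in used:
                used.add(int(i))
                hits += 1
                break
    return hits, len(truth_xy), len(det_xy)


@pytest.fixture
def matcher():
    return match_detections
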