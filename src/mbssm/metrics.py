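"""Point-cloud distance measures used to evaluate shape models.

Three measures, all in mm:

* ``rms_distance`` — root mean square over all 3m coordinate differences,
  RMS(o, t) = sqrt((1/3m) sum_i (o_i - t_i)^2).
* ``avg_point_distance`` — mean Euclidean distance over the m corresponding
  point pairs, d(o, t) = (1/m) sum_i ||p_{o,i} - p_{t,i}||.  Preferred for
  reporting because it reads directly as a 3D error.
* ``hausdorff_distance`` — bidirectional Hausdorff metric, the larger of the
  two directed max-of-min nearest-neighbour distances; a worst-case measure
  that ignores correspondence.

By Jensen's inequality for the concave square root, the mean of per-point
distances never exceeds the root of the mean of their squares, so typically
d(o, t) is of the same order as, and at most sqrt(3) times, the RMS.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .shapes import as_points

__all__ = ["rms_distance", "avg_point_distance", "hausdorff_distance"]

# above this size, brute-force m^2 nearest neighbours give way to a KD-tree
_BRUTE_FORCE_LIMIT = 2048


def _paired(o, t) -> tuple[np.ndarray, np.ndarray]:
    po, pt = as_points(o), as_points(t)
    if po.shape != pt.shape:
        raise ValueError(f"point clouds differ in shape: {po.shape} vs {pt.shape}")
    return po, pt


def rms_distance(o, t) -> float:
    """RMS difference over all 3m coordinates of two corresponded clouds."""
    po, pt = _paired(o, t)
    return float(np.sqrt(np.mean((po - pt) ** 2)))


def avg_point_distance(o, t) -> float:
    """Mean Euclidean distance over corresponding point pairs."""
    po, pt = _paired(o, t)
    return float(np.mean(np.linalg.norm(po - pt, axis=1)))


def hausdorff_distance(o, t) -> float:
    """Bidirectional Hausdorff distance; correspondence order is not used."""
    po, pt = as_points(o), as_points(t)
    if po.shape[0] == 0 or pt.shape[0] == 0:
        raise ValueError("Hausdorff distance requires non-empty clouds")
    if max(po.shape[0], pt.shape[0]) <= _BRUTE_FORCE_LIMIT:
        d = cdist(po, pt)
        return float(max(d.min(axis=1).max(), d.min(axis=0).max()))
    forward = cKDTree(pt).query(po, k=1)[0].max()
    backward = cKDTree(po).query(pt, k=1)[0].max()
    return float(max(forward, backward))
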