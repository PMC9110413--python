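"""Skeleton-based length measurement shared by the diffraction-limited and
super-resolution pipelines.

A binary particle footprint is thinned to a single-pixel-wide skeleton and its
length is the longest geodesic path through the skeleton's 8-connected graph,
counting axial steps as 1 and diagonal steps as sqrt(2) pixels.  The longest
geodesic is preferred over the total skeleton length for elongated fibrils
(branched skeletons would otherwise overcount); the total is also returned.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from skimage.morphology import skeletonize

SQRT2 = float(np.sqrt(2.0))

# 8-neighbour offsets and their step costs in pixel units
_OFFSETS = [(-1, -1, SQRT2), (-1, 0, 1.0), (-1, 1, SQRT2),
            (0, -1, 1.0), (0, 1, 1.0),
            (1, -1, SQRT2), (1, 0, 1.0), (1, 1, SQRT2)]

# exact all-pairs geodesics below this skeleton size; double-sweep above
_EXACT_LIMIT = 1500


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide skeleton (Lee's 3-D thinning,
    which preserves end-point extent on bars and diagonals)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return mask.copy()
    if mask.sum() == 1:
        return mask.copy()
    return skeletonize(mask, method="lee").astype(bool)


def _skeleton_graph(skeleton: np.ndarray):
    """Sparse weighted adjacency of the skeleton's 8-connected pixel graph."""
    pts = np.argwhere(skeleton)
    n = len(pts)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(pts)}
    rows, cols, wts = [], [], []
    for i, (r, c) in enumerate(pts):
        for dr, dc, w in _OFFSETS:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                wts.append(w)
    graph = csr_matrix((wts, (rows, cols)), shape=(n, n))
    return pts, graph


def longest_geodesic_px(skeleton: np.ndarray) -> float:
    """Longest geodesic path length (pixel units) through a skeleton.

    Disconnected skeletons are handled per connected component; the maximum
    over components is returned.  A single pixel has length 0.
    """
    n = int(np.asarray(skeleton, dtype=bool).sum())
    if n <= 1:
        return 0.0
    pts, graph = _skeleton_graph(skeleton)
    n_comp, labels = connected_components(graph, directed=False)
    best = 0.0
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if len(idx) < 2:
            continue
        sub = graph[np.ix_(idx, idx)]
        if len(idx) <= _EXACT_LIMIT:
            dist = dijkstra(sub, directed=False)
            finite = dist[np.isfinite(dist)]
            best = max(best, float(finite.max()))
        else:
            # double-sweep: exact on trees, good approximation otherwise
            d0 = dijkstra(sub, directed=False, indices=0)
            far = int(np.nanargmax(np.where(np.isfinite(d0), d0, -1)))
            d1 = dijkstra(sub, directed=False, indices=far)
            best = max(best, float(d1[np.isfinite(d1)].max()))
    return best


def total_skeleton_px(skeleton: np.ndarray) -> float:
    """Total skeleton length in pixels: sum over unique 8-adjacent pixel pairs."""
    if np.asarray(skeleton, dtype=bool).sum() <= 1:
        return 0.0
    _, graph = _skeleton_graph(skeleton)
    return float(graph.sum()) / 2.0


def mask_length_px(mask: np.ndarray) -> tuple[float, float]:
    """(longest geodesic, total) skeleton length of a binary mask, in pixels."""
    sk = skeletonize_mask(mask)
    return longest_geodesic_px(sk), total_skeleton_px(sk)
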