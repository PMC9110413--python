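"""Deterministic classic DBSCAN.

Density-based clustering with radius ``eps`` and neighbour threshold
``min_pts`` (the point itself counts).  Clusters are expanded breadth-first in
ascending point-index order, so border points join the cluster of their
first-discovered core neighbour and the labelling is fully deterministic — a
property the staged burst-grouping pipeline relies on for reproducible output.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import cKDTree

NOISE = -1


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Cluster ``points`` (n, d); returns integer labels, -1 for noise.

    Neighbourhoods are closed balls of radius ``eps`` (boundary included),
    found with a k-d tree.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if eps <= 0:
        raise ValueError("eps must be positive")
    tree = cKDTree(points)
    neighbourhoods = tree.query_ball_point(points, eps)
    core = np.array([len(nb) >= min_pts for nb in neighbourhoods])
    labels = np.full(n, NOISE, dtype=int)
    cluster_id = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != NOISE:
            continue
        labels[seed] = cluster_id
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for q in sorted(neighbourhoods[p]):
                if labels[q] == NOISE:
                    labels[q] = cluster_id
                    if core[q]:
                        queue.append(q)
        cluster_id += 1
    return labels
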