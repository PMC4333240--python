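"""Detection and measurement of cell aggregates (immature Peyer's patches).

A patch is a single-linkage cluster of arrested motile cells: connected
components of the graph joining any two cells within the linking distance
(under the domain's periodic/reflective metric), keeping components with at
least ``min_size`` members.  Patch area is the summed footprint of its
member cells — monotone in member count and robust for small or elongated
clusters, unlike a convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class Patch:
    """One detected aggregate of arrested cells."""

    member_indices: np.ndarray  # indices into the input position array
    positions: np.ndarray  # (m, 2) wrapped member coordinates
    centroid: np.ndarray  # (2,) wrapped centroid
    area: float | None = None  # um^2, set when a cell radius is known

    @property
    def size(self) -> int:
        return len(self.member_indices)


def patch_area(p: Patch, cell_radius: float) -> float:
    """Summed cell-footprint area of a patch: ``size * pi * cell_radius**2``."""
    if p.size == 0:
        raise ValueError("patch area is undefined for an empty patch")
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    return p.size * np.pi * cell_radius**2


def _pairwise_wrapped_distance(
    xy: np.ndarray, width: float | None
) -> np.ndarray:
    d = xy[:, None, :] - xy[None, :, :]
    if width is not None:
        dx = d[..., 0]
        d[..., 0] = dx - width * np.round(dx / width)
    return np.sqrt(np.sum(d * d, axis=-1))


def detect_patches(
    positions: np.ndarray,
    linking_distance: float,
    min_size: int,
    *,
    width: float | None = None,
    cell_radius: float | None = None,
) -> list[Patch]:
    """Single-linkage clusters of arrested-cell positions.

    ``width`` enables the periodic x metric (pass the domain width; ``None``
    treats coordinates as plain Euclidean).  Centroids are computed in a
    frame unwrapped around each cluster's first member, then mapped back, so
    a cluster straddling the periodic seam gets a sensible centroid.
    Clusters smaller than ``min_size`` are discarded.
    """
    if linking_distance <= 0:
        raise ValueError("linking_distance must be positive")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        return []

    dist = _pairwise_wrapped_distance(positions.copy(), width)
    adj = dist <= linking_distance
    n = len(positions)
    ii, jj = np.nonzero(adj)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)

    patches: list[Patch] = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        if len(members) < min_size:
            continue
        pts = positions[members]
        ref = pts[0]
        rel = pts - ref
        if width is not None:
            rel[:, 0] -= width * np.round(rel[:, 0] / width)
        centroid = ref + rel.mean(axis=0)
        if width is not None:
            centroid[0] = np.mod(centroid[0], width)
        patch = Patch(
            member_indices=members,
            positions=pts,
            centroid=centroid,
        )
        if cell_radius is not None:
            patch.area = patch_area(patch, cell_radius)
        patches.append(patch)
    return patches
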