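"""Inter-capillary spacing via a nearest-vessel partition.

Every background pixel is assigned to the particle whose foreground is
nearest in Euclidean distance (a seeded distance watershed).  Two particles
are neighbors when their compartments share a 4-adjacent pixel pair; for
each neighbor pair the shortest boundary-to-boundary distance between the
two particles' foreground pixels is reported, and the mean over all
neighbor pairs is the mean inter-capillary distance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ptcmorph.morphometry import label_particles
from ptcmorph.segmentation import BinaryMask2D


def nearest_vessel_partition(mask: BinaryMask2D | np.ndarray) -> np.ndarray:
    """Assign every pixel the label of the nearest particle.

    Distances are Euclidean between pixel centers, from each background
    pixel to the nearest foreground pixel of each particle; exact ties go to
    the lowest label id.  Foreground pixels keep their own label.
    """
    labels, ids = label_particles(mask)
    if not ids:
        raise ValueError("empty mask: no particles to partition around")
    best_dist = np.full(labels.shape, np.inf)
    part = np.zeros(labels.shape, dtype=labels.dtype)
    for pid in ids:  # ascending: strict '<' gives ties to the lowest id
        d = ndimage.distance_transform_edt(labels != pid)
        closer = d < best_dist
        best_dist[closer] = d[closer]
        part[closer] = pid
    return part


def _boundary_pixels(labels: np.ndarray, pid: int) -> np.ndarray:
    m = labels == pid
    interior = ndimage.binary_erosion(m, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0)
    b = m & ~interior
    return np.argwhere(b if b.any() else m)


def neighbor_distances(
    mask: BinaryMask2D | np.ndarray,
    partition: np.ndarray | None = None,
    pixel_size: float | None = None,
) -> list[tuple[int, int, float]]:
    """Shortest boundary-to-boundary distances (µm) for all neighbor pairs.

    A pair of particles is a neighbor when their nearest-vessel compartments
    touch across a 4-adjacency; each unordered pair is listed once as
    ``(id_low, id_high, distance_um)``.
    """
    if pixel_size is None:
        pixel_size = mask.pixel_size if isinstance(mask, BinaryMask2D) else 1.0
    if partition is None:
        partition = nearest_vessel_partition(mask)
    labels, ids = label_particles(mask)
    pairs: set[tuple[int, int]] = set()
    for a, b in ((partition[:, :-1], partition[:, 1:]),
                 (partition[:-1, :], partition[1:, :])):
        diff = a != b
        la, lb = a[diff], b[diff]
        lo, hi = np.minimum(la, lb), np.maximum(la, lb)
        pairs.update(zip(lo.tolist(), hi.tolist()))
    boundary = {pid: _boundary_pixels(labels, pid) for pid in ids}
    trees = {pid: cKDTree(boundary[pid]) for pid in ids}
    out = []
    for i, j in sorted(pairs):
        d, _ = trees[j].query(boundary[i])
        out.append((i, j, float(d.min()) * pixel_size))
    return out


def mean_capillary_distance(
    mask: BinaryMask2D | np.ndarray,
    pixel_size: float | None = None,
) -> float:
    """Mean of the neighbor-pair shortest distances (µm).

    Raises for masks with fewer than two particles, where no neighbor pair
    exists.
    """
    dists = neighbor_distances(mask, pixel_size=pixel_size)
    if not dists:
        raise ValueError("no neighbor pairs: need at least two particles")
    return float(np.mean([d for _, _, d in dists]))
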