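"""Grey-level texture matrices: co-occurrence, run-length, zone, neighbourhood.

All matrices are built in 3-D over the VOI. Directional matrices (GLCM,
GLRLM) use the 13 unique 3-D directions at Chebyshev distance 1 and merge
counts across directions into a single matrix; zones (GLZLM) use 26-connected
components; the neighbourhood-difference statistics (NGLDM) use the 26
neighbours of each voxel, restricted to neighbours inside the VOI.

Grey levels are 1-based bin indices; the level value itself (not a bin
centre intensity) enters every index formula, as is conventional for
discretized PET texture analysis.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

#: The 13 unique 3-D directions (one of each ± pair), array axis order (z, y, x).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)


def _shifted_views(a: np.ndarray, d: tuple[int, int, int]):
    """Slices (src, dst) such that a[src] and b[dst] pair voxels offset by d."""
    src, dst = [], []
    for n, step in zip(a.shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                directions=DIRECTIONS_13) -> np.ndarray:
    """Symmetric co-occurrence probability matrix merged over directions.

    Entry (i, j), 0-indexed for levels i+1 and j+1, is the probability that a
    voxel pair at distance 1 along any of the directions has those levels,
    counting each pair in both orders (symmetry).
    """
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for d in directions:
        src, dst = _shifted_views(levels, d)
        valid = mask[src] & mask[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                 directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length count matrix (levels × run length), merged over directions.

    A run is a maximal sequence of equal-level VOI voxels along a direction.
    Along each single direction the run lengths weighted by length sum to the
    VOI voxel count; the merged matrix therefore sums to ``len(directions)``
    times the voxel count.
    """
    max_run = max(levels.shape)  # a straight run cannot exceed the box edge
    counts = np.zeros((n_levels, max_run), dtype=float)
    inside = mask & (levels > 0)
    coords = np.argwhere(inside)
    level_of = levels
    shape = levels.shape
    for d in directions:
        dz, dy, dx = d
        for z, y, x in coords:
            pz, py, px = z - dz, y - dy, x - dx
            # run starts where the predecessor along d is absent or differs
            if (0 <= pz < shape[0] and 0 <= py < shape[1] and 0 <= px < shape[2]
                    and inside[pz, py, px]
                    and level_of[pz, py, px] == level_of[z, y, x]):
                continue
            lev = level_of[z, y, x]
            length = 1
            nz, ny, nx = z + dz, y + dy, x + dx
            while (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
                   and inside[nz, ny, nx] and level_of[nz, ny, nx] == lev):
                length += 1
                nz, ny, nx = nz + dz, ny + dy, nx + dx
            counts[lev - 1, length - 1] += 1.0
    return counts


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glzlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size count matrix: 26-connected equal-level zones (levels × size)."""
    inside = mask & (levels > 0)
    n_vox = int(inside.sum())
    counts = np.zeros((n_levels, max(n_vox, 1)), dtype=float)
    # restrict labelling to the VOI bounding box for speed
    zz, yy, xx = np.nonzero(inside)
    box = (slice(zz.min(), zz.max() + 1), slice(yy.min(), yy.max() + 1),
           slice(xx.min(), xx.max() + 1))
    lev_box = np.where(inside[box], levels[box], 0)
    for lev in np.unique(lev_box[lev_box > 0]):
        lab, n_zones = ndimage.label(lev_box == lev, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[lev - 1, s - 1] += 1.0
    return counts


def ngldm_stats(levels: np.ndarray, mask: np.ndarray, n_levels: int
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occupancy and neighbourhood-difference sums.

    Returns ``(p, s, n_vox)`` where ``p[i]`` is the fraction of VOI voxels at
    level i+1, ``s[i]`` is the summed absolute difference between level i+1
    and the mean level of each such voxel's in-VOI 26-neighbourhood, and
    ``n_vox`` the VOI voxel count. Voxels with no in-VOI neighbour contribute
    zero difference.
    """
    inside = mask & (levels > 0)
    lev_f = np.where(inside, levels, 0).astype(float)
    neigh_sum = np.zeros(levels.shape)
    neigh_cnt = np.zeros(levels.shape)
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        src, dst = _shifted_views(lev_f, d)
        neigh_sum[dst] += lev_f[src]
        neigh_cnt[dst] += inside[src]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_neigh = np.where(neigh_cnt > 0, neigh_sum / np.maximum(neigh_cnt, 1), 0.0)
    diff = np.where(inside & (neigh_cnt > 0), np.abs(levels - mean_neigh), 0.0)

    n_vox = int(inside.sum())
    p = np.zeros(n_levels)
    s = np.zeros(n_levels)
    occupied = levels[inside] - 1
    np.add.at(p, occupied, 1.0)
    np.add.at(s, occupied, diff[inside])
    p /= n_vox
    return p, s, n_vox
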