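"""VOI definition, spatial resampling, and grey-level discretization.

Two discretization schemes are provided, following the absolute/relative
terminology used in PET radiomics:

* **FBS** (fixed bin size, "absolute"): ``level = floor(I / B) + 1`` for bin
  width ``B`` in SUV. Levels shift with the intensity scale.
* **FBN** (fixed bin number, "relative"): ``level = floor(D (I − I_min) /
  (I_max − I_min)) + 1`` clamped to ``D`` at ``I = I_max``. Invariant to
  affine rescaling of the VOI intensities.

The printed equations of both schemes omit the rounding operator; the
floor-plus-one form with a top-edge clamp is the convention adopted here (it
reproduces the ``I_max -> D`` branch exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import SUVImage
from .phantom import LesionTemplate

DEFAULT_BIN_WIDTH_SUV = 0.3125  # FBS bin width B
DEFAULT_BIN_COUNT = 64  # FBN bin count D


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class VOIMask:
    """Boolean volume-of-interest aligned to a SUVImage grid."""

    mask: np.ndarray
    voxel_volume_ml: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise PreprocessingError("VOI is empty")
        object.__setattr__(self, "mask", m)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml


@dataclass(frozen=True)
class GreyLevelVolume:
    """Integer grey levels over a VOI, ready for texture-matrix construction.

    ``levels`` is 0 outside the VOI; inside, levels start at 1. ``n_levels``
    is the largest occupied level (FBS) or the configured bin count D (FBN).
    """

    levels: np.ndarray  # 3-D int, 0 outside VOI
    mask: np.ndarray  # 3-D bool
    n_levels: int
    method: str  # "FBS" | "FBN"
    bin_width: float | None = None  # B, FBS only
    bin_count: int | None = None  # D, FBN only
    i_min: float | None = None  # FBN extrema within VOI
    i_max: float | None = None

    def voi_levels(self) -> np.ndarray:
        """1-D array of levels inside the VOI."""
        return self.levels[self.mask]


def make_voi(template: LesionTemplate, image: SUVImage, mode: str = "ground_truth",
             threshold: float | None = None, occupancy_samples: int = 4) -> VOIMask:
    """Define the VOI on an image grid.

    ``ground_truth`` resamples the template support to the image grid with a
    >=50% occupancy rule: each image voxel is probed on an
    ``occupancy_samples``³ subgrid against the template support (each probe
    nearest-neighbour) and joins the VOI when at least half the probes land
    inside. ``threshold`` keeps image voxels >= the given SUV.
    """
    if mode == "threshold":
        if threshold is None:
            raise PreprocessingError("threshold mode requires a threshold")
        m = image.values >= threshold
        if not m.any():
            raise PreprocessingError(
                f"threshold {threshold} exceeds the image maximum "
                f"{image.values.max():.3g}: empty VOI"
            )
        return VOIMask(mask=m, voxel_volume_ml=image.voxel_volume_ml)
    if mode != "ground_truth":
        raise PreprocessingError(f"unknown VOI mode {mode!r}")

    support = template.support.astype(float)
    t_origin = -(np.array(support.shape) - 1) / 2.0 * template.grid_spacing
    k = max(1, int(occupancy_samples))
    # probe offsets at the centres of a k³ subdivision of each voxel
    sub = (np.arange(k) + 0.5) / k - 0.5
    occupancy = np.zeros(image.values.shape)
    for dz in sub:
        for dy in sub:
            for dx in sub:
                coords = np.meshgrid(
                    *[
                        (image.voxel_centers_axis(a) + d * image.spacing[a] - t_origin[a])
                        / template.grid_spacing
                        for a, d in zip(range(3), (dz, dy, dx))
                    ],
                    indexing="ij",
                )
                occupancy += ndimage.map_coordinates(
                    support, np.stack(coords), order=0, mode="constant")
    m = occupancy >= k**3 / 2.0
    if not m.any():
        raise PreprocessingError("template support does not intersect the image grid")
    return VOIMask(mask=m, voxel_volume_ml=image.voxel_volume_ml)


def resample_image(image: SUVImage, new_spacing: float | tuple[float, float, float],
                   mask: np.ndarray | None = None
                   ) -> SUVImage | tuple[SUVImage, np.ndarray]:
    """Resample intensities trilinearly onto an isotropic (or given) grid.

    The new grid spans the same physical extent, centred identically. A
    companion mask, if given, is resampled nearest-neighbour. Metadata
    (setting/lesion tags) is preserved.
    """
    if np.isscalar(new_spacing):
        new_spacing = (float(new_spacing),) * 3
    if any(s <= 0 for s in new_spacing):
        raise PreprocessingError("new spacing must be positive")
    old_shape = np.array(image.values.shape)
    extent = old_shape * np.array(image.spacing)
    new_shape = tuple(max(1, int(np.floor(extent[a] / new_spacing[a]))) for a in range(3))
    # keep the grid centre fixed
    old_center = np.array(image.origin) + (old_shape - 1) / 2.0 * np.array(image.spacing)
    new_origin = tuple(
        old_center[a] - (new_shape[a] - 1) / 2.0 * new_spacing[a] for a in range(3)
    )
    coords = np.meshgrid(
        *[
            (new_origin[a] + np.arange(new_shape[a]) * new_spacing[a] - image.origin[a])
            / image.spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    values = ndimage.map_coordinates(image.values, coords, order=1, mode="nearest")
    out = SUVImage(values=values, spacing=new_spacing, origin=new_origin,
                   setting_code=image.setting_code, lesion_name=image.lesion_name)
    if mask is None:
        return out
    new_mask = ndimage.map_coordinates(mask.astype(float), coords, order=0,
                                       mode="constant") > 0.5
    return out, new_mask


def discretize_fbs(image: SUVImage, voi: VOIMask | np.ndarray,
                   bin_width: float = DEFAULT_BIN_WIDTH_SUV) -> GreyLevelVolume:
    """Absolute (fixed-bin-size) discretization: level = floor(I/B) + 1."""
    if bin_width <= 0:
        raise PreprocessingError("bin width B must be positive")
    mask = voi.mask if isinstance(voi, VOIMask) else np.asarray(voi, dtype=bool)
    vals = image.values
    if np.any(vals[mask] < 0):
        warnings.warn("negative SUV values inside VOI clamped to 0 before binning",
                      stacklevel=2)
        vals = np.maximum(vals, 0.0)
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[mask] = np.floor(vals[mask] / bin_width).astype(np.int64) + 1
    return GreyLevelVolume(levels=levels, mask=mask, n_levels=int(levels.max()),
                           method="FBS", bin_width=bin_width)


def discretize_fbn(image: SUVImage, voi: VOIMask | np.ndarray,
                   bin_count: int = DEFAULT_BIN_COUNT) -> GreyLevelVolume:
    """Relative (fixed-bin-number) discretization into D bins over [I_min, I_max]."""
    if bin_count < 2:
        raise PreprocessingError("bin count D must be >= 2")
    mask = voi.mask if isinstance(voi, VOIMask) else np.asarray(voi, dtype=bool)
    inside = image.values[mask]
    i_min, i_max = float(inside.min()), float(inside.max())
    levels = np.zeros(image.values.shape, dtype=np.int64)
    if i_max == i_min:
        warnings.warn("constant VOI: degenerate single-level discretization",
                      stacklevel=2)
        levels[mask] = 1
        return GreyLevelVolume(levels=levels, mask=mask, n_levels=bin_count,
                               method="FBN", bin_count=bin_count, i_min=i_min, i_max=i_max)
    lev = np.floor(bin_count * (inside - i_min) / (i_max - i_min)).astype(np.int64) + 1
    lev = np.minimum(lev, bin_count)  # the I = I_max branch
    levels[mask] = lev
    return GreyLevelVolume(levels=levels, mask=mask, n_levels=bin_count,
                           method="FBN", bin_count=bin_count, i_min=i_min, i_max=i_max)
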