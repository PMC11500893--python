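"""SUV image container and grid geometry helpers.

Images use array axis order (z, y, x) with cube-centred physical coordinates:
voxel (i, j, k) sits at ``origin + (i, j, k) * spacing`` mm. NIfTI round-trip
is provided via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class SUVImage:
    """Reconstructed 3-D image in SUV units with spacing metadata."""

    values: np.ndarray  # 3-D float, SUV
    spacing: tuple[float, float, float]  # mm, (z, y, x)
    origin: tuple[float, float, float]  # mm, physical position of voxel (0,0,0)
    setting_code: str = ""
    lesion_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("SUVImage values must be 3-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("SUVImage values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one array axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def with_values(self, values: np.ndarray) -> "SUVImage":
        return replace(self, values=np.asarray(values, dtype=float))


def centered_grid(extent_mm: float, spacing: tuple[float, float, float]
                  ) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Shape and origin of a grid of given voxel size centred on the origin.

    The grid covers ``[-extent/2, extent/2]`` per axis with as many whole
    voxels as fit; voxel centres are symmetric about 0 (a voxel centre falls
    on 0 for odd counts, a voxel boundary for even counts).
    """
    shape = tuple(max(1, int(np.floor(extent_mm / s))) for s in spacing)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return shape, origin


def write_nifti(image: SUVImage, path: str | Path) -> None:
    """Write as NIfTI; array axes (z, y, x) map to NIfTI (x, y, z) by transpose."""
    data = np.asarray(image.values, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([image.spacing[2], image.spacing[1], image.spacing[0], 1.0])
    affine[:3, 3] = [image.origin[2], image.origin[1], image.origin[0]]
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path: str | Path, setting_code: str = "", lesion_name: str = "") -> SUVImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3-D NIfTI volume")
    affine = img.affine
    spacing_xyz = np.abs(np.diag(affine)[:3])
    origin_xyz = affine[:3, 3]
    return SUVImage(
        values=data.transpose(2, 1, 0),
        spacing=(float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0])),
        origin=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
        setting_code=setting_code,
        lesion_name=lesion_name,
    )
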