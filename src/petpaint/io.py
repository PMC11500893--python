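"""Disk formats: lesion templates as NIfTI, trajectory plans as CSV."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import LesionTemplate, TrajectoryPlan


def write_template(template: LesionTemplate, path: str | Path) -> None:
    data = np.asarray(template.values, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([template.grid_spacing] * 3 + [1.0])
    affine[:3, 3] = -(np.array(template.values.shape)[::-1] - 1) / 2.0 * template.grid_spacing
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_template(path: str | Path, name: str | None = None) -> LesionTemplate:
    img = nib.load(str(path))
    spacing = float(np.abs(img.affine[0, 0]))
    values = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    return LesionTemplate(name=name or Path(path).stem, grid_spacing=spacing,
                          values=np.maximum(values, 0.0))


def write_trajectory_csv(plan: TrajectoryPlan, path: str | Path) -> None:
    """Columns x_mm, y_mm, z_mm, dwell_s; waypoint order preserved."""
    df = pd.DataFrame({
        "x_mm": plan.waypoints[:, 2],
        "y_mm": plan.waypoints[:, 1],
        "z_mm": plan.waypoints[:, 0],
        "dwell_s": plan.dwell_times,
    })
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, travel_speed: float = 2.0) -> TrajectoryPlan:
    df = pd.read_csv(path)
    waypoints = np.stack([df["z_mm"], df["y_mm"], df["x_mm"]], axis=1)
    return TrajectoryPlan(waypoints=waypoints, dwell_times=df["dwell_s"].to_numpy(),
                          travel_speed=travel_speed)
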