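"""Multi-setting scanner surrogate: PSF blur, voxel sampling, noise, post-filter, SUV.

Each of the eight imaging settings (codes A–H) stands for one scanner +
reconstruction combination. True iterative reconstruction is not emulated;
a setting is characterised by its reconstructed-image properties — voxel
size, an effective point-spread FWHM, an optional Gaussian post-filter, and
a noise scale tied to exposure (background activity × acquisition time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import SUVImage, centered_grid
from .phantom import (
    LESION_ORDER,
    ActivityMap,
    LesionTemplate,
    PhantomSession,
    build_sessions,
    paint_ground_truth,
    plan_trajectory,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class AcquisitionError(ValueError):
    """Raised when a truth map and an imaging setting are incompatible."""


@dataclass(frozen=True)
class ImagingSetting:
    """One reconstruction surrogate (voxel grid + resolution + noise)."""

    code: str
    scanner_name: str
    voxel_size: tuple[float, float, float]  # mm, (z, y, x)
    psf_fwhm: float  # mm, effective system resolution (assumption, not measured)
    postfilter_fwhm: float  # mm, 0 for no post-filtering
    noise_scale: float  # SUV-relative noise amplitude at reference exposure

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.psf_fwhm < 0 or self.postfilter_fwhm < 0 or self.noise_scale < 0:
            raise ValueError("FWHM and noise scale must be non-negative")


#: The eight imaging settings. Voxel sizes and post-filters follow the
#: published reconstruction parameters of each scanner/protocol; the effective
#: PSF FWHMs are documented assumptions (4–7 mm band; the digital GE MI is the
#: sharpest) since reconstructed resolution is not a published quantity here.
DEFAULT_SETTINGS: dict[str, ImagingSetting] = {
    s.code: s
    for s in [
        ImagingSetting("A", "Siemens Biograph TruePoint 64", (2.67, 2.67, 2.67), 5.5, 5.0, 0.30),
        ImagingSetting("B", "Siemens Biograph TruePoint 64", (3.0, 4.0, 4.0), 6.0, 5.0, 0.30),
        ImagingSetting("C", "Mediso AnyScan PET/CT", (3.0, 3.0, 3.0), 6.0, 0.0, 0.28),
        ImagingSetting("D", "GE Discovery IQ", (2.73, 2.73, 2.73), 6.3, 6.4, 0.25),
        ImagingSetting("E", "GE Discovery IQ", (3.64, 3.64, 3.64), 6.5, 4.4, 0.27),
        ImagingSetting("F", "Philips Gemini TF 64", (4.0, 4.0, 4.0), 5.2, 0.0, 0.30),
        ImagingSetting("G", "GE Discovery MI", (2.73, 2.73, 2.73), 4.0, 0.0, 0.20),
        ImagingSetting("H", "GE Discovery MI", (2.73, 2.73, 2.73), 4.4, 3.2, 0.22),
    ]
}

#: Exposure (MBq·s) used to anchor noise_scale; first-session order of magnitude.
REFERENCE_EXPOSURE = 88.0 * 1730.0


def suv_normalization(session: PhantomSession) -> float:
    """kBq/mL per SUV unit: injected activity over phantom water mass (1 g/mL).

    With this normalisation a uniform tank at session start reads SUV 1.
    """
    mass_g = session.tank_volume_l * 1000.0
    return session.background_activity_mbq * 1000.0 / mass_g


def acquire(truth: ActivityMap, setting: ImagingSetting, *, seed: int = 0,
            extent_mm: float | None = None) -> SUVImage:
    """Render a ground-truth activity map through one imaging setting.

    Pipeline: 3-D Gaussian blur at ``psf_fwhm`` → sampling onto the setting's
    voxel grid → Gaussian noise with variance proportional to local intensity
    and inversely proportional to exposure → Gaussian post-filter → SUV
    conversion. Deterministic for a fixed seed.
    """
    if truth.spacing > min(setting.voxel_size):
        raise AcquisitionError(
            f"truth grid ({truth.spacing} mm) is coarser than setting "
            f"{setting.code} voxels {setting.voxel_size}"
        )
    session = truth.session
    sigma_fine = setting.psf_fwhm * FWHM_TO_SIGMA / truth.spacing
    blurred = ndimage.gaussian_filter(truth.values, sigma_fine, mode="nearest")

    if extent_mm is None:
        extent_mm = truth.values.shape[0] * truth.spacing
    shape, origin = centered_grid(extent_mm, setting.voxel_size)
    coords = np.meshgrid(
        *[
            (origin[a] + np.arange(shape[a]) * setting.voxel_size[a] - truth.origin[a])
            / truth.spacing
            for a in range(3)
        ],
        indexing="ij",
    )
    sampled = ndimage.map_coordinates(blurred, np.stack(coords), order=1, mode="nearest")

    norm = suv_normalization(session)  # kBq/mL per SUV
    if setting.noise_scale > 0:
        rng = np.random.default_rng(seed)
        exposure = session.background_activity_mbq * session.acquisition_time_s
        scale = setting.noise_scale * np.sqrt(REFERENCE_EXPOSURE / exposure)
        sigma = scale * np.sqrt(np.maximum(sampled, 0.0) * norm)
        sampled = sampled + sigma * rng.standard_normal(sampled.shape)

    if setting.postfilter_fwhm > 0:
        sigma_vox = [setting.postfilter_fwhm * FWHM_TO_SIGMA / s for s in setting.voxel_size]
        sampled = ndimage.gaussian_filter(sampled, sigma_vox, mode="nearest")

    return SUVImage(values=sampled / norm, spacing=setting.voxel_size, origin=origin,
                    setting_code=setting.code)


def acquire_all(
    lesions: dict[str, LesionTemplate],
    settings: dict[str, ImagingSetting] | None = None,
    *,
    base_dwell: float = 2.0,
    fine_spacing: float = 1.0,
    seed: int = 0,
    schedule: dict | None = None,
) -> dict[tuple[str, str], tuple[SUVImage, np.ndarray]]:
    """One (SUVImage, VOI mask) per lesion × setting.

    Ground truth is painted once per (lesion, scanner) pair — the session
    background differs between scanners per the measurement log — and rendered
    through every setting of that scanner. VOI masks are the template support
    resampled to each image grid. Keys are (lesion_name, setting_code).
    """
    from .preprocessing import make_voi  # local import: avoids a module cycle

    settings = settings or DEFAULT_SETTINGS
    plans = {name: plan_trajectory(t, base_dwell=base_dwell) for name, t in lesions.items()}
    # lesions are acquired in the canonical session order; extra names follow
    ordered = [n for n in LESION_ORDER if n in lesions]
    ordered += [n for n in lesions if n not in ordered]
    truths: dict[tuple[str, str], ActivityMap] = {}
    out: dict[tuple[str, str], tuple[SUVImage, np.ndarray]] = {}
    for code in sorted(settings):
        setting = settings[code]
        sessions = list(build_sessions(setting.scanner_name, schedule).values())
        for li, name in enumerate(ordered):
            key = (name, setting.scanner_name)
            if key not in truths:
                session = sessions[min(li, len(sessions) - 1)]
                truths[key] = paint_ground_truth(
                    lesions[name], plans[name], session, fine_spacing=fine_spacing
                )
            # one independent noise stream per (lesion, setting)
            sub_seed = (seed * 1009 + ord(code) * 131 + li) % (2**31)
            img = acquire(truths[key], setting, seed=sub_seed)
            img = SUVImage(values=img.values, spacing=img.spacing, origin=img.origin,
                           setting_code=code, lesion_name=name)
            voi = make_voi(lesions[name], img, mode="ground_truth")
            out[(name, code)] = (img, voi.mask)
    return out
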