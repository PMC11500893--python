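"""The 46 radiomic indices: conventional, shape, histogram, and texture families.

Formulas follow the conventions of 3-D PET radiomics software (LIFEx / IBSI
lineage): grey levels are 1-based bin indices, directional matrices merge the
13 unique 3-D directions, and degenerate constant-intensity volumes fall back
to fixed conventions (entropy 0, correlation 0 with a warning, and so on).
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure

from .image import SUVImage
from .preprocessing import (
    GreyLevelVolume,
    VOIMask,
    discretize_fbn,
    discretize_fbs,
)
from .registry import FEATURE_NAMES
from .texture import DIRECTIONS_13, glcm_matrix, glrlm_matrix, glzlm_matrix, ngldm_stats

PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # 1 mL sphere
_EPS = 1e-12


# --- conventional -------------------------------------------------------------

def suv_peak(image: SUVImage, mask: np.ndarray) -> float:
    """Mean SUV in a 1 mL sphere centred on the hottest VOI voxel.

    The sphere is realised on the voxel grid (voxels whose centres lie within
    the sphere radius); it is intersected with the VOI, so for very small
    lesions the peak is averaged over the voxels available (with a warning).
    """
    vals = np.where(mask, image.values, -np.inf)
    center = np.unravel_index(int(np.argmax(vals)), vals.shape)
    spacing = np.array(image.spacing)
    reach = np.ceil(PEAK_SPHERE_RADIUS_MM / spacing).astype(int)
    offs = np.meshgrid(*[np.arange(-r, r + 1) for r in reach], indexing="ij")
    offs = np.stack([o.ravel() for o in offs], axis=1)
    dist = np.linalg.norm(offs * spacing, axis=1)
    offs = offs[dist <= PEAK_SPHERE_RADIUS_MM]
    pos = offs + np.array(center)
    ok = np.all((pos >= 0) & (pos < np.array(vals.shape)), axis=1)
    pos = pos[ok]
    in_voi = mask[pos[:, 0], pos[:, 1], pos[:, 2]]
    if not in_voi.all():
        warnings.warn("1 mL peak sphere extends beyond the VOI; averaging over "
                      "the available VOI voxels", stacklevel=2)
    pos = pos[in_voi]
    return float(image.values[pos[:, 0], pos[:, 1], pos[:, 2]].mean())


def conventional_features(image: SUVImage, voi: VOIMask) -> dict[str, float]:
    """SUVmin/mean/std/max/peak, TLG and MATV over the VOI.

    SUVstd is the population standard deviation; TLG = SUVmean × volume (mL);
    MATV is the segmented volume itself.
    """
    vals = image.values[voi.mask]
    mean = float(vals.mean())
    vol = voi.volume_ml
    return {
        "SUVmin": float(vals.min()),
        "SUVmean": mean,
        "SUVstd": float(vals.std()),
        "SUVmax": float(vals.max()),
        "SUVpeak": suv_peak(image, voi.mask),
        "TLG": mean * vol,
        "MATV": vol,
    }


# --- shape --------------------------------------------------------------------

def mesh_surface_area_mm2(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Surface of the mask boundary from a marching-cubes mesh (mm²)."""
    padded = np.pad(mask.astype(float), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        return float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        # degenerate mask (e.g. a single voxel slab): fall back to exposed faces
        area = 0.0
        for ax in range(3):
            face = np.prod([s for i, s in enumerate(spacing) if i != ax])
            diff = np.diff(np.pad(mask, 1).astype(int), axis=ax)
            area += float(np.abs(diff).sum()) * face
        return area


def shape_features(voi: VOIMask, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Volume (mL), Sphericity and Compacity of the segmented VOI.

    Sphericity = π^(1/3) (6V)^(2/3) / A (1 for a perfect ball);
    Compacity = V / (√π A^(3/2)), both with V in mm³ and A in mm².
    """
    v_mm3 = voi.voxel_count * float(np.prod(spacing))
    area = mesh_surface_area_mm2(voi.mask, spacing)
    sphericity = np.pi ** (1 / 3) * (6.0 * v_mm3) ** (2 / 3) / area
    compacity = v_mm3 / (np.sqrt(np.pi) * area**1.5)
    return {
        "Volume_mL": v_mm3 / 1000.0,
        "Sphericity": float(sphericity),
        "Compacity": float(compacity),
    }


# --- histogram ----------------------------------------------------------------

def histogram_features(glv: GreyLevelVolume) -> dict[str, float]:
    """Skewness, kurtosis, entropy (both log bases) and energy of the level histogram.

    Moments are population moments of the discretized levels; kurtosis is the
    plain (non-excess) standardized fourth moment. A zero-variance VOI yields
    skewness/kurtosis 0 with a warning.
    """
    lev = glv.voi_levels().astype(float)
    mu = lev.mean()
    sd = lev.std()
    if sd < _EPS:
        warnings.warn("zero-variance grey-level volume: skewness/kurtosis undefined, "
                      "reported as 0", stacklevel=2)
        skew = kurt = 0.0
    else:
        skew = float(((lev - mu) ** 3).mean() / sd**3)
        kurt = float(((lev - mu) ** 4).mean() / sd**4)
    counts = np.bincount(lev.astype(int))[1:]
    p = counts[counts > 0] / lev.size
    ent2 = float(-(p * np.log2(p)).sum())
    return {
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy_log10": ent2 * np.log10(2.0),
        "Entropy_log2": ent2,
        "Energy": float((p**2).sum()),
    }


# --- GLCM ---------------------------------------------------------------------

def glcm_features(glv: GreyLevelVolume, directions=DIRECTIONS_13) -> dict[str, float]:
    p = glcm_matrix(glv.levels, glv.mask, glv.n_levels, directions)
    i = np.arange(1, p.shape[0] + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pos = p > 0
    ent2 = float(-(p[pos] * np.log2(p[pos])).sum()) if pos.any() else 0.0
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    var_i = float(((ii - mu_i) ** 2 * p).sum())
    var_j = float(((jj - mu_j) ** 2 * p).sum())
    if var_i < _EPS or var_j < _EPS:
        warnings.warn("degenerate co-occurrence matrix: correlation undefined, "
                      "reported as 0", stacklevel=2)
        corr = 0.0
    else:
        corr = float((((ii - mu_i) * (jj - mu_j) * p).sum())
                     / np.sqrt(var_i * var_j))
    return {
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Energy": float((p**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "Entropy_log10": ent2 * np.log10(2.0),
        "Entropy_log2": ent2,
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
    }


# --- GLRLM / GLZLM (shared index algebra) --------------------------------------

def _length_indices(m: np.ndarray, percentage_denominator: float) -> list[float]:
    """The 11 standard indices of a level × length count matrix.

    Order: short emphasis, long emphasis, low/high grey-level emphasis, the
    four joint emphases, grey-level non-uniformity, length non-uniformity,
    and the run/zone percentage (total count over ``percentage_denominator``).
    """
    n_total = m.sum()
    i = np.arange(1, m.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, m.shape[1] + 1, dtype=float)[None, :]
    return [
        float((m / l**2).sum() / n_total),
        float((m * l**2).sum() / n_total),
        float((m / i**2).sum() / n_total),
        float((m * i**2).sum() / n_total),
        float((m / (i**2 * l**2)).sum() / n_total),
        float((m * i**2 / l**2).sum() / n_total),
        float((m * l**2 / i**2).sum() / n_total),
        float((m * i**2 * l**2).sum() / n_total),
        float((m.sum(axis=1) ** 2).sum() / n_total),
        float((m.sum(axis=0) ** 2).sum() / n_total),
        float(n_total / percentage_denominator),
    ]


def glrlm_features(glv: GreyLevelVolume, directions=DIRECTIONS_13) -> dict[str, float]:
    """Run-length indices; run percentage normalises by voxels × directions."""
    m = glrlm_matrix(glv.levels, glv.mask, glv.n_levels, directions)
    n_vox = int(glv.mask.sum())
    vals = _length_indices(m, float(n_vox * len(directions)))
    names = ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
             "GLNU", "RLNU", "RP")
    return dict(zip(names, vals))


def glzlm_features(glv: GreyLevelVolume) -> dict[str, float]:
    """Zone-length (size-zone) indices; zone percentage = zones / voxels."""
    m = glzlm_matrix(glv.levels, glv.mask, glv.n_levels)
    n_vox = int(glv.mask.sum())
    vals = _length_indices(m, float(n_vox))
    names = ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
             "GLNU", "ZLNU", "ZP")
    return dict(zip(names, vals))


# --- NGLDM ---------------------------------------------------------------------

def ngldm_features(glv: GreyLevelVolume, coarseness_cap: float = 1e6) -> dict[str, float]:
    """Coarseness, Contrast and Busyness from 26-neighbourhood differences.

    A perfectly uniform volume has zero summed difference; its coarseness is
    capped at ``coarseness_cap`` instead of dividing by zero.
    """
    p, s, n_vox = ngldm_stats(glv.levels, glv.mask, glv.n_levels)
    i = np.arange(1, len(p) + 1, dtype=float)
    occupied = p > 0
    ng = int(occupied.sum())
    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 1.0 / coarseness_cap else coarseness_cap
    if ng < 2:
        contrast = 0.0
        busyness = 0.0
    else:
        pi, pj = np.meshgrid(p[occupied], p[occupied], indexing="ij")
        iv = i[occupied]
        di = iv[:, None] - iv[None, :]
        contrast = float((pi * pj * di**2).sum() / (ng * (ng - 1)) * s.sum() / n_vox)
        denom = float(np.abs(iv[:, None] * pi - iv[None, :] * pj).sum())
        busyness = ps / denom if denom > _EPS else 0.0
    return {"Coarseness": float(coarseness), "Contrast": contrast,
            "Busyness": float(busyness)}


# --- full vector ---------------------------------------------------------------

def extract_features(image: SUVImage, voi: VOIMask | np.ndarray, method: str = "FBS",
                     bin_width: float = 0.3125, bin_count: int = 64) -> dict[str, float]:
    """Compute the full 46-index vector for one image/VOI/discretization cell.

    Conventional and shape indices are computed on the continuous SUV values
    and are therefore identical between FBS and FBN; the histogram and texture
    families are computed on the discretized grey-level volume.
    """
    if not isinstance(voi, VOIMask):
        voi = VOIMask(mask=voi, voxel_volume_ml=image.voxel_volume_ml)
    if method == "FBS":
        glv = discretize_fbs(image, voi, bin_width)
    elif method == "FBN":
        glv = discretize_fbn(image, voi, bin_count)
    else:
        raise ValueError(f"unknown discretization method {method!r}")

    values: dict[str, float] = {}
    conv = conventional_features(image, voi)
    for k in ("SUVmin", "SUVmean", "SUVstd", "SUVmax", "SUVpeak", "TLG"):
        values[f"CONV_{k}"] = conv[k]
    shp = shape_features(voi, image.spacing)
    values["SHAPE_Volume_mL"] = shp["Volume_mL"]  # == conv["MATV"]
    values["SHAPE_Sphericity"] = shp["Sphericity"]
    values["SHAPE_Compacity"] = shp["Compacity"]
    for k, v in histogram_features(glv).items():
        values[f"HISTO_{k}"] = v
    for k, v in glcm_features(glv).items():
        values[f"GLCM_{k}"] = v
    for k, v in glrlm_features(glv).items():
        values[f"GLRLM_{k}"] = v
    for k, v in ngldm_features(glv).items():
        values[f"NGLDM_{k}"] = v
    for k, v in glzlm_features(glv).items():
        values[f"GLZLM_{k}"] = v

    assert tuple(values) == FEATURE_NAMES
    return values
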