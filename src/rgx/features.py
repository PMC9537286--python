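"""Radiomics feature extraction from a pre-processed volume/mask pair.

Five feature families are computed: statistical, local intensity,
morphological, intensity histogram and texture (GLSZM/GLCM/GLRLM).  Base
images receive every family; the LoG response map only the statistical and
intensity-histogram families (morphology is image-independent and LoG
texture is structurally unstable, so neither is ever emitted for it).
Feature names follow the compact IBSI-style scheme used in the radiomics
literature: ``stat_p90``, ``morph_vol_dens_aabb``, ``szm_glnu``, with a
``log_`` prefix for features of the LoG response map (``log_stat_p90``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats, signal
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from . import texture
from .errors import DegenerateRoiError
from .images import ImageVolume, PreprocessConfig, RoiMask, discretise

#: Families that are computed on the LoG response map.
LOG_FAMILIES = ("statistical", "intensity_histogram")
#: Radius of the 1 cm^3 sphere used for local intensity peaks.
PEAK_RADIUS_MM = 6.204


@dataclass
class FeatureVector:
    """Named feature values with per-feature family/image provenance."""

    values: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, name: str, value: float, family: str, image: str) -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        self.values[name] = float(value)
        self.metadata[name] = {"family": family, "image": image}

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values)


def statistical_features(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of in-mask intensities."""
    v = np.asarray(values, dtype=float)
    p10, p90 = np.percentile(v, [10, 90])
    q1, q3 = np.percentile(v, [25, 75])
    return {
        "stat_mean": float(v.mean()),
        "stat_var": float(v.var()),
        "stat_skew": float(stats.skew(v)) if v.std() > 0 else 0.0,
        "stat_kurt": float(stats.kurtosis(v)) if v.std() > 0 else 0.0,
        "stat_median": float(np.median(v)),
        "stat_min": float(v.min()),
        "stat_max": float(v.max()),
        "stat_p10": float(p10),
        "stat_p90": float(p90),
        "stat_iqr": float(q3 - q1),
        "stat_range": float(v.max() - v.min()),
        "stat_energy": float((v**2).sum()),
        "stat_rms": float(np.sqrt((v**2).mean())),
    }


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [int(np.ceil(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return (dist2 <= radius_mm**2).astype(float)


def local_intensity_features(
    vol: ImageVolume, mask_int: np.ndarray
) -> dict[str, float]:
    """Local and global intensity peaks (mean in a 1 cm^3 sphere)."""
    kernel = _sphere_kernel(vol.spacing, PEAK_RADIUS_MM)
    kernel /= kernel.sum()
    sphere_mean = signal.fftconvolve(vol.intensities, kernel, mode="same")
    in_mask = mask_int
    vals = vol.intensities[in_mask]
    vmax = vals.max()
    at_max = in_mask & (vol.intensities == vmax)
    return {
        "loc_peak_local": float(sphere_mean[at_max].max()),
        "loc_peak_global": float(sphere_mean[in_mask].max()),
    }


def morphological_features(mask: RoiMask, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Geometry of the morphological mask.

    Volume is voxel-counted and exported in cm^3 (the GTV feature); surface
    area comes from a marching-cubes mesh; ``morph_vol_dens_aabb`` is the
    voxel-counted fraction of the axis-aligned bounding box occupied.
    """
    morph = mask.morphological
    n_vox = int(morph.sum())
    voxel_vol = float(np.prod(spacing))
    volume_mm3 = n_vox * voxel_vol
    coords = np.argwhere(morph)
    bbox_extent = coords.max(axis=0) - coords.min(axis=0) + 1
    vol_dens_aabb = n_vox / float(np.prod(bbox_extent))
    padded = np.pad(morph.astype(float), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):  # ROI thinner than one voxel along an axis
        area = float(2 * (n_vox * voxel_vol) ** (2 / 3))
    # max 3D diameter from the convex hull of surface voxel centres
    pts = coords * np.array(spacing)
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass
    diam = float(pdist(pts).max()) if len(pts) > 1 else float(max(spacing))
    sphericity = float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area)
    return {
        "morph_volume": volume_mm3 / 1000.0,  # cm^3
        "morph_area": area,
        "morph_comp_2": float(36 * np.pi * volume_mm3**2 / area**3),
        "morph_sphericity": sphericity,
        "morph_diam": diam,
        "morph_vol_dens_aabb": float(vol_dens_aabb),
    }


def intensity_histogram_features(labels_in_mask: np.ndarray, n_bins: int) -> dict[str, float]:
    """Histogram features on the discretised grey levels (bins 1..n_bins)."""
    counts = np.bincount(labels_in_mask, minlength=n_bins + 1)[1:].astype(float)
    n = counts.sum()
    p = counts / n
    nz = p > 0
    entropy = -float((p[nz] * np.log2(p[nz])).sum())
    uniformity = float((p**2).sum())
    mode = int(np.argmax(counts)) + 1  # lowest level on ties
    grad = np.gradient(counts)
    return {
        "ih_entropy": entropy,
        "ih_uniformity": uniformity,
        "ih_mode": float(mode),
        "ih_max_grad": float(grad.max()),
        "ih_max_grad_g": float(np.argmax(grad) + 1),
        "ih_min_grad": float(grad.min()),
        "ih_min_grad_g": float(np.argmin(grad) + 1),
    }


def texture_features(labels: np.ndarray, mask_int: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    if int(mask_int.sum()) < 2:
        # single-voxel ROI: texture undefined
        return {name: float("nan") for name in texture_feature_names()}
    out.update(texture.glszm_features(texture.grey_level_size_zone_matrix(labels, mask_int)))
    out.update(texture.glcm_features(texture.grey_level_cooccurrence_matrix(labels, mask_int)))
    out.update(texture.glrlm_features(texture.grey_level_run_length_matrix(labels, mask_int)))
    return out


def texture_feature_names() -> tuple[str, ...]:
    return (
        "szm_sze", "szm_lze", "szm_glnu", "szm_glnu_norm", "szm_zsnu",
        "szm_zsnu_norm", "szm_z_perc", "szm_gl_var", "szm_zs_var", "szm_zs_entr",
        "cm_joint_max", "cm_joint_entr", "cm_energy", "cm_contrast",
        "cm_dissimilarity", "cm_inv_diff", "cm_inv_diff_mom", "cm_corr",
        "rlm_sre", "rlm_lre", "rlm_glnu", "rlm_rlnu", "rlm_r_perc", "rlm_gl_var",
    )


def extract_features(
    base: ImageVolume,
    log: ImageVolume | None,
    mask: RoiMask,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> FeatureVector:
    """Compute the implemented feature subset for base (all families) and LoG
    (statistical + intensity histogram) images."""
    mask_int = mask.intensity_or_morph()
    if not mask_int.any():
        raise DegenerateRoiError("intensity mask is empty")
    fv = FeatureVector()

    base_vals = base.intensities[mask_int]
    for name, value in statistical_features(base_vals).items():
        fv.add(name, value, "statistical", "base")
    for name, value in local_intensity_features(base, mask_int).items():
        fv.add(name, value, "local_intensity", "base")
    for name, value in morphological_features(mask, base.spacing).items():
        fv.add(name, value, "morphological", "base")
    labels = discretise(base, mask_int, cfg.n_bins)
    for name, value in intensity_histogram_features(labels[mask_int], cfg.n_bins).items():
        fv.add(name, value, "intensity_histogram", "base")
    for name, value in texture_features(labels, mask_int).items():
        fv.add(name, value, "texture", "base")

    if log is not None:
        log_vals = log.intensities[mask_int]
        for name, value in statistical_features(log_vals).items():
            fv.add(f"log_{name}", value, "statistical", "log")
        log_labels = discretise(log, mask_int, cfg.n_bins)
        for name, value in intensity_histogram_features(
            log_labels[mask_int], cfg.n_bins
        ).items():
            fv.add(f"log_{name}", value, "intensity_histogram", "log")
    return fv
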