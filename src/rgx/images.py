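"""Image containers and IBSI-style pre-processing for CT radiomics.

The processing chain mirrors standard planning-CT radiomics practice:
resample the volume and the gross-tumour-volume (GTV) segmentation to an
isotropic 1 mm grid, re-segment the region of interest to soft-tissue
Hounsfield units (air cavities and bone are excluded, not clamped), build a
response map from a bank of Laplacian-of-Gaussian filters, and discretise
in-mask intensities to a fixed number of grey levels for texture features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateRoiError, SizingError

#: HU window used for intensity re-segmentation (closed interval).
DEFAULT_HU_WINDOW = (-150.0, 180.0)
#: LoG kernel widths in mm, averaged into a single response map.
DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_TARGET_SPACING = 1.0
DEFAULT_N_BINS = 32


@dataclass(frozen=True)
class ImageVolume:
    """3D intensity grid (HU) with physical voxel spacing in mm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise SizingError("image volume must be 3D")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise SizingError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(arr)):
            raise SizingError("image intensities must be finite")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class RoiMask:
    """Binary tumour segmentation congruent with an :class:`ImageVolume`.

    ``morphological`` is the delineated geometry; ``intensity`` is the subset
    surviving HU re-segmentation (``None`` until :func:`resegment_intensity`
    runs).  Morphology features use the former, intensity/histogram/texture
    features the latter.
    """

    morphological: np.ndarray
    intensity: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        morph = np.asarray(self.morphological).astype(bool)
        if morph.ndim != 3:
            raise SizingError("mask must be 3D")
        if not morph.any():
            raise DegenerateRoiError("morphological mask is empty")
        object.__setattr__(self, "morphological", morph)
        if self.intensity is not None:
            inten = np.asarray(self.intensity).astype(bool)
            if inten.shape != morph.shape:
                raise SizingError("intensity mask shape differs from morphological mask")
            object.__setattr__(self, "intensity", inten)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.morphological.shape

    def intensity_or_morph(self) -> np.ndarray:
        return self.intensity if self.intensity is not None else self.morphological


@dataclass(frozen=True)
class PreprocessConfig:
    """Pre-processing parameters (isotropic grid, HU window, LoG bank, bins)."""

    target_spacing: float = DEFAULT_TARGET_SPACING
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.hu_window[0] >= self.hu_window[1]:
            raise SizingError("HU window low must be below high")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise SizingError("LoG sigmas must be positive")
        if self.n_bins < 2:
            raise SizingError("need at least 2 grey-level bins")


def _check_pair(vol: ImageVolume, mask: RoiMask) -> None:
    if vol.shape != mask.shape:
        raise SizingError(
            f"volume grid {vol.shape} does not match mask grid {mask.shape}"
        )


def resample_isotropic(
    vol: ImageVolume,
    mask: RoiMask,
    target: float = DEFAULT_TARGET_SPACING,
) -> tuple[ImageVolume, RoiMask]:
    """Resample volume (tricubic spline) and mask (trilinear, 0.5 threshold).

    The output grid shares the input volume's physical frame; spacing becomes
    isotropic ``target`` mm along every axis.
    """
    _check_pair(vol, mask)
    if target <= 0:
        raise SizingError("target spacing must be positive")
    factors = np.array(vol.spacing, dtype=float) / float(target)
    if np.allclose(factors, 1.0):
        out_mask = RoiMask(mask.morphological.copy())
        return ImageVolume(vol.intensities.copy(), (target,) * 3, vol.origin), out_mask
    new_shape = np.maximum(np.round(np.array(vol.shape) * factors), 1).astype(int)
    # map_coordinates on the output lattice keeps world coordinates aligned
    # with the input frame (voxel-centre convention).
    scale = (np.array(vol.shape) - 1) / np.maximum(new_shape - 1, 1)
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(new_shape, scale)], indexing="ij"
    )
    coords = np.stack([c.ravel() for c in coords])
    intensities = ndimage.map_coordinates(
        vol.intensities, coords, order=3, mode="nearest"
    ).reshape(tuple(new_shape))
    mask_float = ndimage.map_coordinates(
        mask.morphological.astype(float), coords, order=1, mode="constant", cval=0.0
    ).reshape(tuple(new_shape))
    morph = mask_float >= 0.5
    if not morph.any():
        raise DegenerateRoiError("mask vanished during resampling")
    return (
        ImageVolume(intensities, (target,) * 3, vol.origin),
        RoiMask(morph),
    )


def resegment_intensity(
    vol: ImageVolume,
    mask: RoiMask,
    window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> RoiMask:
    """Exclude in-mask voxels with HU outside the closed ``window``.

    Returns a mask whose ``intensity`` component is the surviving voxel set;
    the morphological component is untouched.
    """
    _check_pair(vol, mask)
    lo, hi = window
    keep = mask.morphological & (vol.intensities >= lo) & (vol.intensities <= hi)
    if not keep.any():
        raise DegenerateRoiError(
            f"no in-mask voxel inside the HU window [{lo}, {hi}]"
        )
    return RoiMask(mask.morphological, keep)


def log_filter_bank(
    vol: ImageVolume,
    sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM,
) -> ImageVolume:
    """Voxelwise mean of Laplacian-of-Gaussian responses at several widths.

    Sigma is given in mm and converted to voxels through the spacing; mirror
    boundary handling.  Averaging several kernel widths yields one response
    map sensitive to both edges (small sigma) and blobs (large sigma).
    """
    spacing = np.array(vol.spacing, dtype=float)
    responses = np.zeros_like(vol.intensities)
    for sigma in sigmas_mm:
        sigma_vox = sigma / spacing
        if np.any(sigma_vox < 0.5):
            raise SizingError(
                f"LoG sigma {sigma} mm below half a voxel for spacing {vol.spacing}"
            )
        responses += _log_response(vol.intensities, sigma_vox, spacing)
    responses /= len(sigmas_mm)
    return ImageVolume(responses, vol.spacing, vol.origin)


def _gauss_kernels(sigma: float, truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian and its second derivative, moment-corrected so a
    constant image yields an exactly zero Laplacian response."""
    half = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    g2 = (x**2 / sigma**4 - 1.0 / sigma**2) * g
    g2 -= g2.sum() / g2.size  # enforce zero DC response despite truncation
    return g, g2


def _log_response(
    arr: np.ndarray, sigma_vox: np.ndarray, spacing_mm: np.ndarray
) -> np.ndarray:
    """Separable Laplacian-of-Gaussian: sum over axes of G'' along that axis
    and G along the others; mirror boundaries; second derivatives in mm^-2
    so the response is independent of the sampling grid."""
    kernels = [_gauss_kernels(float(s)) for s in sigma_vox]
    out = np.zeros_like(arr, dtype=float)
    for axis in range(3):
        part = arr.astype(float)
        for ax2 in range(3):
            k = kernels[ax2][1] if ax2 == axis else kernels[ax2][0]
            part = ndimage.convolve1d(part, k, axis=ax2, mode="mirror")
        out += part / spacing_mm[axis] ** 2
    return out


def discretise(
    vol: ImageVolume,
    mask_int: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Fixed-bin-number discretisation over the in-mask min-max range.

    Returns an integer volume with in-mask labels in ``1..n_bins`` (0 outside
    the mask).  A constant region maps to a single grey level (bin 1).
    """
    mask_int = np.asarray(mask_int).astype(bool)
    if not mask_int.any():
        raise DegenerateRoiError("intensity mask is empty")
    if n_bins < 2:
        raise SizingError("need at least 2 bins")
    values = vol.intensities[mask_int]
    lo, hi = float(values.min()), float(values.max())
    labels = np.zeros(vol.shape, dtype=np.int32)
    if hi <= lo:
        labels[mask_int] = 1
        return labels
    binned = np.floor((vol.intensities - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    np.clip(binned, 1, n_bins, out=binned)
    labels[mask_int] = binned[mask_int]
    return labels


def preprocess(
    vol: ImageVolume,
    mask: RoiMask,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> tuple[ImageVolume, ImageVolume, RoiMask]:
    """Full chain: resample -> re-segment -> LoG bank.

    Returns ``(base, log_response, mask)`` ready for feature extraction.
    """
    vol_r, mask_r = resample_isotropic(vol, mask, cfg.target_spacing)
    mask_seg = resegment_intensity(vol_r, mask_r, cfg.hu_window)
    log_vol = log_filter_bank(vol_r, cfg.log_sigmas_mm)
    return vol_r, log_vol, mask_seg
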