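"""Feature robustness under image augmentation.

Radiomics features are recomputed on perturbed copies of each image
(small in-plane rotations crossed with contour volume changes) and features
whose intraclass correlation across the perturbations is poor are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DegenerateRoiError
from .images import ImageVolume, RoiMask

logger = logging.getLogger(__name__)

DEFAULT_ROTATIONS_DEG = (-4.0, -2.0, 0.0, 2.0, 4.0)
DEFAULT_VOLUME_CHANGES = (-0.20, -0.10, 0.10, 0.20)
ICC_THRESHOLD = 0.75


@dataclass(frozen=True)
class AugmentationScheme:
    """Rotation (cranio-caudal axis) x contour volume-change grid."""

    rotations_deg: tuple[float, ...] = DEFAULT_ROTATIONS_DEG
    volume_changes: tuple[float, ...] = DEFAULT_VOLUME_CHANGES
    volume_tolerance: float = 0.01

    @property
    def n_variants(self) -> int:
        return len(self.rotations_deg) * len(self.volume_changes)


@dataclass
class StabilityReport:
    """Per-feature ICC estimate, 95% CI and retention decision."""

    table: pd.DataFrame  # columns: icc, ci_low, ci_high, retained
    threshold: float = ICC_THRESHOLD

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def _rotate(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    if angle_deg == 0.0:
        return arr.copy()
    return ndimage.rotate(
        arr, angle_deg, axes=(0, 1), reshape=False, order=order, mode="nearest"
    )


def alter_volume(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    change: float,
    tolerance: float = 0.01,
) -> np.ndarray:
    """Grow/shrink a mask by ``change`` (fraction) via its signed distance field.

    The signed Euclidean distance transform (positive inside) is thresholded
    at an offset found by bisection until the achieved voxel count is within
    ``tolerance`` of the target.  Shape is preserved to first order.
    """
    mask = mask.astype(bool)
    n0 = int(mask.sum())
    target = n0 * (1.0 + change)
    n_target = int(round(target))
    if change == 0.0:
        return mask.copy()
    if n_target < 1 or (change < 0 and n_target >= n0):
        raise DegenerateRoiError(
            f"volume change {change:+.0%} unreachable (mask of {n0} voxels)"
        )
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    signed = inside - outside  # > 0 strictly inside, < 0 outside
    lo, hi = float(signed.min()), float(signed.max())
    thr = lo
    for _ in range(60):
        thr = 0.5 * (lo + hi)
        n = int((signed > thr).sum())
        if n > n_target:
            lo = thr
        elif n < n_target:
            hi = thr
        else:
            break
    core = signed > thr
    n_core = int(core.sum())
    if n_core < n_target:
        # boundary shell of equidistant voxels: take the deterministic prefix
        shell = np.flatnonzero(~core.ravel() & (signed.ravel() >= lo))
        shell = shell[np.argsort(-signed.ravel()[shell], kind="stable")]
        out = core.ravel().copy()
        out[shell[: n_target - n_core]] = True
        core = out.reshape(mask.shape)
    achieved = int(core.sum())
    if achieved == 0 or abs(achieved - target) / target > tolerance:
        raise DegenerateRoiError(
            f"volume change {change:+.0%} unreachable within {tolerance:.0%} "
            f"(mask of {n0} voxels, achieved {achieved})"
        )
    return core


def augment(
    vol: ImageVolume,
    mask: RoiMask,
    scheme: AugmentationScheme = AugmentationScheme(),
) -> list[tuple[ImageVolume, RoiMask]]:
    """One perturbed (volume, mask) pair per (rotation, volume change).

    Rotation resamples the image with cubic splines and the mask with linear
    interpolation thresholded at 0.5; the volume change only perturbs the
    mask.  Unreachable volume targets drop the variant with a warning.
    """
    variants: list[tuple[ImageVolume, RoiMask]] = []
    for angle in scheme.rotations_deg:
        rot_img = _rotate(vol.intensities, angle, order=3)
        rot_mask = _rotate(mask.morphological.astype(float), angle, order=1) >= 0.5
        for change in scheme.volume_changes:
            try:
                new_mask = alter_volume(
                    rot_mask, vol.spacing, change, scheme.volume_tolerance
                )
            except DegenerateRoiError as exc:
                warnings.warn(f"augmentation variant dropped: {exc}")
                continue
            variants.append(
                (
                    ImageVolume(rot_img, vol.spacing, vol.origin),
                    RoiMask(new_mask),
                )
            )
    return variants


def icc(values: np.ndarray) -> tuple[float, float, float]:
    """One-way random-effects ICC(1,1) with a 95% F-distribution CI.

    ``values`` is subjects x conditions.  The augmentation variants act as
    exchangeable raters, so the one-way form applies.  Estimates are clipped
    to [-1, 1]; a table with zero total variance is perfectly repeatable by
    convention (ICC 1, CI [1, 1]).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(x).any():
        raise ValueError("missing cells not allowed")
    n, k = x.shape
    grand = x.mean()
    subject_means = x.mean(axis=1)
    ssb = k * ((subject_means - grand) ** 2).sum()
    ssw = ((x - subject_means[:, None]) ** 2).sum()
    df_b, df_w = n - 1, n * (k - 1)
    msb, msw = ssb / df_b, ssw / df_w
    if msb == 0 and msw == 0:
        return 1.0, 1.0, 1.0
    if msw == 0:
        return 1.0, 1.0, 1.0
    est = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    f_low = f_obs / stats.f.ppf(0.975, df_b, df_w)
    f_high = f_obs * stats.f.ppf(0.975, df_w, df_b)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    clip = lambda v: float(np.clip(v, -1.0, 1.0))
    return clip(est), clip(ci_low), clip(ci_high)


def stability_filter(
    feature_table: pd.DataFrame,
    threshold: float = ICC_THRESHOLD,
) -> StabilityReport:
    """Retain features whose ICC 95% CI lower bound is at least ``threshold``.

    ``feature_table`` has a (patient, variant) MultiIndex and one column per
    feature.  Patients missing variants are excluded with a warning.
    """
    if not isinstance(feature_table.index, pd.MultiIndex):
        raise ValueError("feature table needs a (patient, variant) MultiIndex")
    patients = feature_table.index.get_level_values(0).unique()
    if len(patients) < 10:
        warnings.warn(
            f"stability analysis on only {len(patients)} patients; "
            "ICC confidence intervals will be wide"
        )
    n_variants = feature_table.groupby(level=0).size()
    full = n_variants.max()
    complete = n_variants.index[n_variants == full]
    dropped = set(patients) - set(complete)
    if dropped:
        warnings.warn(f"patients excluded from ICC (missing variants): {sorted(dropped)}")
    sub = feature_table.loc[list(complete)]
    rows = {}
    for feature in feature_table.columns:
        mat = sub[feature].unstack(level=1).to_numpy()
        if np.isnan(mat).any():
            warnings.warn(f"feature {feature!r} has undefined values; dropped")
            rows[feature] = (np.nan, np.nan, np.nan, False)
            continue
        est, lo, hi = icc(mat)
        rows[feature] = (est, lo, hi, lo >= threshold)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["icc", "ci_low", "ci_high", "retained"]
    )
    table["retained"] = table["retained"].astype(bool)
    return StabilityReport(table, threshold)
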