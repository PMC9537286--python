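"""Yeo-Johnson power transform + z-standardisation with leak-free transfer.

Parameters (lambda, z-shift, z-scale) are estimated on the discovery cohort
only and stored, so validation data are transformed with frozen parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ModelError


def yeo_johnson(x: np.ndarray, lam: float) -> np.ndarray:
    """Yeo-Johnson transform, defined for all reals.

    x >= 0: ((x+1)^lam - 1)/lam, or ln(x+1) at lam = 0;
    x <  0: -(((-x+1)^(2-lam) - 1)/(2-lam)), or -ln(-x+1) at lam = 2.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    # expm1/log1p forms are exact at lam = 0 (resp. 2) and stable nearby
    if abs(lam) > 1e-10:
        out[pos] = np.expm1(lam * np.log1p(x[pos])) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if abs(2.0 - lam) > 1e-10:
        out[~pos] = -np.expm1((2.0 - lam) * np.log1p(-x[~pos])) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def yeo_johnson_inverse(y: np.ndarray, lam: float) -> np.ndarray:
    """Inverse of :func:`yeo_johnson` (used to map z-space values back to raw)."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lam) > 1e-10:
        out[pos] = np.expm1(np.log1p(y[pos] * lam) / lam)
    else:
        out[pos] = np.expm1(y[pos])
    if abs(2.0 - lam) > 1e-10:
        out[~pos] = -np.expm1(np.log1p(-(2.0 - lam) * y[~pos]) / (2.0 - lam))
    else:
        out[~pos] = -np.expm1(-y[~pos])
    return out


def fit_lambda(x: np.ndarray, bounds: tuple[float, float] = (-3.0, 3.0)) -> float:
    """Maximum-likelihood lambda over a bounded interval."""
    x = np.asarray(x, dtype=float)
    res = optimize.minimize_scalar(
        lambda lam: -stats.yeojohnson_llf(lam, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


@dataclass
class TransformParams:
    """Per-feature (lambda, z-shift, z-scale); z-scale strictly positive."""

    table: pd.DataFrame  # index: feature; columns: lam, shift, scale

    def features(self) -> list[str]:
        return list(self.table.index)

    def subset(self, features) -> "TransformParams":
        missing = [f for f in features if f not in self.table.index]
        if missing:
            raise ModelError(f"no transform parameters for: {missing}")
        return TransformParams(self.table.loc[list(features)].copy())

    def to_dict(self) -> dict:
        return {
            f: {
                "lambda": float(r["lam"]),
                "shift": float(r["shift"]),
                "scale": float(r["scale"]),
            }
            for f, r in self.table.iterrows()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        rows = {
            f: (v["lambda"], v["shift"], v["scale"]) for f, v in d.items()
        }
        return cls(
            pd.DataFrame.from_dict(rows, orient="index", columns=["lam", "shift", "scale"])
        )


def fit_transforms(features: pd.DataFrame) -> TransformParams:
    """Estimate Yeo-Johnson lambda and z-parameters per feature (discovery only)."""
    rows = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        sd_raw = x.std(ddof=0)
        if sd_raw == 0:
            raise ModelError(f"feature {col!r} has zero variance in discovery")
        lam = fit_lambda(x)
        y = yeo_johnson(x, lam)
        shift = float(y.mean())
        scale = float(y.std(ddof=0))
        if scale == 0:
            raise ModelError(f"feature {col!r} degenerate after Yeo-Johnson")
        rows[col] = (lam, shift, scale)
    return TransformParams(
        pd.DataFrame.from_dict(rows, orient="index", columns=["lam", "shift", "scale"])
    )


def apply_transforms(features: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    """Pure application of stored parameters: YJ then (y - shift)/scale."""
    missing = [f for f in params.features() if f not in features.columns]
    if missing:
        raise ModelError(f"features missing from input: {missing}")
    out = {}
    for col in params.features():
        row = params.table.loc[col]
        y = yeo_johnson(features[col].to_numpy(dtype=float), float(row["lam"]))
        out[col] = (y - row["shift"]) / row["scale"]
    return pd.DataFrame(out, index=features.index)
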