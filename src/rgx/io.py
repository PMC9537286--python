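"""Standard-format I/O: NIfTI volumes/masks, CSV matrices, JSON artifacts.

The on-disk cohort layout::

    images/<id>_ct.nii.gz     masks/<id>_gtv.nii.gz
    expression.csv            (rows = gene symbols, columns = sample ids)
    clinical.csv              (id, time_months, event, batch, split)
    centroids.csv             gene_sets.gmt
    truth.json                (labels, coefficients, linear predictors)
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError, SizingError
from .images import ImageVolume, RoiMask
from .transcriptome import write_gmt


def write_nifti(vol_or_mask, path: Path, spacing=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol_or_mask, ImageVolume):
        data = vol_or_mask.intensities.astype(np.float32)
        spacing = vol_or_mask.spacing
    else:
        data = np.asarray(vol_or_mask, dtype=np.uint8)
        if spacing is None:
            raise ConfigError("mask writing needs an explicit spacing")
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing)


def read_mask(path: Path, volume: ImageVolume) -> RoiMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj)
    if data.shape != volume.shape or not np.allclose(spacing, volume.spacing, atol=1e-4):
        raise SizingError(
            f"mask grid {data.shape}@{spacing} does not match volume "
            f"{volume.shape}@{volume.spacing}"
        )
    return RoiMask(data > 0)


def read_matrix_csv(path: Path, index_name: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ConfigError(f"duplicate {index_name} identifiers in {path}: {dup[:5]}")
    if df.isna().any().any():
        raise ConfigError(f"missing values in {path}")
    return df


def read_clinical(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "time_months", "event", "batch", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"clinical table {path} lacks columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ConfigError(f"duplicate sample ids in {path}")
    if not df["event"].isin([0, 1]).all():
        raise ConfigError("event flags must be 0/1")
    if (df["time_months"] <= 0).any():
        raise ConfigError("times must be positive")
    return df


def write_cohort(cohort, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, (vol, mask) in cohort.volumes.items():
        write_nifti(vol, outdir / "images" / f"{pid}_ct.nii.gz")
        write_nifti(mask.morphological, outdir / "masks" / f"{pid}_gtv.nii.gz", vol.spacing)
    cohort.expression.rename_axis("gene").to_csv(outdir / "expression.csv")
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.centroids.rename_axis("gene").to_csv(outdir / "centroids.csv")
    cohort.features.rename_axis("id").to_csv(outdir / "features_true.csv")
    write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    truth = {
        "subtype": cohort.truth["subtype"].to_dict(),
        "signature_classes": {
            k: {i: int(v) for i, v in s.items()}
            for k, s in cohort.truth["signature_classes"].items()
        },
        "activations": {
            k: {i: float(v) for i, v in s.items()}
            for k, s in cohort.truth["activations"].items()
        },
        "hazard_coefficients": cohort.truth["hazard_coefficients"],
        "lp_true": {i: float(v) for i, v in cohort.truth["lp_true"].items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)


def read_cohort_tables(indir: Path) -> dict:
    """Read back the tabular cohort artifacts (images load lazily by id)."""
    indir = Path(indir)
    out = {
        "expression": read_matrix_csv(indir / "expression.csv"),
        "clinical": read_clinical(indir / "clinical.csv"),
        "centroids": read_matrix_csv(indir / "centroids.csv"),
    }
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            out["truth"] = json.load(fh)
    return out


def load_patient_image(indir: Path, pid: str) -> tuple[ImageVolume, RoiMask]:
    indir = Path(indir)
    vol = read_volume(indir / "images" / f"{pid}_ct.nii.gz")
    mask = read_mask(indir / "masks" / f"{pid}_gtv.nii.gz", vol)
    return vol, mask
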