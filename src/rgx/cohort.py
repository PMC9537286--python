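"""Synthetic paired image / expression / outcome cohorts with planted,
recoverable structure.

The generator emulates the study conditions of a multicentre HNSCC
radiochemotherapy cohort: a discovery (n = 122) and validation (n = 84)
split, planning-CT-like tumour volumes with controllable shape
irregularity and grey-level heterogeneity (plus air- and bone-like
inclusions that the HU re-segmentation must exclude), expression profiles
built as subtype centroids plus Gaussian noise plus additive/multiplicative
batch effects, and exponential survival times from a ground-truth Cox model
linking extracted image features and planted metagene activations to
hazard, with independent uniform censoring.

All randomness flows from one root seed through named substreams (images,
expression, outcomes), so a fixed seed regenerates byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .errors import ConfigError, SizingError
from .features import extract_features
from .images import ImageVolume, PreprocessConfig, RoiMask, preprocess
from .transcriptome import SUBTYPES, UNCLASSIFIED, GeneSet

HEDGEHOG_SET = "HALLMARK_HEDGEHOG_SIGNALING"
E2F_SET = "HALLMARK_E2F_TARGETS"

#: subtype mix of the emulated cohort (remainder stays unclassified)
DEFAULT_SUBTYPE_PROPORTIONS = (0.156, 0.185, 0.083, 0.112)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_discovery: int = 122
    n_validation: int = 84
    subtype_proportions: tuple[float, float, float, float] = DEFAULT_SUBTYPE_PROPORTIONS
    noise_sd_expression: float = 1.0
    batch_effects: dict = field(
        default_factory=lambda: {
            "discovery": {"shift": 0.0, "scale": 1.0},
            "validation": {"shift": 0.8, "scale": 1.1},
        }
    )
    tumour_shape: float = 0.4  # irregularity amplitude in [0, 1]
    tumour_texture: float = 0.5  # heterogeneity amplitude in [0, 1]
    tumour_size_mm: float = 24.0  # mean diameter
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    hazard_coefficients: dict = field(
        default_factory=lambda: {
            "log_stat_p90": 0.5,
            "morph_volume": 0.3,
            HEDGEHOG_SET: 0.5,
            E2F_SET: -0.4,
        }
    )
    baseline_rate: float = 0.02  # events per month
    censoring_rate: float = 0.35
    n_centroid_genes: int = 200
    n_extra_genes: int = 300
    include_outliers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discovery <= 0 or self.n_validation <= 0:
            raise ConfigError("cohort sizes must be positive")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if len(props) != 4 or (props < 0).any() or (props > 1).any() or props.sum() > 1:
            raise ConfigError("subtype proportions must be four values in [0,1] summing <= 1")
        if not 0 <= self.censoring_rate <= 1:
            raise ConfigError("censoring rate must be in [0, 1]")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline rate must be positive")


@dataclass
class SyntheticCohort:
    """In-memory cohort: images, expression, outcomes and the planted truth."""

    config: CohortConfig
    ids: list[str]
    volumes: dict  # id -> (ImageVolume, RoiMask), native grid
    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # id, time_months, event, batch, split
    features: pd.DataFrame  # patients x extracted radiomics features
    centroids: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: dict  # subtype labels, signature classes, lp, activations

    @property
    def discovery_ids(self) -> list[str]:
        return list(self.clinical.loc[self.clinical["split"] == "discovery", "id"])

    @property
    def validation_ids(self) -> list[str]:
        return list(self.clinical.loc[self.clinical["split"] == "validation", "id"])


# ---------------------------------------------------------------------------
# tumour volumes
# ---------------------------------------------------------------------------

def _spherical_harmonic_field(theta: np.ndarray, phi: np.ndarray, rng) -> np.ndarray:
    """Random real combination of degree-2..4 spherical harmonics, unit-peak."""
    field_vals = np.zeros_like(theta)
    sph = getattr(special, "sph_harm_y", None)
    for ell in range(2, 5):
        for m in range(-ell, ell + 1):
            a = rng.normal(0.0, 1.0 / (1 + ell))
            if sph is not None:
                y = sph(ell, m, theta, phi)
            else:  # older scipy argument order
                y = special.sph_harm(m, ell, phi, theta)
            field_vals += a * np.real(y)
    peak = np.abs(field_vals).max()
    return field_vals / peak if peak > 0 else field_vals


def generate_tumour_volume(
    shape: float,
    texture: float,
    size_mm: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    include_outliers: bool = True,
    background_hu: float = -100.0,
    soft_tissue_hu: float = 40.0,
) -> tuple[ImageVolume, RoiMask]:
    """One tumour: harmonic-perturbed sphere with Gaussian-random-field texture.

    ``shape`` scales the boundary perturbation (0 = discrete sphere);
    ``texture`` scales both the variance and the correlation length of the
    in-mask intensity field (0 = constant soft tissue).  With
    ``include_outliers`` an air-like (< -150 HU) and a bone-like (> 180 HU)
    inclusion are embedded, exercising the HU re-segmentation.
    """
    if size_mm <= 0:
        raise SizingError("tumour size must be positive")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise SizingError("spacing components must be positive")
    if not (0 <= shape <= 1 and 0 <= texture <= 1):
        raise SizingError("shape and texture amplitudes must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    radius = size_mm / 2.0
    half = [int(np.ceil(radius * (1.0 + shape) / s)) + 3 for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    r = np.sqrt(sum(g**2 for g in grids))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, grids[2] / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(grids[1], grids[0])
    if shape > 0:
        # sharpened outward lobes: protrusions stretch the axis-aligned
        # bounding box while adding little volume, so higher shape
        # irregularity lowers the bounding-box volume density
        pert = _spherical_harmonic_field(theta, phi, rng)
        lobes = np.maximum(pert, 0.0) ** 4
        peak = lobes.max()
        if peak > 0:
            lobes /= peak
        r_limit = radius * (1.0 + shape * lobes)
    else:
        rng.normal(size=45)  # keep the stream aligned across shape settings
        r_limit = np.full_like(r, radius)
    mask = r <= r_limit
    if not mask.any():
        raise SizingError("tumour smaller than one voxel at this spacing")
    # keep the largest connected component (extreme perturbations can pinch off)
    comp, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = np.bincount(comp.ravel())[1:]
        mask = comp == (np.argmax(sizes) + 1)

    intensities = np.full(mask.shape, background_hu)
    if texture > 0:
        # heterogeneity amplitude grows and granularity gets finer with the
        # texture dial, so size zones fragment and szm_glnu rises with it
        noise = rng.standard_normal(mask.shape)
        sigma_vox = [max(0.4, (3.0 - 2.2 * texture)) / s for s in spacing]
        fieldv = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
        sd = fieldv.std()
        fieldv = fieldv / sd if sd > 0 else fieldv
        intensities[mask] = soft_tissue_hu + texture * 40.0 * fieldv[mask]
    else:
        rng.standard_normal(mask.shape)  # stream alignment
        intensities[mask] = soft_tissue_hu
    np.clip(intensities, -140.0, 170.0, out=intensities)

    if include_outliers:
        for offset_sign, value in ((1, -800.0), (-1, 400.0)):
            centre = np.array([offset_sign * radius / 2.0, 0.0, 0.0])
            d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre)))
            blob = (d <= max(2.0, radius / 5.0)) & mask
            intensities[blob] = value
    return ImageVolume(intensities, spacing), RoiMask(mask)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_centroids(n_genes: int = 200, seed: int = 0) -> pd.DataFrame:
    """Synthetic subtype centroid profiles (genes x 4 subtypes).

    A stand-in for published centroid data: shared baseline log2 intensity
    around 8 with unit-SD subtype-specific deviations.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    base = rng.normal(8.0, 1.0, size=(n_genes, 1))
    dev = rng.normal(0.0, 1.0, size=(n_genes, 4))
    return pd.DataFrame(base + dev, index=genes, columns=list(SUBTYPES))


def make_gene_sets(
    genes: list[str], seed: int = 0, extra_sets: int = 4
) -> list[GeneSet]:
    """Hallmark-style synthetic gene sets over the cohort's gene universe.

    Always contains a 35-gene hedgehog-signalling-like and a 200-gene
    E2F-targets-like set (the metagenes the prognostic task combines with
    radiomics) plus a few decoys.
    """
    rng = np.random.default_rng(seed)
    pool = list(genes)
    if len(pool) < 260:
        raise ConfigError("gene universe too small for the default gene sets")
    sets = []
    chosen = rng.choice(len(pool), size=35, replace=False)
    sets.append(GeneSet(HEDGEHOG_SET, tuple(pool[i] for i in chosen)))
    remaining = [i for i in range(len(pool)) if i not in set(chosen)]
    chosen2 = rng.choice(remaining, size=min(200, len(remaining)), replace=False)
    sets.append(GeneSet(E2F_SET, tuple(pool[i] for i in chosen2)))
    for k in range(extra_sets):
        size = int(rng.integers(20, 60))
        idx = rng.choice(len(pool), size=size, replace=False)
        sets.append(GeneSet(f"HALLMARK_SYNTHETIC_{k + 1}", tuple(pool[i] for i in idx)))
    return sets


def generate_expression(
    n: int,
    centroids: pd.DataFrame,
    labels,
    noise_sd: float,
    batch_labels=None,
    batch_effects: dict | None = None,
    seed: int = 0,
    extra_genes: list[str] | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Expression = subtype centroid + Gaussian noise + batch shift/scale.

    ``labels`` may name a centroid column or be ``"unclassified"`` (drawn as
    a 50/50 mixture of two random centroids, so the ambiguity rule has
    positive cases).  Genes not in the centroid profile are filled with
    independent noise around the overall baseline.
    """
    labels = list(labels)
    if len(labels) != n:
        raise ConfigError(f"{n} samples but {len(labels)} labels")
    rng = np.random.default_rng(seed)
    genes = list(centroids.index)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    cols = {}
    for j, label in enumerate(labels):
        if label == UNCLASSIFIED:
            a, b = rng.choice(len(centroids.columns), size=2, replace=False)
            mean = 0.5 * (centroids.iloc[:, a] + centroids.iloc[:, b]).to_numpy()
        elif label in centroids.columns:
            mean = centroids[label].to_numpy()
        else:
            raise ConfigError(f"label {label!r} names no centroid column")
        cols[sample_ids[j]] = mean + rng.normal(0.0, noise_sd, size=len(genes))
    expr = pd.DataFrame(cols, index=genes)
    if extra_genes:
        extra = pd.DataFrame(
            rng.normal(8.0, 1.0, size=(len(extra_genes), n)),
            index=extra_genes,
            columns=expr.columns,
        )
        expr = pd.concat([expr, extra])
    if batch_labels is not None and batch_effects:
        batch_labels = list(batch_labels)
        for j, batch in enumerate(batch_labels):
            eff = batch_effects.get(batch, {"shift": 0.0, "scale": 1.0})
            expr.iloc[:, j] = expr.iloc[:, j] * eff.get("scale", 1.0) + eff.get("shift", 0.0)
    return expr


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def generate_outcomes(
    design: pd.DataFrame,
    hazard_coefficients: dict,
    baseline_rate: float = 0.02,
    censoring_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times under a ground-truth Cox model.

    ``T ~ Exp(rate = baseline_rate * exp(x'beta))`` with independent uniform
    censoring whose upper bound is calibrated by bisection to the requested
    censoring fraction.  The linear predictor is kept as ground truth.
    """
    if baseline_rate <= 0:
        raise ConfigError("baseline rate must be positive")
    missing = [f for f in hazard_coefficients if f not in design.columns]
    if missing:
        raise ConfigError(f"hazard coefficients name absent features: {missing}")
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(design))
    for name, beta in hazard_coefficients.items():
        lp += beta * design[name].to_numpy(dtype=float)
    rate = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate <= 0:
        time, event = t_event, np.ones(len(design), dtype=int)
    else:
        u = rng.uniform(size=len(design))
        lo, hi = 1e-6, float(t_event.max() * 100)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = float((t_event > mid * u).mean())
            if frac > censoring_rate:
                lo = mid
            else:
                hi = mid
        c = hi * u
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    return pd.DataFrame(
        {"time_months": time, "event": event, "lp_true": lp}, index=design.index
    )


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _draw_subtype_labels(n: int, proportions, rng) -> list[str]:
    probs = list(proportions) + [1.0 - float(np.sum(proportions))]
    cats = list(SUBTYPES) + [UNCLASSIFIED]
    return [cats[i] for i in rng.choice(len(cats), size=n, p=probs)]


def generate_cohort(config: CohortConfig, outdir: str | Path | None = None) -> SyntheticCohort:
    """Generate a full paired cohort; optionally write the on-disk layout.

    The per-patient pipeline: draw a subtype and per-patient shape/texture
    dials, synthesise the tumour volume, pre-process and extract radiomics
    features, plant bimodal metagene activations into the expression
    profile, and draw survival from the ground-truth Cox model on the
    z-scored design of extracted features and activations.
    """
    ss = np.random.SeedSequence(config.seed)
    img_seed, expr_seed, out_seed, aux_seed = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)
    ]
    rng_img = np.random.default_rng(img_seed)
    rng_aux = np.random.default_rng(aux_seed)

    n = config.n_discovery + config.n_validation
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    splits = ["discovery"] * config.n_discovery + ["validation"] * config.n_validation
    batches = list(splits)  # expression batches coincide with recruiting study

    subtype_labels = _draw_subtype_labels(n, config.subtype_proportions, rng_aux)

    # --- images + features --------------------------------------------------
    volumes: dict = {}
    feat_rows = {}
    cfg_img = PreprocessConfig()
    for i, pid in enumerate(ids):
        # atypical tumours are more regular and grey-level homogeneous,
        # which is what the radiomics subtype classifier has to pick up
        atypical = subtype_labels[i] == "atypical"
        shape_mu = config.tumour_shape * (0.45 if atypical else 1.0)
        texture_mu = config.tumour_texture * (0.45 if atypical else 1.0)
        size_mu = config.tumour_size_mm * (0.85 if atypical else 1.0)
        shape_i = float(np.clip(rng_img.normal(shape_mu, 0.12), 0.0, 1.0))
        texture_i = float(np.clip(rng_img.normal(texture_mu, 0.15), 0.02, 1.0))
        size_i = float(size_mu * np.exp(rng_img.normal(0.0, 0.25)))
        vol, mask = generate_tumour_volume(
            shape_i,
            texture_i,
            size_i,
            config.spacing,
            seed=int(rng_img.integers(0, 2**31 - 1)),
            include_outliers=config.include_outliers,
        )
        volumes[pid] = (vol, mask)
        base, logv, mask_p = preprocess(vol, mask, cfg_img)
        feat_rows[pid] = extract_features(base, logv, mask_p, cfg_img).values
    features = pd.DataFrame.from_dict(feat_rows, orient="index")

    # --- expression ----------------------------------------------------------
    centroids = make_centroids(config.n_centroid_genes, seed=expr_seed)
    extra_genes = [f"X{i:04d}" for i in range(1, config.n_extra_genes + 1)]
    expr = generate_expression(
        n,
        centroids,
        subtype_labels,
        config.noise_sd_expression,
        batch_labels=batches,
        batch_effects=config.batch_effects,
        seed=expr_seed + 1,
        extra_genes=extra_genes,
        sample_ids=ids,
    )
    gene_sets = make_gene_sets(list(expr.index), seed=expr_seed + 2)
    rng_expr = np.random.default_rng(expr_seed + 3)
    activations = {}
    signature_truth = {}
    for gs in gene_sets[:2]:  # hedgehog-like and E2F-like carry real signal
        group = rng_expr.integers(0, 2, size=n)
        act = (2 * group - 1) * 1.0 + rng_expr.normal(0.0, 0.3, size=n)
        loadings = rng_expr.uniform(0.4, 0.9, size=len(gs.genes))
        for g, load in zip(gs.genes, loadings):
            expr.loc[g] = expr.loc[g].to_numpy() + load * act
        activations[gs.name] = pd.Series(act, index=ids)
        signature_truth[gs.name] = pd.Series(group + 1, index=ids)

    # --- outcomes ------------------------------------------------------------
    design_cols = {}
    for name in config.hazard_coefficients:
        if name in features.columns:
            design_cols[name] = features[name]
        elif name in activations:
            design_cols[name] = activations[name]
        else:
            raise ConfigError(f"hazard coefficient {name!r} matches no feature or metagene")
    design = pd.DataFrame(design_cols, index=ids)
    design = (design - design.mean()) / design.std(ddof=0)  # per-SD log hazard ratios
    outcomes = generate_outcomes(
        design,
        config.hazard_coefficients,
        config.baseline_rate,
        config.censoring_rate,
        seed=out_seed,
    )

    clinical = pd.DataFrame(
        {
            "id": ids,
            "time_months": outcomes["time_months"].to_numpy(),
            "event": outcomes["event"].to_numpy(),
            "batch": batches,
            "split": splits,
        }
    )
    truth = {
        "subtype": pd.Series(subtype_labels, index=ids),
        "signature_classes": signature_truth,
        "activations": activations,
        "hazard_coefficients": dict(config.hazard_coefficients),
        "lp_true": outcomes["lp_true"],
    }
    cohort = SyntheticCohort(
        config=config,
        ids=ids,
        volumes=volumes,
        expression=expr,
        clinical=clinical,
        features=features,
        centroids=centroids,
        gene_sets=gene_sets,
        truth=truth,
    )
    if outdir is not None:
        from . import io as rgx_io

        rgx_io.write_cohort(cohort, Path(outdir))
    return cohort
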