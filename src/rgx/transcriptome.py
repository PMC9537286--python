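"""Expression-side computations.

Molecular subtyping assigns each tumour to one of the four HNSCC
expression subtypes (atypical, basal, classical, mesenchymal) by Pearson
correlation of its median-centred profile with published subtype centroids;
ambiguous or weakly correlated samples stay unclassified.  Gene-signature
surrogate classes are built by k-means (k = 2) on the signature genes in the
discovery cohort and transferred to validation by nearest centroid.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigError, ModelError

SUBTYPES = ("atypical", "basal", "classical", "mesenchymal")
UNCLASSIFIED = "unclassified"
#: minimum top correlation and minimum (top - second) gap for a call
MIN_CORRELATION = 0.2
MIN_GAP = 0.2


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.genes:
            if g not in seen:
                seen.append(g)
        if not seen:
            raise ConfigError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(seen))


@dataclass
class SubtypeAssignment:
    """Per-sample subtype correlations and the resulting label."""

    correlations: pd.DataFrame  # samples x subtypes
    labels: pd.Series  # samples -> subtype or "unclassified"


def assign_subtypes(
    expr: pd.DataFrame, centroids: pd.DataFrame
) -> SubtypeAssignment:
    """Nearest-centroid subtype call with the 0.2 / 0.2-gap rule.

    ``expr``: genes x samples (log2 scale); ``centroids``: genes x subtypes.
    Profiles are restricted to the shared genes and median-centred per
    sample before correlating.  A sample stays unclassified when its best
    correlation is below 0.2 or the gap to the runner-up is 0.2 or less.
    """
    shared = expr.index.intersection(centroids.index)
    if len(shared) < 2:
        raise ConfigError("need at least 2 genes shared with the centroid profile")
    x = expr.loc[shared]
    x = x - x.median(axis=0)
    c = centroids.loc[shared]
    xs = x.to_numpy(dtype=float)
    cs = c.to_numpy(dtype=float)
    xs_c = xs - xs.mean(axis=0)
    cs_c = cs - cs.mean(axis=0)
    x_norm = np.linalg.norm(xs_c, axis=0)
    c_norm = np.linalg.norm(cs_c, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xs_c.T @ cs_c) / np.outer(x_norm, c_norm)
    corr_df = pd.DataFrame(corr, index=expr.columns, columns=centroids.columns)
    labels = []
    for sample in corr_df.index:
        row = corr_df.loc[sample]
        if row.isna().any():  # constant profile
            labels.append(UNCLASSIFIED)
            continue
        ranked = row.sort_values(ascending=False)
        top, second = ranked.iloc[0], ranked.iloc[1]
        if top < MIN_CORRELATION or (top - second) <= MIN_GAP:
            labels.append(UNCLASSIFIED)
        else:
            labels.append(ranked.index[0])
    return SubtypeAssignment(corr_df, pd.Series(labels, index=corr_df.index, name="subtype"))


@dataclass
class SignatureClassModel:
    """Fitted k = 2 signature clustering (z-params + centroids) for transfer."""

    signature: str
    genes: tuple[str, ...]
    z_mean: pd.Series
    z_sd: pd.Series
    centroids: np.ndarray  # 2 x genes, class 1 first (higher mean expression)


def signature_classes(
    expr: pd.DataFrame,
    signature: GeneSet,
    mode: str = "fit",
    model: SignatureClassModel | None = None,
    seed: int = 0,
) -> tuple[pd.Series, SignatureClassModel]:
    """Binary signature classes by k-means (fit) or nearest centroid (transfer).

    Fit: per-gene z-scoring (parameters stored), k-means with k = 2 and 10
    restarts; class 1 is relabelled to the cluster with the higher mean
    signature expression.  Transfer: apply stored z-parameters and assign to
    the nearest stored centroid (Euclidean; ties to the lower-indexed one).
    """
    present = [g for g in signature.genes if g in expr.index]
    missing = [g for g in signature.genes if g not in expr.index]
    if missing:
        warnings.warn(f"signature {signature.name!r}: genes not measured: {missing}")
    if not present:
        raise ConfigError(f"no gene of signature {signature.name!r} measured")
    x = expr.loc[present].T  # samples x genes
    if mode == "fit":
        if len(x) < 2:
            raise ModelError("k-means needs at least 2 samples")
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        if (sd == 0).all():
            raise ModelError("all signature genes constant; k-means degenerate")
        sd = sd.replace(0.0, 1.0)
        z = (x - mu) / sd
        if z.drop_duplicates().shape[0] < 2:
            raise ModelError("all samples identical; k-means degenerate")
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z.to_numpy())
        labels = km.labels_
        # class 1 = cluster whose raw mean signature expression is higher
        mean0 = x.to_numpy()[labels == 0].mean()
        mean1 = x.to_numpy()[labels == 1].mean()
        order = [1, 0] if mean0 > mean1 else [0, 1]
        centroids = km.cluster_centers_[order][::-1]  # row 0 = class 1
        out = np.where(labels == order[1], 1, 2)
        fitted = SignatureClassModel(signature.name, tuple(present), mu, sd, centroids)
        return pd.Series(out, index=x.index, name=signature.name), fitted
    if mode == "transfer":
        if model is None:
            raise ConfigError("transfer mode needs a fitted model")
        xt = expr.loc[list(model.genes)].T
        z = ((xt - model.z_mean) / model.z_sd).to_numpy()
        d = np.linalg.norm(z[:, None, :] - model.centroids[None, :, :], axis=2)
        cls = np.argmin(d, axis=1) + 1  # argmin ties -> lower index (class 1)
        return pd.Series(cls, index=xt.index, name=model.signature), model
    raise ConfigError(f"unknown mode {mode!r}")


def filter_gene_sets(
    sets: list[GeneSet] | dict[str, GeneSet], keep_list: list[str]
) -> list[GeneSet]:
    """Subset gene sets to ``keep_list`` (in its order); unknown names error
    with a near-miss suggestion."""
    if not keep_list:
        raise ConfigError("keep_list must not be empty")
    by_name = {s.name: s for s in (sets.values() if isinstance(sets, dict) else sets)}
    out = []
    for name in keep_list:
        if name not in by_name:
            near = difflib.get_close_matches(name, by_name, n=1)
            hint = f"; did you mean {near[0]!r}?" if near else ""
            raise ConfigError(
                f"unknown gene set {name!r}{hint} Available: {sorted(by_name)}"
            )
        out.append(by_name[name])
    return out


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ConfigError(f"{path}:{lineno}: GMT line has fewer than 2 genes")
            sets.append(GeneSet(parts[0], tuple(parts[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")
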