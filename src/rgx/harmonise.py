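"""Batch-effect harmonisation: consensus-cluster reference selection and
reference-batch ComBat.

The imaging use case: centres differ in scanners and reconstruction, so a
"reference" population of patients whose feature profiles cluster together
robustly is identified by subsampled consensus clustering in PCA space, and
every other patient is aligned to it by location/scale ComBat adjustment.
The same ComBat core serves expression batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.decomposition import PCA

from .errors import ConfigError


# ---------------------------------------------------------------------------
# consensus clustering for the imaging reference batch
# ---------------------------------------------------------------------------

@dataclass
class ConsensusConfig:
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_resamples: int = 100
    subsample_frac: float = 0.8
    pca_variance: float = 0.9
    seed: int = 0


def _hierarchical_labels(x: np.ndarray, k: int) -> np.ndarray:
    z = linkage(x, method="complete")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_matrix(
    x: np.ndarray, k: int, n_resamples: int, subsample_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Co-clustering frequency over subsampled complete-linkage runs."""
    n = x.shape[0]
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    m = max(2, int(round(subsample_frac * n)))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        labels = _hierarchical_labels(x[idx], min(k, m))
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
        sampled[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        cons = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    return cons


def reference_cluster(
    features: pd.DataFrame,
    config: ConsensusConfig = ConsensusConfig(),
) -> tuple[list, list]:
    """Identify reference patients stable across consensus clusterings.

    z-score features, project to the PCA components covering 90% of the
    variance, run subsampled consensus clustering for each k, and return the
    largest patient set that is pairwise co-assigned at *every* k (ties by
    first occurrence); the remainder are the outliers to be harmonised.
    """
    if len(features) < 3:
        raise ConfigError("need at least 3 patients for consensus clustering")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(z.shape) if min(z.shape) > 1 else 1
    pca = PCA(n_components=n_comp, random_state=config.seed)
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, config.pca_variance) + 1)
    scores = scores[:, :n_keep]
    rng = np.random.default_rng(config.seed)
    partitions = []
    for k in config.k_range:
        cons = consensus_matrix(
            scores, k, config.n_resamples, config.subsample_frac, rng
        )
        dist = squareform(1.0 - cons, checks=False)
        partitions.append(_hierarchical_labels_from_dist(dist, k))
    keys = list(zip(*partitions))  # per patient: cluster label at every k
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    best = max(order, key=lambda key: len(groups[key]))  # ties: first occurrence
    ref_idx = groups[best]
    if len(ref_idx) < 2:
        raise ConfigError(
            "no stable patient set of size >= 2 found; supply a reference manually"
        )
    ids = list(features.index)
    reference = [ids[i] for i in ref_idx]
    outliers = [i for i in ids if i not in set(reference)]
    return reference, outliers


def _hierarchical_labels_from_dist(condensed: np.ndarray, k: int) -> np.ndarray:
    z = linkage(condensed, method="complete")
    return fcluster(z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# reference-batch ComBat
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted reference-batch ComBat adjustment."""

    reference_batch: object
    batches: list
    gamma_star: pd.DataFrame  # batches x features, additive effects
    delta_star: pd.DataFrame  # batches x features, variance effects
    alpha: pd.Series
    pooled_sd: pd.Series
    mode: str
    skipped_features: list = field(default_factory=list)


def _parametric_eb(
    gamma_hat: np.ndarray, delta_hat: np.ndarray, z_batch: np.ndarray, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative-moments empirical-Bayes solution (normal / inverse-gamma priors)."""
    n = z_batch.shape[1]
    g_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1) if delta_hat.size > 1 else 0.0
    if s2 == 0:
        return gamma_hat.copy(), delta_hat.copy()
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * gamma_hat + delta_star * g_bar) / (n * t2 + delta_star)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2 + a_prior - 1)
        if np.max(np.abs(g_new - gamma_star)) < 1e-10 and np.max(
            np.abs(d_new - delta_star)
        ) < 1e-10:
            gamma_star, delta_star = g_new, d_new
            break
        gamma_star, delta_star = g_new, d_new
    return gamma_star, delta_star


def _nonparametric_eb(
    gamma_hat: np.ndarray, delta_hat: np.ndarray, z_batch: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo weighted posterior means on the empirical effect grid.

    For each feature the posterior weight of every *other* feature's
    (gamma_hat, delta_hat) pair is its normal likelihood for this feature's
    standardised batch data."""
    n_features = gamma_hat.size
    gamma_star = np.empty(n_features)
    delta_star = np.empty(n_features)
    for g in range(n_features):
        others = np.arange(n_features) != g
        gh, dh = gamma_hat[others], delta_hat[others]
        x = z_batch[g]
        log_lh = norm.logpdf(x[None, :], loc=gh[:, None], scale=np.sqrt(dh)[:, None]).sum(
            axis=1
        )
        log_lh -= log_lh.max()
        w = np.exp(log_lh)
        total = w.sum()
        if total == 0 or not np.isfinite(total):
            gamma_star[g], delta_star[g] = gamma_hat[g], delta_hat[g]
            continue
        w /= total
        gamma_star[g] = float((w * gh).sum())
        delta_star[g] = float((w * dh).sum())
    return gamma_star, delta_star


def fit_combat(
    features: pd.DataFrame,
    batch_labels: pd.Series,
    reference_batch,
    mode: str = "nonparametric",
) -> BatchModel:
    """Estimate per-batch location/scale adjustments against a reference batch.

    Features are standardised with the reference batch's mean and variance;
    per-batch additive (gamma) and multiplicative (delta^2) effects are
    shrunk by empirical Bayes (``parametric``, ``nonparametric``) or used
    as-is (``direct``).  The reference batch is returned unchanged.
    """
    if mode not in {"parametric", "nonparametric", "direct"}:
        raise ConfigError(f"unknown ComBat mode {mode!r}")
    batch_labels = batch_labels.loc[features.index]
    batches = list(pd.unique(batch_labels))
    if reference_batch not in batches:
        raise ConfigError(f"reference batch {reference_batch!r} not among labels")
    if len(batches) < 2:
        raise ConfigError("need at least 2 batches")
    counts = batch_labels.value_counts()
    if (counts < 2).any():
        raise ConfigError("every batch needs at least 2 members")

    ref_rows = features.loc[batch_labels == reference_batch]
    alpha = ref_rows.mean(axis=0)
    pooled_var = ref_rows.var(axis=0, ddof=1)
    skipped = []
    for batch in batches:
        sub_var = features.loc[batch_labels == batch].var(axis=0, ddof=1)
        zero = sub_var[sub_var == 0].index
        for f in zero:
            if f not in skipped:
                skipped.append(f)
    zero_pooled = pooled_var[pooled_var == 0].index
    for f in zero_pooled:
        if f not in skipped:
            skipped.append(f)
    if skipped:
        warnings.warn(
            f"features passed through unadjusted (zero within-batch variance): {skipped}"
        )
    cols = [c for c in features.columns if c not in set(skipped)]
    pooled_sd = np.sqrt(pooled_var[cols])

    gamma_rows, delta_rows = {}, {}
    z_all = (features[cols] - alpha[cols]) / pooled_sd
    for batch in batches:
        if batch == reference_batch:
            gamma_rows[batch] = pd.Series(0.0, index=cols)
            delta_rows[batch] = pd.Series(1.0, index=cols)
            continue
        zb = z_all.loc[batch_labels == batch].to_numpy().T  # features x samples
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        if mode == "parametric":
            gamma_star, delta_star = _parametric_eb(gamma_hat, delta_hat, zb)
        elif mode == "nonparametric":
            gamma_star, delta_star = _nonparametric_eb(gamma_hat, delta_hat, zb)
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        gamma_rows[batch] = pd.Series(gamma_star, index=cols)
        delta_rows[batch] = pd.Series(np.maximum(delta_star, 1e-12), index=cols)
    return BatchModel(
        reference_batch=reference_batch,
        batches=batches,
        gamma_star=pd.DataFrame(gamma_rows).T,
        delta_star=pd.DataFrame(delta_rows).T,
        alpha=alpha[cols],
        pooled_sd=pooled_sd,
        mode=mode,
        skipped_features=skipped,
    )


def apply_combat(
    features: pd.DataFrame, batch_labels: pd.Series, model: BatchModel
) -> pd.DataFrame:
    """Align non-reference batches to the reference; reference rows are copied
    bit-unchanged."""
    out = features.copy()
    cols = list(model.alpha.index)
    batch_labels = batch_labels.loc[features.index]
    for batch in model.batches:
        if batch == model.reference_batch:
            continue
        rows = batch_labels == batch
        if not rows.any():
            continue
        z = (features.loc[rows, cols] - model.alpha) / model.pooled_sd
        adj = (z - model.gamma_star.loc[batch]) / np.sqrt(model.delta_star.loc[batch])
        out.loc[rows, cols] = adj * model.pooled_sd + model.alpha
    return out


def combat(
    features: pd.DataFrame,
    batch_labels: pd.Series,
    reference_batch,
    mode: str = "nonparametric",
) -> pd.DataFrame:
    """One-shot fit + apply."""
    model = fit_combat(features, batch_labels, reference_batch, mode)
    return apply_combat(features, batch_labels, model)
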