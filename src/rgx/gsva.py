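"""Gene Set Variation Analysis: per-sample, per-gene-set enrichment scores.

The statistic follows the standard GSVA recipe for log-intensity data: each
gene's expression is turned into a sample-relative score through a Gaussian
kernel CDF (bandwidth = the gene's sample SD / 4), genes are ranked per
sample, and a weighted Kolmogorov-Smirnov-like random walk over the ranked
list yields the enrichment score, reported as the signed maximum deviation
from zero.  Scores therefore live in [-1, 1]: +1 means the set's genes sit
at the very top of the sample's ranking, -1 at the very bottom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .transcriptome import GeneSet


def kernel_cdf_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Gaussian-kernel CDF statistic z_ij per gene i and sample j.

    Bandwidth is s_i / 4 with s_i the gene's SD across samples; zero-SD
    genes are dropped (no ranking information).
    """
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes from GSVA")
    x = x[keep]
    h = sd[keep] / 4.0
    # z_ij = mean_k Phi((x_ij - x_ik) / h_i)
    diff = (x[:, :, None] - x[:, None, :]) / h[:, None, None]
    z = norm.cdf(diff).mean(axis=2)
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def _walk_scores(
    order: np.ndarray, weights: np.ndarray, in_set: np.ndarray
) -> float:
    """Signed maximum deviation of the weighted random walk for one sample."""
    w = weights[order]
    member = in_set[order]
    n_out = (~member).sum()
    w_in = w[member].sum()
    steps = np.where(member, w / w_in if w_in > 0 else 0.0, -1.0 / n_out)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


def gsva(
    expr: pd.DataFrame,
    gene_sets: list[GeneSet],
    tau: float = 1.0,
) -> pd.DataFrame:
    """Enrichment scores (samples x gene sets), signed maximum deviation.

    Run separately per cohort by the caller: the kernel CDF couples samples,
    so pooling cohorts would leak validation data into discovery scores.
    """
    if expr.shape[1] < 3:
        raise ConfigError("GSVA needs at least 3 samples")
    z = kernel_cdf_scores(expr)
    genes = list(z.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    zv = z.to_numpy()
    # per sample: stable argsort of decreasing z (ties keep gene order)
    orders = np.argsort(-zv, axis=0, kind="stable")
    ranks = np.empty_like(orders)
    col = np.arange(zv.shape[1])
    ranks[orders, col[None, :]] = np.arange(1, p + 1)[:, None]
    weights = np.abs(ranks - (p + 1) / 2.0) ** tau

    out = {}
    for gs in gene_sets:
        members = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if len(members) < 2:
            warnings.warn(
                f"gene set {gs.name!r} retains fewer than 2 measured genes; skipped"
            )
            continue
        if len(members) >= p:
            warnings.warn(f"gene set {gs.name!r} covers every gene; skipped")
            continue
        in_set = np.zeros(p, dtype=bool)
        in_set[members] = True
        scores = [
            _walk_scores(orders[:, j], weights[:, j], in_set)
            for j in range(zv.shape[1])
        ]
        out[gs.name] = scores
    return pd.DataFrame(out, index=expr.columns)
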