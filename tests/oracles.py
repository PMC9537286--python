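"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops,
textbook formulas) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


# ---------------------------------------------------------------------------
# texture matrices by exhaustive enumeration
# ---------------------------------------------------------------------------

NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def glszm_bruteforce(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Size zones by breadth-first flood fill over the 26-neighbourhood."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    shape = labels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []  # (grey level, size)
    for idx in np.ndindex(shape):
        if not mask[idx] or seen[idx] or labels[idx] == 0:
            continue
        level = labels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                nb = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                    continue
                if mask[nb] and not seen[nb] and labels[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(level), size))
    n_levels = int(labels[mask].max())
    max_size = max(s for _, s in zones)
    out = np.zeros((n_levels, max_size), dtype=np.int64)
    for level, size in zones:
        out[level - 1, size - 1] += 1
    return out


def szm_glnu_bruteforce(labels: np.ndarray, mask: np.ndarray) -> float:
    m = glszm_bruteforce(labels, mask)
    s_g = m.sum(axis=1)
    return float((s_g.astype(float) ** 2).sum() / m.sum())


def glcm_bruteforce(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit voxel-pair enumeration."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    shape = labels.shape
    n_levels = int(labels[mask].max())
    out = np.zeros((n_levels, n_levels), dtype=np.int64)
    for idx in np.ndindex(shape):
        if not mask[idx] or labels[idx] == 0:
            continue
        a = labels[idx]
        for d in DIRECTIONS_13:
            nb = (idx[0] + d[0], idx[1] + d[1], idx[2] + d[2])
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue
            if mask[nb] and labels[nb] > 0:
                b = labels[nb]
                out[a - 1, b - 1] += 1
                out[b - 1, a - 1] += 1
    return out


def glrlm_bruteforce(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Maximal runs by scalar walking from every run start, per direction."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    shape = labels.shape
    runs = []  # (level, length)
    for d in DIRECTIONS_13:
        for idx in np.ndindex(shape):
            if not mask[idx] or labels[idx] == 0:
                continue
            prev = (idx[0] - d[0], idx[1] - d[1], idx[2] - d[2])
            prev_ok = all(0 <= c < s for c, s in zip(prev, shape))
            if prev_ok and mask[prev] and labels[prev] == labels[idx]:
                continue  # not a run start
            length = 1
            cur = idx
            while True:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if not all(0 <= c < s for c, s in zip(nxt, shape)):
                    break
                if not mask[nxt] or labels[nxt] != labels[idx]:
                    break
                length += 1
                cur = nxt
            runs.append((int(labels[idx]), length))
    n_levels = int(labels[mask].max())
    max_len = max(l for _, l in runs)
    out = np.zeros((n_levels, max_len), dtype=np.int64)
    for level, length in runs:
        out[level - 1, length - 1] += 1
    return out


# ---------------------------------------------------------------------------
# one-way ANOVA ICC
# ---------------------------------------------------------------------------

def icc_anova_oracle(x: np.ndarray) -> float:
    """ICC(1,1) from the textbook one-way ANOVA decomposition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ssb = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssw = sum((x[i, j] - x[i].mean()) ** 2 for i in range(n) for j in range(k))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0:
        return 1.0
    return (msb - msw) / (msb + (k - 1) * msw)


# ---------------------------------------------------------------------------
# GSVA, step by step
# ---------------------------------------------------------------------------

def gsva_bruteforce(expr: np.ndarray, genes: list[str], set_genes: list[str]) -> list[float]:
    """Enumerated GSVA score per sample (Gaussian kernel CDF, bandwidth sd/4,
    symmetric rank weights with tau = 1, signed maximum deviation)."""
    expr = np.asarray(expr, dtype=float)
    p, n = expr.shape
    # kernel CDF statistic, gene by gene
    z = np.zeros((p, n))
    for i in range(p):
        sd = np.std(expr[i], ddof=1)
        h = sd / 4.0
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += norm.cdf((expr[i, j] - expr[i, k]) / h)
            z[i, j] = acc / n
    in_set = np.array([g in set(set_genes) for g in genes])
    scores = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], i))  # stable in gene order
        ranks = np.empty(p, dtype=int)
        for position, i in enumerate(order, start=1):
            ranks[i] = position
        w = np.abs(ranks - (p + 1) / 2.0)
        w_in_total = sum(w[i] for i in range(p) if in_set[i])
        n_out = p - int(in_set.sum())
        running = 0.0
        best = 0.0
        for i in order:
            if in_set[i]:
                running += w[i] / w_in_total
            else:
                running -= 1.0 / n_out
            if abs(running) > abs(best):
                best = running
        scores.append(best)
    return scores


# ---------------------------------------------------------------------------
# complete-linkage agglomeration (naive O(n^3))
# ---------------------------------------------------------------------------

def complete_linkage_clusters(dist: np.ndarray, height: float) -> list[set[int]]:
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if d < best_d:
                    best_d, best = d, (a, b)
        if best_d > height:
            break
        a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return clusters


# ---------------------------------------------------------------------------
# MRMR criterion, exhaustively evaluated
# ---------------------------------------------------------------------------

def mrmr_greedy_oracle(X, y, mi_fn, bins_fn) -> list[str]:
    """Re-evaluates the greedy quotient criterion over all candidates at
    every step (no caching, no shortcuts)."""
    cols = list(X.columns)
    xd = {c: bins_fn(X[c].to_numpy()) for c in cols}
    yd = bins_fn(np.asarray(y, dtype=float)) if np.asarray(y).dtype.kind == "f" else np.asarray(y)
    selected = []
    while len(selected) < len(cols):
        scored = []
        for c in cols:
            if c in selected:
                continue
            rel = mi_fn(xd[c], yd)
            if selected:
                red = np.mean([mi_fn(xd[c], xd[s]) for s in selected])
                score = rel / max(red, 1e-12)
            else:
                score = rel
            scored.append((c, score))
        # ties by name order: sort names first, pick max score stably
        scored.sort(key=lambda t: t[0])
        best = max(scored, key=lambda t: t[1])
        selected.append(best[0])
    return selected
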