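"""Grey-level texture matrices (GLSZM, GLCM, GLRLM) on 3D discretised volumes.

Conventions: 26-connectivity for size zones; co-occurrences and runs use the
13 unique 3D directions at Chebyshev distance 1, counted symmetrically and
merged into a single matrix before feature computation.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

#: The 13 unique direction vectors of the 3D unit neighbourhood (up to sign).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def _masked_labels(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    g = np.zeros(labels.shape, dtype=np.int32)
    g[mask] = labels[mask]
    return g


def grey_level_size_zone_matrix(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """GLSZM: ``M[g-1, s-1]`` counts 26-connected zones of grey level ``g`` and size ``s``."""
    mask = np.asarray(mask, dtype=bool)
    g = _masked_labels(labels, mask)
    n_levels = int(g.max())
    sizes_per_level: list[np.ndarray] = []
    max_size = 1
    for level in range(1, n_levels + 1):
        comp = measure.label(g == level, connectivity=3)
        if comp.max() == 0:
            sizes_per_level.append(np.empty(0, dtype=np.int64))
            continue
        sizes = np.bincount(comp.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    out = np.zeros((n_levels, max_size), dtype=np.int64)
    for level_idx, sizes in enumerate(sizes_per_level):
        for s in sizes:
            out[level_idx, s - 1] += 1
    return out


def _offset_slices(shape: tuple[int, ...], d: tuple[int, int, int]):
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def grey_level_cooccurrence_matrix(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric GLCM merged over the 13 directions (distance 1, 26-neighbourhood)."""
    mask = np.asarray(mask, dtype=bool)
    g = _masked_labels(labels, mask)
    n_levels = int(g.max())
    out = np.zeros((n_levels, n_levels), dtype=np.int64)
    for d in DIRECTIONS_3D:
        src, dst = _offset_slices(g.shape, d)
        a, b = g[src], g[dst]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        np.add.at(out, (a[ok] - 1, b[ok] - 1), 1)
        np.add.at(out, (b[ok] - 1, a[ok] - 1), 1)
    return out


def grey_level_run_length_matrix(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """GLRLM ``M[g-1, r-1]``: maximal same-level runs, merged over the 13 directions."""
    mask = np.asarray(mask, dtype=bool)
    g = _masked_labels(labels, mask)
    n_levels = int(g.max())
    shape = np.array(g.shape)
    rows: list[np.ndarray] = []
    lens: list[np.ndarray] = []
    for d in DIRECTIONS_3D:
        dv = np.array(d)
        # run starts: in-mask voxels whose predecessor along -d has a different level
        pred = np.zeros_like(g)
        src, dst = _offset_slices(g.shape, d)
        pred[dst] = g[src]
        start = (g > 0) & (pred != g)
        pos = np.argwhere(start)
        level = g[start]
        length = np.ones(len(pos), dtype=np.int64)
        active = np.arange(len(pos))
        cur = pos.copy()
        while active.size:
            nxt = cur[active] + dv
            inside = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(active.size, dtype=bool)
            if inside.any():
                ii = nxt[inside]
                cont[inside] = g[ii[:, 0], ii[:, 1], ii[:, 2]] == level[active[inside]]
            keep = active[cont]
            length[keep] += 1
            cur[keep] += dv
            active = keep
        rows.append(level)
        lens.append(length)
    level = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    length = np.concatenate(lens) if lens else np.empty(0, dtype=np.int64)
    max_len = int(length.max()) if length.size else 1
    out = np.zeros((n_levels, max_len), dtype=np.int64)
    np.add.at(out, (level - 1, length - 1), 1)
    return out


# ---------------------------------------------------------------------------
# features from the matrices
# ---------------------------------------------------------------------------

def glszm_features(m: np.ndarray) -> dict[str, float]:
    n_s = m.sum()
    if n_s == 0:
        return {}
    gl = np.arange(1, m.shape[0] + 1, dtype=float)
    sz = np.arange(1, m.shape[1] + 1, dtype=float)
    p = m / n_s
    s_g = m.sum(axis=1).astype(float)  # zones per grey level
    s_z = m.sum(axis=0).astype(float)  # zones per size
    n_vox = float((m * sz[None, :]).sum())
    mu_g = float((p.sum(axis=1) * gl).sum())
    mu_z = float((p.sum(axis=0) * sz).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entr = -float((p[p > 0] * np.log2(p[p > 0])).sum())
    return {
        "szm_sze": float((s_z / sz**2).sum() / n_s),
        "szm_lze": float((s_z * sz**2).sum() / n_s),
        "szm_glnu": float((s_g**2).sum() / n_s),
        "szm_glnu_norm": float((s_g**2).sum() / n_s**2),
        "szm_zsnu": float((s_z**2).sum() / n_s),
        "szm_zsnu_norm": float((s_z**2).sum() / n_s**2),
        "szm_z_perc": float(n_s / n_vox),
        "szm_gl_var": float((p * (gl[:, None] - mu_g) ** 2).sum()),
        "szm_zs_var": float((p * (sz[None, :] - mu_z) ** 2).sum()),
        "szm_zs_entr": entr,
    }


def glcm_features(m: np.ndarray) -> dict[str, float]:
    total = m.sum()
    if total == 0:
        return {}
    p = m / total
    n = m.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    var_i = float((p * (ii - mu_i) ** 2).sum())
    var_j = float((p * (jj - mu_j) ** 2).sum())
    diff = np.abs(ii - jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        joint_entr = -float((p[p > 0] * np.log2(p[p > 0])).sum())
    if var_i > 0 and var_j > 0:
        corr = float((p * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 1.0  # single grey level: perfectly correlated by convention
    return {
        "cm_joint_max": float(p.max()),
        "cm_joint_entr": joint_entr,
        "cm_energy": float((p**2).sum()),
        "cm_contrast": float((p * diff**2).sum()),
        "cm_dissimilarity": float((p * diff).sum()),
        "cm_inv_diff": float((p / (1.0 + diff)).sum()),
        "cm_inv_diff_mom": float((p / (1.0 + diff**2)).sum()),
        "cm_corr": corr,
    }


def glrlm_features(m: np.ndarray, n_directions: int = len(DIRECTIONS_3D)) -> dict[str, float]:
    n_r = m.sum()
    if n_r == 0:
        return {}
    gl = np.arange(1, m.shape[0] + 1, dtype=float)
    rl = np.arange(1, m.shape[1] + 1, dtype=float)
    r_g = m.sum(axis=1).astype(float)
    r_l = m.sum(axis=0).astype(float)
    p = m / n_r
    mu_g = float((p.sum(axis=1) * gl).sum())
    # voxels counted once per direction
    n_vox = float((m * rl[None, :]).sum()) / n_directions
    return {
        "rlm_sre": float((r_l / rl**2).sum() / n_r),
        "rlm_lre": float((r_l * rl**2).sum() / n_r),
        "rlm_glnu": float((r_g**2).sum() / n_r),
        "rlm_rlnu": float((r_l**2).sum() / n_r),
        "rlm_r_perc": float(n_r / (n_vox * n_directions)),
        "rlm_gl_var": float((p * (gl[:, None] - mu_g) ** 2).sum()),
    }
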