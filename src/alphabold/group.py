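"""Second-level inference over subjects' alpha-coupling maps.

One- and two-sample t-tests with mean-centered covariates on the per-subject
contrast estimates (the summary-statistics approach), gray-matter masking,
uncorrected-p voxel thresholding with a cluster-extent criterion, overlap of
surviving clusters with an atlas mask, per-subject hit counting across ROIs,
and pooled-variance scalar group comparisons (including a summary-statistic
variant usable with printed moments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import StatMap


def make_gm_mask(prob_map: np.ndarray, thresh: float = 0.3) -> np.ndarray:
    """Binary gray-matter mask: voxels with tissue probability >= ``thresh``."""
    prob = np.asarray(prob_map, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    mask = prob >= thresh
    if not np.any(mask):
        raise ValueError("gray-matter mask is empty")
    return mask


def _stack_maps(maps) -> np.ndarray:
    arrs = [m.values if isinstance(m, StatMap) else np.asarray(m, dtype=float)
            for m in maps]
    return np.stack(arrs, axis=0)


def _center_covars(covars, n: int) -> np.ndarray | None:
    if covars is None:
        return None
    C = np.asarray(covars, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("one covariate row per subject required")
    return C - C.mean(axis=0)


def _voxelwise_t(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray,
                 df: int) -> tuple[np.ndarray, np.ndarray]:
    """t for ``contrast' beta`` of subject-level OLS at every voxel.

    Returns (t, zero_variance_flag, contrast_estimate); zero-residual voxels
    get a signed infinity sentinel when the contrast estimate is nonzero,
    0 otherwise.
    """
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df
    scale = float(contrast @ np.linalg.inv(X.T @ X) @ contrast)
    cb = contrast @ B
    zero = sigma2 <= np.finfo(float).eps * np.maximum(1.0, np.sum(Y**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = cb / np.sqrt(sigma2 * scale)
    t[zero & (cb > 0)] = np.inf
    t[zero & (cb < 0)] = -np.inf
    t[zero & (cb == 0)] = 0.0
    return t, zero, cb


def one_sample_t(maps, covars=None) -> StatMap:
    """Voxel-wise one-sample t (intercept) across subjects, adjusted for
    mean-centered covariates. ``df = n - 1 - n_covars``."""
    Y = _stack_maps(maps)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("at least 3 subject maps required")
    C = _center_covars(covars, n)
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    grid = Y.shape[1:]
    flat = Y.reshape(n, -1)
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    t, zero, eff = _voxelwise_t(flat, X, contrast, df)
    return StatMap(values=t.reshape(grid), df=df, contrast="one_sample",
                   n_zero_variance=int(zero.sum()), effect=eff.reshape(grid))


def two_sample_t(maps_a, maps_b, covars=None) -> StatMap:
    """Voxel-wise group-difference t (group A minus group B) with pooled
    residual variance and mean-centered covariates shared across groups.
    ``df = n - 2 - n_covars``."""
    Ya, Yb = _stack_maps(maps_a), _stack_maps(maps_b)
    if Ya.shape[0] < 2 or Yb.shape[0] < 2:
        raise ValueError("each group requires at least 2 subject maps")
    Y = np.concatenate([Ya, Yb], axis=0)
    n = Y.shape[0]
    g = np.concatenate([np.ones(Ya.shape[0]), np.zeros(Yb.shape[0])])
    C = _center_covars(covars, n)
    X = np.column_stack([g, np.ones(n)] if C is None else [g, np.ones(n), C])
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    flat = Y.reshape(n, -1)
    t, zero, eff = _voxelwise_t(flat, X, contrast, df)
    return StatMap(values=t.reshape(Y.shape[1:]), df=df, contrast="two_sample",
                   n_zero_variance=int(zero.sum()),
                   effect=eff.reshape(Y.shape[1:]))


# ---------------------------------------------------------------------------
# clusters

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterTable:
    """Suprathreshold connected components surviving the extent threshold."""

    table: pd.DataFrame  # size, peak_t, i, j, k, x_mm, y_mm, z_mm
    labels: np.ndarray  # 3D int array, 0 = background, ids match table rows
    threshold: float
    df: int

    def __len__(self) -> int:
        return len(self.table)


def threshold_clusters(
    stat_map: StatMap,
    p: float = 0.01,
    k: int = 50,
    connectivity: int = 18,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> ClusterTable:
    """One-sided suprathreshold clustering of a t map.

    Voxels with one-sided p below ``p`` (i.e. ``t > t_crit``) are labeled
    into connected components (6, 18 or 26 connectivity); components smaller
    than ``k`` voxels are discarded. Rows are sorted by size descending,
    ties by peak t descending, then by lexicographic peak index. Pass the
    negated map for the negative contrast.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18, or 26")
    t_crit = float(stats.t.ppf(1.0 - p, stat_map.df))
    vals = stat_map.values
    supra = np.isfinite(vals) & (vals > t_crit)
    supra |= np.isposinf(vals)  # zero-variance positive sentinels exceed any t
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n_labels = ndimage.label(supra, structure=structure)
    rows = []
    out_labels = np.zeros_like(labels)
    if affine is None:
        affine = np.eye(4)
    for lab in range(1, n_labels + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < k:
            continue
        comp_vals = np.where(comp, vals, -np.inf)
        peak_flat = int(np.argmax(comp_vals))  # first occurrence = lexicographic
        i, j, kk = np.unravel_index(peak_flat, vals.shape)
        x, y, z = (affine @ np.array([i, j, kk, 1.0]))[:3]
        rows.append(dict(size=size, peak_t=float(vals[i, j, kk]),
                         i=int(i), j=int(j), k=int(kk),
                         x_mm=float(x), y_mm=float(y), z_mm=float(z),
                         _lab=lab))
    rows.sort(key=lambda r: (-r["size"], -r["peak_t"], (r["i"], r["j"], r["k"])))
    for new_id, r in enumerate(rows, start=1):
        out_labels[labels == r.pop("_lab")] = new_id
    table = pd.DataFrame(rows, columns=["size", "peak_t", "i", "j", "k",
                                        "x_mm", "y_mm", "z_mm"])
    return ClusterTable(table=table, labels=out_labels, threshold=t_crit,
                        df=stat_map.df)


def atlas_overlap(clusters: ClusterTable, label_mask: np.ndarray) -> pd.DataFrame:
    """Per-cluster overlap fraction (|c ∩ atlas| / |c|) and Dice with an
    atlas mask on the same grid."""
    atlas = np.asarray(label_mask, dtype=bool)
    if atlas.shape != clusters.labels.shape:
        raise ValueError("atlas grid does not match cluster grid")
    n_atlas = int(atlas.sum())
    rows = []
    for cid in range(1, len(clusters) + 1):
        comp = clusters.labels == cid
        size = int(comp.sum())
        inter = int(np.sum(comp & atlas))
        rows.append(dict(cluster=cid, size=size,
                         overlap_frac=inter / size if size else 0.0,
                         dice=2.0 * inter / (size + n_atlas) if size + n_atlas else 0.0))
    return pd.DataFrame(rows, columns=["cluster", "size", "overlap_frac", "dice"])


def count_first_level_hits(
    subject_maps: dict,
    roi_masks: dict,
    p: float = 0.01,
) -> pd.DataFrame:
    """Per-group/band/ROI count of subjects with any suprathreshold voxel.

    ``subject_maps`` maps ``(group, band)`` to a list of per-subject
    :class:`StatMap`; a subject is a hit for an ROI when any in-ROI voxel
    has one-sided p below ``p``.
    """
    for name, m in roi_masks.items():
        if not np.any(m):
            raise ValueError(f"ROI mask {name!r} is empty")
    rows = []
    for (grp, band), maps in subject_maps.items():
        for roi_name, roi in roi_masks.items():
            roi = np.asarray(roi, dtype=bool)
            count = 0
            for sm in maps:
                if roi.shape != sm.values.shape:
                    raise ValueError("ROI grid does not match subject map grid")
                t_crit = stats.t.ppf(1.0 - p, sm.df)
                vals = sm.values[roi]
                if np.any(np.isfinite(vals) & (vals > t_crit)):
                    count += 1
            rows.append(dict(group=grp, band=band, roi=roi_name, n=count))
    return pd.DataFrame(rows, columns=["group", "band", "roi", "n"])


# ---------------------------------------------------------------------------
# scalar comparisons


def compare_scalars(values_a, values_b, two_sided: bool = True) -> tuple[float, float]:
    """Pooled-variance independent-samples t-test on two samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least 2 observations per group required")
    return compare_scalars_summary(a.mean(), a.std(ddof=1), len(a),
                                   b.mean(), b.std(ddof=1), len(b),
                                   two_sided=two_sided)


def compare_scalars_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    two_sided: bool = True,
) -> tuple[float, float]:
    """Pooled two-sample t from summary moments; ``df = n_a + n_b - 2``.

    Zero pooled variance yields ``(0, 1)`` for equal means and an infinite
    sentinel with p = 0 otherwise.
    """
    df = n_a + n_b - 2
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if sp2 == 0:
        return (0.0, 1.0) if diff == 0 else (float(np.sign(diff)) * np.inf, 0.0)
    t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    if two_sided:
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(t, df))
    return float(t), p
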