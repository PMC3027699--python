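"""Group inference: t-maps, Monte-Carlo cluster-extent FWE control,
cluster tables.

The cluster-extent threshold is calibrated empirically: smooth Gaussian
null volumes are simulated on the analysis grid, re-standardized within
the mask, thresholded at the voxel-wise p, and the distribution of the
largest suprathreshold cluster is tabulated.  The returned extent is the
smallest k whose exceedance probability is at or below the family-wise
alpha.  Smoothness is the applied smoothing FWHM from the configuration,
not estimated from residuals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import FWHM_TO_SIGMA
from .structures import McThresholdResult, StatMap, TemplateMap, voxel_sizes
from .template import CONNECTIVITY_STRUCTS, _suprathreshold

logger = logging.getLogger("dmnconnect.inference")


def _null_max_cluster_sizes(mask: np.ndarray, sigmas: np.ndarray,
                            z_crit: float, sided: str, n_iter: int,
                            rng: np.random.Generator,
                            structure: np.ndarray) -> np.ndarray:
    """Largest suprathreshold cluster size in each smooth null volume."""
    mask = np.asarray(mask, dtype=bool)
    maxima = np.zeros(n_iter, dtype=np.int64)
    for i in range(n_iter):
        noise = rng.standard_normal(mask.shape).astype(np.float32)
        if sigmas.any():
            noise = ndimage.gaussian_filter(noise, sigma=tuple(sigmas))
        vals = noise[mask]
        z = (noise - vals.mean()) / vals.std()
        supra = (z > z_crit) if sided == "one" else (np.abs(z) > z_crit)
        supra &= mask
        if not supra.any():
            continue
        labels, n_labels = ndimage.label(supra, structure)
        if n_labels:
            sizes = np.bincount(labels.ravel())[1:]
            maxima[i] = sizes.max()
    return maxima


def monte_carlo_cluster_threshold(mask: np.ndarray, fwhm_mm: float = 6.0,
                                  voxel_p: float = 0.005,
                                  alpha: float = 0.05,
                                  sided: str = "two",
                                  n_iter: int = 1000,
                                  connectivity: int = 6,
                                  seed: int = 0,
                                  voxel_mm: tuple[float, float, float] =
                                  (3.0, 3.0, 3.0)) -> McThresholdResult:
    """Calibrate the minimum cluster extent controlling FWE at ``alpha``.

    Returns the smallest k with empirical P(max cluster >= k) <= alpha
    together with the achieved level and the null max-cluster sizes.
    """
    if not (0.0 < voxel_p < 1.0):
        raise ValueError("voxel_p must be in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 for a usable tail estimate")
    z_crit = (stats.norm.ppf(1.0 - voxel_p) if sided == "one"
              else stats.norm.ppf(1.0 - voxel_p / 2.0))
    sigmas = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_mm, dtype=float)
    rng = np.random.default_rng(seed)
    maxima = _null_max_cluster_sizes(np.asarray(mask, dtype=bool), sigmas,
                                     z_crit, sided, n_iter, rng,
                                     CONNECTIVITY_STRUCTS[connectivity])
    note = ""
    if maxima.max() == 0:
        note = "no suprathreshold voxel in any null iteration"
        logger.warning("monte_carlo_cluster_threshold: %s", note)
        return McThresholdResult(min_cluster_vox=1, alpha_achieved=0.0,
                                 n_iterations=n_iter, max_cluster_null=maxima,
                                 seed=seed, note=note)
    # smallest k with P(max >= k) <= alpha
    for k in range(1, int(maxima.max()) + 2):
        achieved = float((maxima >= k).mean())
        if achieved <= alpha:
            return McThresholdResult(min_cluster_vox=k,
                                     alpha_achieved=achieved,
                                     n_iterations=n_iter,
                                     max_cluster_null=maxima, seed=seed)
    raise AssertionError("unreachable: exceedance falls to 0 above the max")


def validate_fwe(mask: np.ndarray, min_cluster_vox: int,
                 fwhm_mm: float = 6.0, voxel_p: float = 0.005,
                 sided: str = "two", n_iter: int = 1000,
                 connectivity: int = 6, seed: int = 1,
                 voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
                 ) -> float:
    """Family-wise false-positive proportion of a given extent threshold
    on fresh smooth null volumes."""
    z_crit = (stats.norm.ppf(1.0 - voxel_p) if sided == "one"
              else stats.norm.ppf(1.0 - voxel_p / 2.0))
    sigmas = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_mm, dtype=float)
    rng = np.random.default_rng(seed)
    maxima = _null_max_cluster_sizes(np.asarray(mask, dtype=bool), sigmas,
                                     z_crit, sided, n_iter, rng,
                                     CONNECTIVITY_STRUCTS[connectivity])
    return float((maxima >= min_cluster_vox).mean())


def two_sample_t_map(maps_a: list[np.ndarray] | np.ndarray,
                     maps_b: list[np.ndarray] | np.ndarray,
                     mask: np.ndarray) -> StatMap:
    """Pooled-variance two-sample t (group A minus group B), two-sided.

    df = n_a + n_b - 2.  Voxels with zero pooled variance get t = 0 and
    are flagged non-significant.
    """
    a = np.asarray(maps_a, dtype=np.float64)
    b = np.asarray(maps_b, dtype=np.float64)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    mask = np.asarray(mask, dtype=bool)
    na, nb = a.shape[0], b.shape[0]
    va, vb = a[:, mask], b[:, mask]
    diff = va.mean(axis=0) - vb.mean(axis=0)
    ss = va.var(axis=0, ddof=1) * (na - 1) + vb.var(axis=0, ddof=1) * (nb - 1)
    df = na + nb - 2
    pooled_se = np.sqrt(ss / df * (1.0 / na + 1.0 / nb))
    tvals = np.zeros_like(diff)
    ok = pooled_se > 0
    tvals[ok] = diff[ok] / pooled_se[ok]
    flagged = np.zeros(mask.shape, dtype=bool)
    flagged[mask] = ~ok
    out = np.zeros(mask.shape)
    out[mask] = tvals
    return StatMap(values=out, df=df, sided="two", mask=mask,
                   flagged_zero_variance=flagged)


def or_mask(group_map_a: TemplateMap | np.ndarray,
            group_map_b: TemplateMap | np.ndarray) -> np.ndarray:
    """Voxel-wise union of two group network maps."""
    a = group_map_a.voxels if isinstance(group_map_a, TemplateMap) else group_map_a
    b = group_map_b.voxels if isinstance(group_map_b, TemplateMap) else group_map_b
    a, b = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a | b


def cluster_mean_z(z_map: np.ndarray, cluster: np.ndarray) -> float:
    """Arithmetic mean of a subject's z over the cluster voxels."""
    cluster = np.asarray(cluster, dtype=bool)
    if not cluster.any():
        raise ValueError("cluster is empty")
    return float(np.asarray(z_map, dtype=np.float64)[cluster].mean())


def _peak_voxel(tvals: np.ndarray, cluster: np.ndarray) -> tuple[int, int, int]:
    """Voxel of maximum |t| in the cluster; ties to first in x-fastest order."""
    idx = np.argwhere(cluster)
    mags = np.abs(tvals[cluster])
    best = mags.max()
    tied = idx[np.isclose(mags, best)]
    # x-fastest scan order == Fortran-order linear index of an (x,y,z) array
    lin = np.ravel_multi_index(tied.T, tvals.shape, order="F")
    return tuple(int(c) for c in tied[np.argmin(lin)])


def extract_clusters(stat: StatMap, voxel_p: float = 0.005,
                     min_cluster_vox: int = 1, connectivity: int = 6,
                     subject_maps_by_group: dict[str, np.ndarray] | None = None,
                     affine: np.ndarray | None = None) -> pd.DataFrame:
    """Cluster table of suprathreshold connected components.

    Columns: size_voxels, size_mm3, peak voxel and world coordinates
    (X left->right, Y posterior->anterior, Z inferior->superior), peak
    statistic, and — when subject maps are given — per-group mean and SD
    of the subject-level cluster-averaged z.  Rows sorted by size
    descending; an empty table is a legitimate result.
    """
    supra = _suprathreshold(stat, voxel_p)
    labels, n_labels = ndimage.label(supra, CONNECTIVITY_STRUCTS[connectivity])
    vox_vol = float(np.prod(voxel_sizes(affine))) if affine is not None else None

    rows = []
    for lab in range(1, n_labels + 1):
        cluster = labels == lab
        size = int(cluster.sum())
        if size < min_cluster_vox:
            continue
        peak = _peak_voxel(stat.values, cluster)
        row: dict[str, object] = {
            "size_voxels": size,
            "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
            "peak_stat": float(stat.values[peak]),
        }
        if vox_vol is not None:
            row["size_mm3"] = size * vox_vol
            world = affine @ np.array([*peak, 1.0])
            row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"] = (
                float(world[0]), float(world[1]), float(world[2]))
        if subject_maps_by_group:
            for group, maps in subject_maps_by_group.items():
                per_subject = [cluster_mean_z(m, cluster) for m in maps]
                row[f"z_mean_{group}"] = float(np.mean(per_subject))
                row[f"z_sd_{group}"] = float(np.std(per_subject, ddof=1))
        rows.append((cluster, row))

    table = pd.DataFrame([r for _, r in rows])
    if len(table):
        table = table.sort_values("size_voxels", ascending=False,
                                  kind="stable").reset_index(drop=True)
    return table


def cluster_label_image(stat: StatMap, voxel_p: float,
                        min_cluster_vox: int,
                        connectivity: int = 6) -> np.ndarray:
    """Integer label image of the significant clusters (0 = background)."""
    supra = _suprathreshold(stat, voxel_p)
    labels, n_labels = ndimage.label(supra, CONNECTIVITY_STRUCTS[connectivity])
    out = np.zeros_like(labels)
    next_id = 1
    for lab in range(1, n_labels + 1):
        cluster = labels == lab
        if cluster.sum() >= min_cluster_vox:
            out[cluster] = next_id
            next_id += 1
    return out
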