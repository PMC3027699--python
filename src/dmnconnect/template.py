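"""Group DMN template construction and best-fit component selection.

Two-pass selection, applied identically to both cohorts:

1. bootstrap pass — per subject, the candidate component is the one whose
   z-map correlates most with a prior map (the simulator's ground-truth
   network, or a user-supplied prior mask on real data); the pooled
   candidate maps of *all* subjects enter a voxel-wise one-sample t-test
   whose positive, cluster-corrected voxels form the template;
2. goodness-of-fit pass — per subject, every component is scored by
   mean z inside the template minus mean z outside it (over the brain
   mask), and the top-scoring component is the best fit.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats

from .structures import ComponentSet, FitResult, StatMap, TemplateMap

logger = logging.getLogger("dmnconnect.template")

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def one_sample_t_map(maps: list[np.ndarray] | np.ndarray,
                     mask: np.ndarray) -> StatMap:
    """Voxel-wise one-sample t across subjects: t = mean / (SD / sqrt(n)).

    Zero-variance voxels get t = 0 and are flagged, not dropped.
    """
    stack = np.asarray(maps, dtype=np.float64)
    if stack.ndim != 4 or stack.shape[0] < 2:
        raise ValueError("need >= 2 subject maps on a common grid")
    mask = np.asarray(mask, dtype=bool)
    n = stack.shape[0]
    vals = stack[:, mask]                      # (n, V)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    tvals = np.zeros_like(mean)
    ok = sd > 0
    tvals[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    flagged = np.zeros(mask.shape, dtype=bool)
    flagged[mask] = ~ok
    out = np.zeros(mask.shape)
    out[mask] = tvals
    return StatMap(values=out, df=n - 1, sided="one", mask=mask,
                   flagged_zero_variance=flagged)


def _suprathreshold(tmap: StatMap, voxel_p: float) -> np.ndarray:
    """Boolean suprathreshold image at the voxel-wise p threshold.

    One-sided maps threshold positive t at p; two-sided maps threshold
    |t| at total two-sided mass p.
    """
    if tmap.sided == "one":
        crit = stats.t.ppf(1.0 - voxel_p, tmap.df)
        supra = tmap.values > crit
    else:
        crit = stats.t.ppf(1.0 - voxel_p / 2.0, tmap.df)
        supra = np.abs(tmap.values) > crit
    return supra & tmap.mask


def build_template(tmap: StatMap, voxel_p: float = 0.005,
                   min_cluster_vox: int = 1,
                   connectivity: int = 6) -> TemplateMap:
    """Threshold a one-sided group t-map and keep large-enough clusters.

    An empty template is returned with a warning rather than raised, so
    the caller can surface the failed selection.
    """
    supra = _suprathreshold(tmap, voxel_p)
    labels, n_labels = ndimage.label(supra, CONNECTIVITY_STRUCTS[connectivity])
    keep = np.zeros_like(supra)
    for lab in range(1, n_labels + 1):
        cluster = labels == lab
        if cluster.sum() >= min_cluster_vox:
            keep |= cluster
    if not keep.any():
        logger.warning("build_template: no suprathreshold cluster survives "
                       "(p<%g, extent>=%d)", voxel_p, min_cluster_vox)
    return TemplateMap(voxels=keep,
                       provenance={"voxel_p": voxel_p,
                                   "min_cluster_vox": min_cluster_vox,
                                   "df": tmap.df,
                                   "connectivity": connectivity})


def goodness_of_fit(z_map: np.ndarray, template: TemplateMap,
                    mask: np.ndarray) -> float:
    """Mean z inside the template minus mean z outside it (within mask)."""
    mask = np.asarray(mask, dtype=bool)
    inside = template.voxels & mask
    outside = mask & ~template.voxels
    if not inside.any():
        raise ValueError("template is empty inside the mask")
    if not outside.any():
        raise ValueError("template covers the whole mask; no outside voxels")
    z = np.asarray(z_map, dtype=np.float64)
    return float(z[inside].mean() - z[outside].mean())


def select_best_fit(components: ComponentSet,
                    template: TemplateMap) -> FitResult:
    """Rank components by goodness-of-fit; ties go to the lower index."""
    if components.n_components < 2:
        raise ValueError("need at least 2 components to rank")
    scores = np.array([goodness_of_fit(components.maps[k], template,
                                       components.mask)
                       for k in range(components.n_components)])
    order = np.lexsort((np.arange(len(scores)), -scores))
    best, second = int(order[0]), int(order[1])
    tie = bool(np.isclose(scores[best], scores[second]))
    if tie:
        logger.info("select_best_fit: tie between components %d and %d "
                    "broken by lower index", best, second)
    return FitResult(scores=scores, best_index=best, second_index=second,
                     tie_broken=tie)


def select_candidate_by_correlation(components: ComponentSet,
                                    prior_map: np.ndarray) -> int:
    """Bootstrap pass: component maximizing |spatial r| with a prior map."""
    prior = np.asarray(prior_map, dtype=np.float64)[components.mask]
    prior = prior - prior.mean()
    norm = np.linalg.norm(prior)
    if norm == 0:
        raise ValueError("prior map is constant inside the mask")
    vecs = components.map_vectors()
    vecs = vecs - vecs.mean(axis=1, keepdims=True)
    r = vecs @ prior / (np.linalg.norm(vecs, axis=1) * norm)
    return int(np.argmax(np.abs(r)))
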