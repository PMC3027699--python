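"""Spatial independent component analysis of a preprocessed BOLD series.

The masked series is flattened to a (time x voxel) matrix, reduced to the
requested model order by principal components, and unmixed by a
deflationary fixed-point iteration (log-cosh contrast) in the *spatial*
domain: voxels are the samples and maps the independent sources.  The
contrast is kurtosis, whose one-unit stable points are single sources
for the sparse super-Gaussian maps this analysis targets.

Components are extracted one at a time, each with its own convergence
test and a small budget of random restarts.  Directions that carry no
stable non-Gaussian structure (for a fixed-point contrast, an exactly
Gaussian direction has zero attraction: E[z g(z)] - E[g'(z)] = 0) do not
converge; when a component exhausts its restarts, extraction stops and
the achieved model order is the number of components extracted so far.
The realized order therefore varies with the data and routinely differs
from the requested order, as ICA software shows on real runs; every
attempt is recorded in a convergence log.

Maps are z-scored over the brain mask (sample SD), components are ordered
by the variance of the series they explain, and each map is sign-flipped
so its spatial skewness is nonnegative — the conventional resolution of
ICA's sign ambiguity that makes "activation" positive.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from scipy import stats

from .structures import BoldSeries, ComponentSet

ICA_TOL = 1e-4
ICA_MAX_ITER = 200


def zscore_map(raw_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize a 3D map over the mask (sample SD); zero outside."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(raw_map, dtype=np.float64)[mask]
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("map has zero spatial variance inside the mask")
    out = np.zeros(raw_map.shape, dtype=np.float64)
    out[mask] = (vals - vals.mean()) / sd
    return out


def _pca_whiten(y: np.ndarray, n_components: int
                ) -> tuple[np.ndarray, float]:
    """Whiten a (t, V) matrix to (n_components, V) unit-variance rows.

    Returns the whitened data and the fraction of variance retained.
    """
    t, v = y.shape
    x = y - y.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / (v - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = evals[:n_components]
    if top[-1] <= 0:
        raise ValueError(
            f"series rank < requested model order {n_components}")
    whitened = (evecs[:, :n_components] / np.sqrt(top)).T @ x
    explained = float(top.sum() / max(evals.sum(), np.finfo(float).tiny))
    return whitened, explained


def _deflation_ica(yw: np.ndarray, rng: np.random.Generator, tol: float,
                   max_iter: int, restarts: int
                   ) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """One-unit fixed-point extraction with Gram-Schmidt deflation.

    The contrast is kurtosis (cube nonlinearity): for whitened data its
    stable fixed points are single sources whenever the sources share the
    sign of their excess kurtosis, which sparse spatial maps do — so the
    iteration cannot settle on a mixture of two networks, a failure mode
    the log-cosh contrast exhibits here.

    Returns the unmixing rows of every converged component and the
    per-attempt log.  Extraction stops at the first component whose
    restart budget is exhausted.
    """
    yw = np.asarray(yw, dtype=np.float32)   # fits cache; tol >> eps(float32)
    n, v = yw.shape
    rows: list[np.ndarray] = []
    log: list[dict[str, Any]] = []
    for k in range(n):
        basis = np.array(rows, dtype=np.float32) if rows else None
        extracted = None
        for attempt in range(restarts):
            w = rng.standard_normal(n).astype(np.float32)
            if basis is not None:
                w -= basis.T @ (basis @ w)
            w /= np.linalg.norm(w)
            converged, iters = False, 0
            for iters in range(1, max_iter + 1):
                wx = w @ yw
                # E[y (w.y)^3] - 3 w  (E[(w.y)^2] = 1 on whitened data)
                w_new = (yw @ (wx * wx * wx)) / v - 3.0 * w
                if basis is not None:
                    w_new -= basis.T @ (basis @ w_new)
                norm = np.linalg.norm(w_new)
                if norm < np.finfo(np.float32).eps:
                    break
                w_new /= norm
                lim = abs(abs(float(w_new @ w)) - 1.0)
                w = w_new
                if lim < tol:
                    converged = True
                    break
            log.append({"component": k, "attempt": attempt,
                        "iterations": iters, "converged": converged})
            if converged:
                extracted = w
                break
        if extracted is None:
            break
        rows.append(extracted)
    return np.array(rows, dtype=np.float64), log


def spatial_ica(series: BoldSeries, n_components: int = 25,
                seed: int = 0, max_attempts: int = 3,
                tol: float = ICA_TOL,
                max_iter: int = ICA_MAX_ITER) -> ComponentSet:
    """Decompose a preprocessed series into spatial components.

    ``n_components`` sets the principal-component reduction (the target
    model order); the realized order is the number of components whose
    fixed-point iteration converged, at least 2 (1 for a single-component
    request).  ``max_attempts`` is the per-component restart budget.
    Raises if too few components converge; the error carries the
    convergence log.
    """
    mask = series.mask
    y = series.masked().astype(np.float64)       # (t, V)
    t, v = y.shape
    n_max = min(t, v) - 1
    if not (1 <= n_components <= n_max):
        raise ValueError(
            f"n_components must be in [1, {n_max}] for a {t}x{v} series")

    rng = np.random.default_rng(seed)
    yw, explained = _pca_whiten(y, n_components)
    w, log = _deflation_ica(yw, rng, tol, max_iter, max_attempts)
    n_realized = len(w)
    if n_realized < min(2, n_components):
        raise RuntimeError(
            f"spatial ICA converged on only {n_realized} component(s) "
            f"of {n_components} requested; log: {log}")

    sources = w @ yw                              # (n_realized, V) maps
    gram = sources @ sources.T
    courses = np.linalg.solve(gram, sources @ y.T).T   # (t, n_realized)

    energy = (courses ** 2).sum(axis=0) * (sources ** 2).sum(axis=1)
    rank = np.argsort(energy)[::-1]
    sources, courses = sources[rank], courses[:, rank]

    maps = np.zeros((n_realized,) + mask.shape, dtype=np.float64)
    for k in range(n_realized):
        flat = np.zeros(mask.shape)
        flat[mask] = sources[k]
        zed = zscore_map(flat, mask)
        if stats.skew(zed[mask]) < 0:
            zed = -zed
            courses[:, k] = -courses[:, k]
        maps[k] = zed

    return ComponentSet(maps=maps, courses=np.asarray(courses, dtype=np.float64),
                        mask=mask, n_requested=n_components,
                        n_realized=n_realized, explained_variance=explained,
                        convergence_log=log)
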