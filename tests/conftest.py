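"""Shared fixtures: small synthetic grids, cohort fixtures, oracles."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from dmnconnect import BoldSeries, default_affine, ellipsoid_mask
from dmnconnect import synth


def spatial_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two 3D images over a mask."""
    x, y = np.asarray(a)[mask], np.asarray(b)[mask]
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))


def flood_fill_clusters(supra: np.ndarray, connectivity: int) -> list[int]:
    """Brute-force BFS connected-component sizes of a boolean 3D image.

    Independent oracle for the labelling used by cluster extraction.
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    supra = np.asarray(supra, dtype=bool)
    seen = np.zeros_like(supra)
    sizes = []
    for start in zip(*np.nonzero(supra)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < supra.shape[0] and 0 <= p[1] < supra.shape[1]
                        and 0 <= p[2] < supra.shape[2]
                        and supra[p] and not seen[p]):
                    seen[p] = True
                    queue.append(p)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def make_series(data: np.ndarray, tr_s: float = 2.0,
                mask: np.ndarray | None = None,
                voxel_mm: float = 3.0) -> BoldSeries:
    """Wrap a 4D array as a BoldSeries with an all-true mask by default."""
    data = np.asarray(data, dtype=np.float64)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    affine = default_affine((voxel_mm,) * 3, data.shape[:3])
    return BoldSeries(data=data, affine=affine, tr_s=tr_s, mask=mask)


@pytest.fixture(scope="session")
def networks():
    """Default planted-network layout on the standard analysis grid."""
    return synth.make_network_maps(seed=3)


@pytest.fixture(scope="session")
def default_subject(networks):
    """One simulated control subject at default conditions."""
    return synth.synthesize_subject(networks, None, "B", seed=2024)


@pytest.fixture(scope="session")
def small_networks():
    """A 3-network layout on a reduced grid for fast end-to-end tests."""
    return synth.make_network_maps(grid_dims=(18, 20, 18), n_networks=3,
                                   seed=11)


@pytest.fixture(scope="session")
def analysis_mask():
    return ellipsoid_mask((30, 36, 30))
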