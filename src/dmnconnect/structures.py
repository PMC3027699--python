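"""Shared data containers for the DMN connectivity pipeline.

All spatial images live on a single common voxel grid with a fixed
voxel-to-world affine; the world axes follow the radiological-report
convention X left→right, Y posterior→anterior, Z inferior→superior.
Voxel indices are 0-based internally; world coordinates are mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np


def default_affine(voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
                   shape: tuple[int, int, int] = (30, 36, 30)) -> np.ndarray:
    """RAS+ affine with the world origin at the grid centre."""
    aff = np.eye(4)
    for i, v in enumerate(voxel_mm):
        aff[i, i] = v
        aff[i, 3] = -v * (shape[i] - 1) / 2.0
    return aff


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths (mm) from an affine, sign-free."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class BoldSeries:
    """One participant's 4D BOLD time series.

    data   : (x, y, z, t) float array
    affine : 4x4 voxel-to-world map (mm)
    tr_s   : repetition time in seconds
    mask   : (x, y, z) boolean brain mask on the same grid
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldSeries.data must be 4D (x,y,z,t); got {self.data.ndim} axes")
        if self.data.shape[3] < 2:
            raise ValueError("BoldSeries needs at least 2 time points")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != data grid {self.data.shape[:3]}")
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def masked(self) -> np.ndarray:
        """Masked series as a (t, n_voxels) matrix."""
        return self.data[self.mask].T

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return dataclasses.replace(self, data=data)


@dataclass
class NuisanceDesign:
    """Confound regressors (t x k), intercept added implicitly."""

    regressors: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a t x k table")
        if self.names is None:
            self.names = [f"reg{i}" for i in range(self.regressors.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]

    def with_intercept(self) -> np.ndarray:
        t = self.n_frames
        return np.column_stack([np.ones(t), self.regressors])


@dataclass
class ComponentSet:
    """Spatial ICA result: z-scored maps plus time courses.

    maps    : (n_comp, x, y, z) z-score images, zero outside the mask
    courses : (t, n_comp) component time courses
    """

    maps: np.ndarray
    courses: np.ndarray
    mask: np.ndarray
    n_requested: int
    n_realized: int
    explained_variance: float
    convergence_log: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_vectors(self) -> np.ndarray:
        """(n_comp, n_mask_voxels) view of the maps inside the mask."""
        return self.maps[:, self.mask]


@dataclass
class TemplateMap:
    """Binary group-level network template used for goodness-of-fit."""

    voxels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.voxels.sum())


@dataclass
class FitResult:
    """Goodness-of-fit ranking of one subject's components."""

    scores: np.ndarray
    best_index: int
    second_index: int
    tie_broken: bool = False


@dataclass
class StatMap:
    """Voxel-wise t-statistic image with its degrees of freedom."""

    values: np.ndarray
    df: int
    sided: str
    mask: np.ndarray
    flagged_zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


@dataclass
class McThresholdResult:
    """Monte-Carlo cluster-extent calibration result."""

    min_cluster_vox: int
    alpha_achieved: float
    n_iterations: int
    max_cluster_null: np.ndarray
    seed: int
    note: str = ""


@dataclass
class NetworkSpec:
    """Planted coherent networks: nonnegative spatial weights on one grid."""

    component_maps: np.ndarray        # (n_networks, x, y, z), nonnegative
    mask: np.ndarray                  # brain mask
    affine: np.ndarray
    band: tuple[float, float] = (0.01, 0.08)
    amplitudes: np.ndarray | None = None
    dmn_index: int = 0
    lobe_labels: np.ndarray | None = None   # int image: lobe id of DMN map

    def __post_init__(self) -> None:
        if self.amplitudes is None:
            self.amplitudes = np.ones(self.component_maps.shape[0])

    @property
    def n_networks(self) -> int:
        return self.component_maps.shape[0]


@dataclass
class GroupEffectSpec:
    """Planted group difference: per-region sign and fractional magnitude."""

    target_regions: dict[str, np.ndarray]   # name -> boolean voxel image
    direction: dict[str, int]               # name -> +1 / -1
    magnitude: float = 0.5

    def __post_init__(self) -> None:
        names = list(self.target_regions)
        for name in names:
            if self.direction.get(name) not in (1, -1):
                raise ValueError(f"direction for region '{name}' must be +1 or -1")
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if (self.target_regions[a] & self.target_regions[b]).any():
                    raise ValueError(f"target regions '{a}' and '{b}' overlap")


@dataclass
class SubjectSim:
    """One simulated participant with its generative ground truth."""

    subject_id: str
    cohort: str
    series: np.ndarray                # (x, y, z, t)
    motion_regressors: np.ndarray     # (t, 6)
    ground_truth_index: int
    ground_truth_map: np.ndarray      # subject-level DMN weight image
    seed: int
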