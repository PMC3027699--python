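"""Synthetic resting-state cohorts with planted coherent networks.

The generative model is the one spatial ICA assumes: each voxel's BOLD
series is a linear mixture of a few spatially fixed network maps driven by
band-limited (0.01-0.08 Hz) temporally coherent fluctuations, plus
motion-correlated drift and white Gaussian noise,

    y(x, t) = sum_k a_k * w_s,k * M_k(x) * c_k(t)
            + sum_j g_j(x) * m_j(t) + eps(x, t),

with per-subject multiplicative weight jitter w_s,k ~ N(1, 0.1) so that
between-subject statistics are non-degenerate. One designated "DMN-like"
map is a union of several disjoint lobes (posterior-cingulate-, medial-
prefrontal-, parietal-, hippocampus-, dACC- and caudate-like nodes); group
effects scale the DMN map inside named target regions by (1 +/- magnitude)
in cohort A only.

The default cohort design mirrors a two-group resting-state study:
14 vs 13 participants, 180 frames at TR = 2 s (a six-minute run), a
30x36x30 grid at nominal 3 mm isotropic voxels.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from . import fileio
from .structures import (BoldSeries, GroupEffectSpec, NetworkSpec, SubjectSim,
                         default_affine)

DEFAULT_GRID = (30, 36, 30)
DEFAULT_N_FRAMES = 180
DEFAULT_TR_S = 2.0
DEFAULT_BAND = (0.01, 0.08)
DEFAULT_NOISE_SD = 2.0
SUBJECT_JITTER_SD = 0.10
MOTION_LEAK_GAIN = 0.30     # leak SD per motion regressor, x noise_sd
MOTION_GAIN_MODULATION = 0.25   # relative spatial variation of the leak gain

# Lobe layout in per-axis grid fractions (x L->R, y P->A, z I->S) with
# per-lobe Gaussian widths in voxels.  The DMN-like map unions the first
# seven; the three starred lobes double as group-effect target regions.
_DMN_LOBES = [
    ("pcc", (0.50, 0.30, 0.60), 3.0),
    ("mpfc", (0.50, 0.80, 0.52), 2.6),
    ("l-parietal", (0.20, 0.38, 0.68), 2.2),
    ("r-parietal", (0.80, 0.38, 0.68), 2.2),
    ("hippocampus-like", (0.72, 0.44, 0.26), 1.9),   # *
    ("dacc-like", (0.50, 0.62, 0.78), 1.8),          # *
    ("caudate-like", (0.33, 0.57, 0.44), 1.8),       # *
]
_OTHER_NETWORKS = [
    [("visual", (0.46, 0.10, 0.42), 3.0), ("r-occipital", (0.74, 0.16, 0.62), 2.6)],
    [("l-motor", (0.28, 0.58, 0.88), 2.8), ("r-motor", (0.72, 0.58, 0.88), 2.8)],
    [("l-temporal", (0.12, 0.52, 0.36), 2.8), ("r-temporal", (0.88, 0.68, 0.40), 2.8)],
    [("cerebellar", (0.40, 0.22, 0.20), 2.8), ("r-cerebellar", (0.66, 0.18, 0.30), 2.4)],
    [("l-frontal", (0.18, 0.80, 0.55), 2.6), ("r-insula", (0.84, 0.48, 0.60), 2.6)],
    [("thalamic", (0.50, 0.44, 0.36), 2.2)],
    [("l-occipital", (0.26, 0.12, 0.64), 2.2)],
]
TARGET_REGION_DIRECTIONS = {"hippocampus-like": 1, "dacc-like": -1,
                            "caudate-like": -1}


def ellipsoid_mask(grid_dims: tuple[int, int, int] = DEFAULT_GRID,
                   margin: float = 1.5) -> np.ndarray:
    """Brain-like ellipsoid mask inscribed in the grid."""
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in grid_dims],
                         indexing="ij")
    q = np.zeros(grid_dims)
    for c, s in zip(coords, grid_dims):
        centre, radius = (s - 1) / 2.0, s / 2.0 - margin
        q += ((c - centre) / radius) ** 2
    return q <= 1.0


def _gaussian_blob(grid_dims, centre_vox, sigma_vox) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in grid_dims],
                         indexing="ij")
    q = sum(((c - mu) ** 2) for c, mu in zip(coords, centre_vox))
    return np.exp(-q / (2.0 * sigma_vox ** 2))


def make_network_maps(grid_dims: tuple[int, int, int] = DEFAULT_GRID,
                      n_networks: int = 5,
                      seed: int = 0) -> NetworkSpec:
    """Generate smooth, spatially distinct network weight maps.

    Map 0 is the DMN-like network: a union of >= 4 disjoint lobes.  Lobe
    centres receive a small seeded jitter (< 1 voxel) and widths a +/-10%
    jitter, so different seeds give different but layout-compatible maps.
    Pairwise spatial correlation between maps stays below 0.2 because the
    lobes occupy separated sub-regions of the mask.
    """
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2 (one DMN-like plus noise networks)")
    if n_networks > 1 + len(_OTHER_NETWORKS):
        raise ValueError(
            f"at most {1 + len(_OTHER_NETWORKS)} distinct networks supported")
    if min(grid_dims) < 16:
        raise ValueError(
            f"grid {grid_dims} too small to hold {n_networks} disjoint networks; "
            "each axis must span >= 16 voxels")

    rng = np.random.default_rng(seed)
    mask = ellipsoid_mask(grid_dims)
    scale = min(grid_dims) / 30.0     # widths specified at the reference grid

    def render(lobes):
        img = np.zeros(grid_dims)
        centres = {}
        for name, frac, sigma in lobes:
            centre = np.array([f * (s - 1) for f, s in zip(frac, grid_dims)])
            centre = centre + rng.uniform(-0.5, 0.5, size=3)
            sig = sigma * scale * (1.0 + rng.uniform(-0.1, 0.1))
            img += _gaussian_blob(grid_dims, centre, sig)
            centres[name] = (centre, sig)
        img *= mask
        return img / img.max(), centres

    dmn_map, dmn_centres = render(_DMN_LOBES)
    maps = [dmn_map]
    for spec in _OTHER_NETWORKS[: n_networks - 1]:
        img, _ = render(spec)
        maps.append(img)
    maps = np.stack(maps)

    # lobe label image: nearest target lobe core, used to carve effect regions
    labels = np.zeros(grid_dims, dtype=np.int16)
    for i, (name, _, _) in enumerate(_DMN_LOBES, start=1):
        centre, sig = dmn_centres[name]
        lobe = _gaussian_blob(grid_dims, centre, sig) * mask
        labels[lobe > 0.5] = i

    amplitudes = np.full(n_networks, 1.1)
    amplitudes[0] = 1.2
    return NetworkSpec(component_maps=maps, mask=mask,
                       affine=default_affine(shape=grid_dims),
                       band=DEFAULT_BAND, amplitudes=amplitudes,
                       dmn_index=0, lobe_labels=labels)


def default_effect(networks: NetworkSpec,
                   magnitude: float = 0.5) -> GroupEffectSpec:
    """Planted group difference in three DMN sub-regions.

    Cohort A gains hippocampus-like connectivity and loses dACC-like and
    caudate-like connectivity, each by the given fractional magnitude.
    """
    if networks.lobe_labels is None:
        raise ValueError("networks carry no lobe labels; use make_network_maps")
    names = [name for name, _, _ in _DMN_LOBES]
    regions = {}
    for name in TARGET_REGION_DIRECTIONS:
        lobe_id = names.index(name) + 1
        region = networks.lobe_labels == lobe_id
        if not region.any():
            raise ValueError(f"target region '{name}' is empty on this grid")
        regions[name] = region
    return GroupEffectSpec(target_regions=regions,
                           direction=dict(TARGET_REGION_DIRECTIONS),
                           magnitude=magnitude)


def make_timecourses(n_frames: int, tr_s: float,
                     band: tuple[float, float], n_networks: int,
                     seed: int) -> np.ndarray:
    """Band-limited, mutually orthogonal, unit-variance time courses.

    White Gaussian noise is hard band-passed in the Fourier domain, then
    QR-orthogonalised (linear combinations of band-limited signals remain
    band-limited) and scaled to unit sample SD.  Returns (t, n_networks).
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 <= low < high < nyquist):
        raise ValueError(
            f"band [{low}, {high}] Hz must satisfy 0 <= low < high < "
            f"Nyquist {nyquist:g} Hz at TR {tr_s} s")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_frames, n_networks))
    freqs = np.fft.rfftfreq(n_frames, tr_s)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if keep.sum() < n_networks:
        raise ValueError(
            f"only {int(keep.sum())} Fourier bins in band; cannot build "
            f"{n_networks} orthogonal courses")
    spectrum = np.fft.rfft(white, axis=0)
    spectrum[~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n_frames, axis=0)
    q, _ = np.linalg.qr(filtered)
    return q / q.std(axis=0, ddof=1)


def _motion_walks(n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Six smooth random walks: 3 translations (mm) and 3 rotations (deg)."""
    steps = rng.standard_normal((n_frames, 6)) * 0.02
    walks = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    for j in range(6):
        walks[:, j] = np.convolve(walks[:, j], kernel, mode="same")
    return walks


def synthesize_subject(networks: NetworkSpec,
                       effect: GroupEffectSpec | None,
                       cohort: str,
                       noise_sd: float = DEFAULT_NOISE_SD,
                       seed: int = 0,
                       n_frames: int = DEFAULT_N_FRAMES,
                       tr_s: float = DEFAULT_TR_S,
                       subject_id: str = "sub-00") -> SubjectSim:
    """Simulate one participant's 4D series and motion table.

    The planted group effect applies to cohort ``"A"`` only: inside each
    target region the DMN-like map is scaled by (1 + direction*magnitude).
    Motion leakage and noise both scale with ``noise_sd``, so the
    noiseless limit is an exact low-rank mixture.
    """
    rng = np.random.default_rng(seed)
    grid = networks.component_maps.shape[1:]
    n_net = networks.n_networks

    courses = make_timecourses(n_frames, tr_s, networks.band, n_net,
                               seed=int(rng.integers(2 ** 31)))
    jitter = 1.0 + rng.normal(0.0, SUBJECT_JITTER_SD, size=n_net)
    jitter = np.clip(jitter, 0.5, None)

    maps = networks.component_maps.copy()
    if effect is not None and cohort == "A":
        dmn = maps[networks.dmn_index].copy()
        for name, region in effect.target_regions.items():
            dmn[region] *= 1.0 + effect.direction[name] * effect.magnitude
        maps[networks.dmn_index] = dmn
    truth = maps[networks.dmn_index].copy()

    weights = (networks.amplitudes * jitter).astype(np.float32)
    mixing = (maps.reshape(n_net, -1).astype(np.float32).T * weights)
    series = (mixing @ courses.T.astype(np.float32)).reshape(grid + (n_frames,))

    motion = _motion_walks(n_frames, rng)
    if noise_sd > 0:
        # motion-correlated drift: near-uniform gain per regressor with a
        # smooth, mild spatial modulation; dominates the background
        # variance, exactly as scanner drift and residual motion do, and
        # is removed by nuisance regression
        m_std = (motion - motion.mean(axis=0)) / motion.std(axis=0, ddof=1)
        from scipy import ndimage
        for j in range(6):
            field = ndimage.gaussian_filter(rng.standard_normal(grid), 3.0)
            field /= field.std()
            sign = rng.choice([-1.0, 1.0])
            gain = (MOTION_LEAK_GAIN * noise_sd * sign
                    * (1.0 + MOTION_GAIN_MODULATION * field))
            series += gain.astype(np.float32)[..., None] * \
                m_std[:, j].astype(np.float32)
        noise = rng.standard_normal(series.shape, dtype=np.float32)
        series += noise * np.float32(noise_sd)

    if not np.isfinite(series).all():
        raise FloatingPointError("simulated series contains non-finite values")
    return SubjectSim(subject_id=subject_id, cohort=cohort, series=series,
                      motion_regressors=motion,
                      ground_truth_index=networks.dmn_index,
                      ground_truth_map=truth, seed=seed)


def subject_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def synthesize_cohorts(n_a: int = 14, n_b: int = 13,
                       networks: NetworkSpec | None = None,
                       effect: GroupEffectSpec | None = None,
                       seed: int = 0,
                       out_dir: str | os.PathLike | None = None,
                       noise_sd: float = DEFAULT_NOISE_SD,
                       n_frames: int = DEFAULT_N_FRAMES,
                       tr_s: float = DEFAULT_TR_S,
                       ) -> tuple[list[SubjectSim], dict[str, str]]:
    """Simulate a two-cohort study; optionally write it to disk.

    Returns the subjects plus a manifest (flat key-value entries).  With
    ``out_dir`` set, per-subject 4D NIfTI series, headerless motion TSVs,
    the brain mask, the ground-truth DMN map/region labels and the
    manifest are written there.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each cohort needs at least 2 subjects")
    if networks is None:
        networks = make_network_maps(seed=seed)
    seeds = subject_seeds(seed, n_a + n_b)

    subjects: list[SubjectSim] = []
    manifest: dict[str, str] = {
        "master_seed": str(seed),
        "n_subjects": str(n_a + n_b),
        "n_a": str(n_a),
        "n_b": str(n_b),
        "tr_s": str(tr_s),
        "n_frames": str(n_frames),
        "dmn_component": str(networks.dmn_index),
        "grid": "x".join(str(s) for s in networks.component_maps.shape[1:]),
        "mask_file": "mask.nii.gz",
        "dmn_map_file": "dmn_truth.nii.gz",
        "region_labels_file": "region_labels.nii.gz",
    }
    for i, sub_seed in enumerate(seeds):
        cohort = "A" if i < n_a else "B"
        sid = f"sub-{cohort}{(i if cohort == 'A' else i - n_a) + 1:02d}"
        sub = synthesize_subject(networks, effect, cohort, noise_sd=noise_sd,
                                 seed=sub_seed, n_frames=n_frames, tr_s=tr_s,
                                 subject_id=sid)
        subjects.append(sub)
        manifest[f"subject.{sid}.cohort"] = cohort
        manifest[f"subject.{sid}.seed"] = str(sub_seed)
        manifest[f"subject.{sid}.gt_component"] = str(sub.ground_truth_index)
        manifest[f"subject.{sid}.series"] = f"{sid}.nii.gz"
        manifest[f"subject.{sid}.motion"] = f"{sid}_motion.tsv"

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            fileio.write_volume(out / "mask.nii.gz",
                                networks.mask.astype(np.float32),
                                networks.affine)
            fileio.write_volume(out / "dmn_truth.nii.gz",
                                networks.component_maps[networks.dmn_index],
                                networks.affine)
            if networks.lobe_labels is not None:
                fileio.write_volume(out / "region_labels.nii.gz",
                                    networks.lobe_labels.astype(np.float32),
                                    networks.affine)
            for sub in subjects:
                bold = BoldSeries(data=sub.series, affine=networks.affine,
                                  tr_s=tr_s, mask=networks.mask)
                fileio.write_series(out / f"{sub.subject_id}.nii.gz", bold)
                fileio.write_tsv(out / f"{sub.subject_id}_motion.tsv",
                                 sub.motion_regressors)
            fileio.write_keyvalue(out / "manifest.txt", manifest)
        except OSError as exc:
            raise OSError(f"failed writing cohort to {out}: {exc}") from exc

    return subjects, manifest
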