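"""End-to-end orchestration: configuration, pipeline wiring, run records.

Stage order is fixed: preprocess -> spatial ICA -> pooled template ->
per-subject best-fit selection -> group inference -> report.  Every
stochastic stage takes an explicit seed from the configuration; a run
with an identical configuration on identical inputs reproduces identical
output checksums, which the run record captures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import fileio, ica, inference, preprocess, synth, template
from .structures import (BoldSeries, ComponentSet, NuisanceDesign, StatMap,
                         TemplateMap, voxel_sizes)

logger = logging.getLogger("dmnconnect.runner")


@dataclass
class PipelineConfig:
    """All stage parameters, serializable as flat dotted-key text."""

    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    smooth_fwhm_mm: float = 6.0
    smooth_mode: str = "constant"
    normalize_mode: str = "zscore"
    ica_n_components: int = 25
    ica_max_attempts: int = 9
    ica_tol: float = 1e-4
    ica_max_iter: int = 500
    voxel_p: float = 0.005
    alpha: float = 0.05
    connectivity: int = 6
    mc_n_iter: int = 1000
    template_min_cluster_vox: int | None = None   # override skips template MC
    group_a: str = "A"
    group_b: str = "B"
    seed_ica: int | None = None
    seed_mc: int | None = None

    _KEYS = {
        "band_low_hz": "band.low_hz", "band_high_hz": "band.high_hz",
        "smooth_fwhm_mm": "smooth.fwhm_mm", "smooth_mode": "smooth.mode",
        "normalize_mode": "normalize.mode",
        "ica_n_components": "ica.n_components",
        "ica_max_attempts": "ica.max_attempts", "ica_tol": "ica.tol",
        "ica_max_iter": "ica.max_iter",
        "voxel_p": "stats.voxel_p", "alpha": "stats.alpha",
        "connectivity": "stats.connectivity", "mc_n_iter": "mc.n_iter",
        "template_min_cluster_vox": "template.min_cluster_vox",
        "group_a": "groups.a", "group_b": "groups.b",
        "seed_ica": "seed.ica", "seed_mc": "seed.mc",
    }

    def validate(self) -> None:
        if self.seed_ica is None or self.seed_mc is None:
            raise ValueError(
                "configuration must set explicit seeds (seed.ica, seed.mc) "
                "before any computation")
        if not (0 <= self.band_low_hz < self.band_high_hz):
            raise ValueError("band must satisfy 0 <= low < high")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_entries(self) -> dict[str, str]:
        out = {}
        for f in dataclasses.fields(self):
            key = self._KEYS[f.name]
            val = getattr(self, f.name)
            out[key] = "" if val is None else str(val)
        return out

    @classmethod
    def from_entries(cls, entries: dict[str, str]) -> "PipelineConfig":
        inv = {v: k for k, v in cls._KEYS.items()}
        kwargs: dict[str, Any] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, raw in entries.items():
            if key not in inv:
                raise ValueError(f"unknown configuration key {key!r}")
            name = inv[key]
            if raw == "":
                kwargs[name] = None
                continue
            t = types[name]
            if t.startswith("int"):
                kwargs[name] = int(raw)
            elif t.startswith("float"):
                kwargs[name] = float(raw)
            else:
                kwargs[name] = raw
        return cls(**kwargs)

    def save(self, path: str | os.PathLike) -> None:
        fileio.write_keyvalue(path, self.to_entries())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PipelineConfig":
        return cls.from_entries(fileio.read_keyvalue(path))

    def digest(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in sorted(self.to_entries().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config_hash: str
    checksums: dict[str, str] = field(default_factory=dict)
    realized_orders: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    complete: bool = False

    def add_checksum(self, name: str, array: np.ndarray) -> None:
        data = np.ascontiguousarray(np.asarray(array, dtype=np.float64))
        self.checksums[name] = hashlib.sha256(data.tobytes()).hexdigest()[:16]

    def to_entries(self) -> dict[str, str]:
        out = {"config_hash": self.config_hash,
               "complete": str(self.complete)}
        for k, v in self.checksums.items():
            out[f"checksum.{k}"] = v
        for k, v in self.realized_orders.items():
            out[f"realized_order.{k}"] = str(v)
        for i, w in enumerate(self.warnings):
            out[f"warning.{i}"] = w
        return out


class PipelineError(RuntimeError):
    """Stage failure carrying the stage, subject, and partial run record."""

    def __init__(self, stage: str, subject: str | None, cause: Exception,
                 record: RunRecord):
        self.stage, self.subject, self.record = stage, subject, record
        where = f"stage '{stage}'" + (f", subject '{subject}'" if subject else "")
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass
class CohortResult:
    """Everything the group analysis produces for one cohort dataset."""

    fit_table: pd.DataFrame
    best_maps: dict[str, np.ndarray]
    cohorts: dict[str, str]
    template: TemplateMap
    template_mc: inference.McThresholdResult | None
    group_stat: dict[str, StatMap]
    group_masks: dict[str, np.ndarray]
    or_mask: np.ndarray
    two_sample_stat: StatMap
    two_sample_mc: inference.McThresholdResult
    cluster_table: pd.DataFrame
    record: RunRecord


def preprocess_subject(series: BoldSeries, motion: np.ndarray,
                       config: PipelineConfig) -> BoldSeries:
    design = NuisanceDesign(regressors=motion,
                            names=[f"motion{i}" for i in range(
                                np.atleast_2d(motion).shape[1])])
    return preprocess.preprocess_series(
        series, design, fwhm_mm=config.smooth_fwhm_mm,
        band=(config.band_low_hz, config.band_high_hz),
        normalize_mode=config.normalize_mode, smooth_mode=config.smooth_mode)


def analyze_cohort(subjects: Iterable[synth.SubjectSim],
                   mask: np.ndarray, affine: np.ndarray, tr_s: float,
                   config: PipelineConfig,
                   prior_map: np.ndarray) -> CohortResult:
    """Run the full analysis on in-memory subjects.

    ``prior_map`` drives the bootstrap candidate selection (the
    simulator's ground-truth network map, or a prior mask on real data).
    Subjects are consumed lazily: each series is preprocessed and
    decomposed, then released.
    """
    config.validate()
    record = RunRecord(config_hash=config.digest())
    mask = np.asarray(mask, dtype=bool)
    vox_mm = tuple(voxel_sizes(affine))

    candidate_maps: list[np.ndarray] = []
    component_sets: dict[str, ComponentSet] = {}
    cohorts: dict[str, str] = {}
    sub_ids: list[str] = []
    for i, sub in enumerate(subjects):
        sid = sub.subject_id
        sub_ids.append(sid)
        cohorts[sid] = sub.cohort
        try:
            bold = BoldSeries(data=sub.series, affine=affine, tr_s=tr_s,
                              mask=mask)
            clean = preprocess_subject(bold, sub.motion_regressors, config)
        except Exception as exc:
            raise PipelineError("preprocess", sid, exc, record) from exc
        try:
            seed = synth.subject_seeds(config.seed_ica, i + 1)[-1]
            comp = ica.spatial_ica(clean, config.ica_n_components, seed=seed,
                                   max_attempts=config.ica_max_attempts,
                                   tol=config.ica_tol,
                                   max_iter=config.ica_max_iter)
        except Exception as exc:
            raise PipelineError("ica", sid, exc, record) from exc
        component_sets[sid] = comp
        record.realized_orders[sid] = comp.n_realized
        if comp.n_realized != comp.n_requested:
            record.warnings.append(
                f"{sid}: realized model order {comp.n_realized} != "
                f"requested {comp.n_requested}")
        cand = template.select_candidate_by_correlation(comp, prior_map)
        candidate_maps.append(comp.maps[cand])

    try:
        pooled_t = template.one_sample_t_map(candidate_maps, mask)
        if config.template_min_cluster_vox is not None:
            extent, template_mc = config.template_min_cluster_vox, None
        else:
            template_mc = inference.monte_carlo_cluster_threshold(
                mask, fwhm_mm=config.smooth_fwhm_mm, voxel_p=config.voxel_p,
                alpha=config.alpha, sided="one", n_iter=config.mc_n_iter,
                connectivity=config.connectivity, seed=config.seed_mc,
                voxel_mm=vox_mm)
            extent = template_mc.min_cluster_vox
        dmn_template = template.build_template(
            pooled_t, voxel_p=config.voxel_p, min_cluster_vox=extent,
            connectivity=config.connectivity)
        if dmn_template.size == 0:
            record.warnings.append("empty DMN template")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("template", None, exc, record) from exc

    fit_rows, best_maps = [], {}
    for sid in sub_ids:
        try:
            fit = template.select_best_fit(component_sets[sid], dmn_template)
        except Exception as exc:
            raise PipelineError("select", sid, exc, record) from exc
        best_maps[sid] = component_sets[sid].maps[fit.best_index]
        for rank, comp_idx in enumerate(
                np.lexsort((np.arange(len(fit.scores)), -fit.scores))):
            fit_rows.append({"subject": sid, "cohort": cohorts[sid],
                             "component": int(comp_idx), "rank": rank + 1,
                             "score": float(fit.scores[comp_idx])})
    fit_table = pd.DataFrame(fit_rows)

    try:
        a_ids = [s for s in sub_ids if cohorts[s] == config.group_a]
        b_ids = [s for s in sub_ids if cohorts[s] == config.group_b]
        maps_a = np.array([best_maps[s] for s in a_ids])
        maps_b = np.array([best_maps[s] for s in b_ids])
        group_stat, group_masks = {}, {}
        for label, maps in ((config.group_a, maps_a), (config.group_b, maps_b)):
            gstat = template.one_sample_t_map(maps, mask)
            gtmpl = template.build_template(
                gstat, voxel_p=config.voxel_p, min_cluster_vox=extent,
                connectivity=config.connectivity)
            group_stat[label] = gstat
            group_masks[label] = gtmpl.voxels
        union = inference.or_mask(group_masks[config.group_a],
                                  group_masks[config.group_b])
        if not union.any():
            record.warnings.append("empty OR mask; two-sample test skipped")
            union = mask  # degenerate fallback, flagged above
        tstat = inference.two_sample_t_map(maps_a, maps_b, union)
        two_mc = inference.monte_carlo_cluster_threshold(
            union, fwhm_mm=config.smooth_fwhm_mm, voxel_p=config.voxel_p,
            alpha=config.alpha, sided="two", n_iter=config.mc_n_iter,
            connectivity=config.connectivity, seed=config.seed_mc + 1,
            voxel_mm=vox_mm)
        clusters = inference.extract_clusters(
            tstat, voxel_p=config.voxel_p,
            min_cluster_vox=two_mc.min_cluster_vox,
            connectivity=config.connectivity,
            subject_maps_by_group={config.group_a: maps_a,
                                   config.group_b: maps_b},
            affine=affine)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inference", None, exc, record) from exc

    record.add_checksum("template", dmn_template.voxels)
    record.add_checksum("two_sample_t", tstat.values)
    for sid in sub_ids:
        record.add_checksum(f"best_map.{sid}", best_maps[sid])
    record.complete = True
    return CohortResult(fit_table=fit_table, best_maps=best_maps,
                        cohorts=cohorts, template=dmn_template,
                        template_mc=template_mc, group_stat=group_stat,
                        group_masks=group_masks, or_mask=union,
                        two_sample_stat=tstat, two_sample_mc=two_mc,
                        cluster_table=clusters, record=record)


def _iter_manifest_subjects(data_dir: Path, manifest: dict[str, str],
                            mask: np.ndarray, tr_s: float):
    sids = sorted({k.split(".")[1] for k in manifest if k.startswith("subject.")})
    for sid in sids:
        series_file = data_dir / manifest[f"subject.{sid}.series"]
        motion_file = data_dir / manifest[f"subject.{sid}.motion"]
        bold = fileio.read_series(series_file, mask, tr_s=tr_s)
        motion = fileio.read_tsv(motion_file)
        yield synth.SubjectSim(
            subject_id=sid, cohort=manifest[f"subject.{sid}.cohort"],
            series=bold.data, motion_regressors=motion,
            ground_truth_index=int(manifest.get(
                f"subject.{sid}.gt_component", -1)),
            ground_truth_map=np.zeros(mask.shape),
            seed=int(manifest.get(f"subject.{sid}.seed", 0)))


def run_pipeline(config: PipelineConfig, data_dir: str | os.PathLike,
                 out_dir: str | os.PathLike) -> CohortResult:
    """Run the full pipeline on an on-disk dataset and write all outputs."""
    config.validate()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    manifest = fileio.read_keyvalue(data_dir / "manifest.txt")
    mask, affine = fileio.read_volume(data_dir / manifest["mask_file"])
    mask = mask > 0.5
    tr_s = float(manifest.get("tr_s", 2.0))
    prior, _ = fileio.read_volume(data_dir / manifest["dmn_map_file"])

    result = analyze_cohort(
        _iter_manifest_subjects(data_dir, manifest, mask, tr_s),
        mask, affine, tr_s, config, prior_map=prior)

    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "config.txt")
    fileio.write_volume(out_dir / "template.nii.gz",
                        result.template.voxels.astype(np.float32), affine)
    fileio.write_volume(out_dir / "two_sample_t.nii.gz",
                        result.two_sample_stat.values, affine)
    fileio.write_volume(out_dir / "or_mask.nii.gz",
                        result.or_mask.astype(np.float32), affine)
    labels = inference.cluster_label_image(
        result.two_sample_stat, config.voxel_p,
        result.two_sample_mc.min_cluster_vox, config.connectivity)
    fileio.write_volume(out_dir / "cluster_labels.nii.gz",
                        labels.astype(np.float32), affine)
    result.fit_table.to_csv(out_dir / "fit_scores.tsv", sep="\t", index=False)
    result.cluster_table.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    fileio.write_keyvalue(out_dir / "run_record.txt",
                          result.record.to_entries())
    logger.info("pipeline complete: %d clusters, template %d voxels",
                len(result.cluster_table), result.template.size)
    return result
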