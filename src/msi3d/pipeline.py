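"""Workflow orchestration: configuration, logging, staged execution.

Stages run in dependency order (simulate -> preprocess -> peaks -> segment /
stats / register -> volume -> annotate); every stage writes its artifacts
under ``<outdir>/<stage>/`` together with a ``manifest.json`` recording the
stage parameters, derived seed, inputs and package version, so a run is
reproducible and individually re-runnable. A single global seed fans out to
per-stage seeds by stable hashing of the stage name, which keeps stages
independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DependencyError, InputError
from .io import (
    MSIStudy,
    export_feature_matrix,
    read_imzml,
    write_imzml,
    write_mask_tiff,
    write_volume_tiff,
)
from .annotate import assignments_to_frame, load_candidates, match_peaks
from .peakpick import FeatureMatrix, PeakList, align_to_mean, detect_peaks_omp, section_key
from .phantom import PhantomConfig, generate_study
from .preprocess import PreprocessParams, mean_spectrum, preprocess_study
from .segment import bisecting_kmeans, cut_tree, label_maps
from .stats import (
    balanced_subsample,
    correlation_to_frame,
    group_intensity_summary,
    pearson_colocalization,
    roc_discriminative,
    roc_to_frame,
)
from .volume3d import (
    apply_transform,
    build_volume,
    register_stack,
    transforms_to_frame,
)

logger = logging.getLogger("msi3d")

STAGES = ("simulate", "preprocess", "peaks", "segment", "stats", "register", "volume", "annotate")

#: upstream stage whose artifacts each stage needs
REQUIRES = {
    "simulate": None,
    "preprocess": "simulate",
    "peaks": "preprocess",
    "segment": "peaks",
    "stats": "peaks",
    "register": "preprocess",
    "volume": "register",
    "annotate": "peaks",
}


@dataclass
class PipelineConfig:
    """Nested per-stage parameter blocks plus global seed and output dir."""

    outdir: Path = Path("msi3d_out")
    seed: int = 0
    phantom: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    volume: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in PipelineConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(**raw)
        cfg.outdir = Path(cfg.outdir)
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + zlib.crc32(stage.encode())) % (2**31 - 1)


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    return config.outdir / stage


def _write_manifest(config: PipelineConfig, stage: str, params: dict, inputs: list, outputs: list):
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.stage_seed(stage),
        "params": params,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(Path(p).relative_to(config.outdir)) for p in outputs),
    }
    path = _stage_dir(config, stage) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _require(config: PipelineConfig, stage: str):
    upstream = REQUIRES[stage]
    if upstream and not (_stage_dir(config, upstream) / "manifest.json").exists():
        raise DependencyError(
            f"stage {stage!r} needs artifacts from {upstream!r}; run {upstream!r} first"
        )


def _load_study(config: PipelineConfig, stage: str) -> MSIStudy:
    sections = []
    for path in sorted(_stage_dir(config, stage).glob("*.imzML")):
        sections.extend(read_imzml(path))
    if not sections:
        raise DependencyError(f"no imzML artifacts under {_stage_dir(config, stage)}")
    return MSIStudy(sections)


def _load_features(config: PipelineConfig) -> FeatureMatrix:
    d = _stage_dir(config, "peaks")
    frame = pd.read_csv(d / "features.csv")
    meta = json.loads((d / "features.meta.json").read_text())
    key_cols = ["section", "timepoint_days", "segment", "z_index", "x", "y"]
    value_cols = [c for c in frame.columns if c not in key_cols]
    slices = {
        k: (slice(v["start"], v["stop"]), tuple(v["grid_shape"]))
        for k, v in meta["sections"].items()
    }
    return FeatureMatrix(
        values=frame[value_cols].to_numpy(),
        centers=np.array([float(c) for c in value_cols]),
        sigmas=np.array(meta["sigmas"]),
        keys=frame[key_cols],
        section_slices=slices,
    )


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _run_simulate(config: PipelineConfig):
    params = dict(config.phantom)
    params.setdefault("seed", config.stage_seed("simulate"))
    pcfg = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in params.items()})
    out = _stage_dir(config, "simulate")
    generate_study(pcfg, out_dir=out)
    outputs = sorted(out.rglob("*.imzML")) + [out / "ground_truth.json"]
    _write_manifest(config, "simulate", params, [], outputs)


def _run_preprocess(config: PipelineConfig):
    _require(config, "preprocess")
    params = dict(config.preprocess)
    study = _load_study(config, "simulate")
    processed = preprocess_study(study, PreprocessParams(**params))
    out = _stage_dir(config, "preprocess")
    outputs = []
    for (tp, seg), group in processed.groups():
        path = out / f"{tp}d_{seg}.imzML"
        write_imzml(group, path)
        outputs.append(path)
    mean = mean_spectrum(processed)
    mean_path = out / "mean_spectrum.csv"
    pd.DataFrame({"mz": processed.mz_axis, "intensity": mean}).to_csv(mean_path, index=False)
    outputs.append(mean_path)
    _write_manifest(config, "preprocess", params,
                    sorted(_stage_dir(config, "simulate").glob("*.imzML")), outputs)


def _run_peaks(config: PipelineConfig):
    _require(config, "peaks")
    params = dict(config.peaks)
    study = _load_study(config, "preprocess")
    mean = mean_spectrum(study)
    peaks = detect_peaks_omp(
        mean,
        study.mz_axis,
        max_peaks=params.get("max_peaks", 200),
        residual_fraction=params.get("residual_fraction", 0.01),
        width_model=tuple(params.get("width_model", (0.05, 1e-4))),
    )
    features = align_to_mean(study, peaks, params.get("match_tolerance_da"))
    out = _stage_dir(config, "peaks")
    out.mkdir(parents=True, exist_ok=True)
    peaks.to_frame().to_csv(out / "peaks.csv", index=False)
    export_feature_matrix(features, out / "features.csv")
    meta = {
        "sigmas": features.sigmas.tolist(),
        "sections": {
            k: {"start": sl.start, "stop": sl.stop, "grid_shape": list(shape)}
            for k, (sl, shape) in features.section_slices.items()
        },
    }
    (out / "features.meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    _write_manifest(config, "peaks", params,
                    sorted(_stage_dir(config, "preprocess").glob("*.imzML")),
                    [out / "peaks.csv", out / "features.csv"])


def _run_segment(config: PipelineConfig):
    _require(config, "segment")
    params = dict(config.segment)
    features = _load_features(config)
    tree = bisecting_kmeans(
        features,
        n_leaves=params.get("n_leaves", 4),
        seed=config.stage_seed("segment"),
        restarts=params.get("restarts", 10),
    )
    depth = params.get("depth", tree.height())
    labels = cut_tree(tree, depth)
    out = _stage_dir(config, "segment")
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.json").write_text(tree.to_json())
    outputs = [out / "tree.json"]
    for key, img in label_maps(features, labels).items():
        path = out / f"labels_{key}.tif"
        write_mask_tiff(img + 1, path)  # shift so off-tissue is 0
        outputs.append(path)
    _write_manifest(config, "segment", params, [config.outdir / "peaks" / "features.csv"], outputs)


def _run_stats(config: PipelineConfig):
    _require(config, "stats")
    params = dict(config.stats)
    features = _load_features(config)
    out = _stage_dir(config, "stats")
    out.mkdir(parents=True, exist_ok=True)
    outputs = []

    reference_mz = params.get("reference_mz")
    if reference_mz is not None:
        j = features.interval_index(float(reference_mz))
        results = pearson_colocalization(features, features.values[:, j])
        path = out / f"pearson_vs_{reference_mz}.csv"
        correlation_to_frame(results).to_csv(path, index=False)
        outputs.append(path)

    segments = features.keys["segment"].to_numpy()
    if {"L", "R1", "C1"}.issubset(set(segments)):
        l_idx = np.nonzero(segments == "L")[0]
        ref = balanced_subsample(
            np.nonzero(segments == "R1")[0],
            np.nonzero(segments == "C1")[0],
            n_target=min(l_idx.size, (segments == "R1").sum() + (segments == "C1").sum()),
            seed=config.stage_seed("stats"),
        )
        roc = roc_discriminative(features, l_idx, ref)
        path = out / "roc_L_vs_R1C1.csv"
        roc_to_frame(roc).to_csv(path, index=False)
        outputs.append(path)

    for grouping in ("timepoint_days", "segment"):
        if features.keys[grouping].nunique() > 1:
            rows = group_intensity_summary(
                features, grouping, params.get("ci_level", 0.95)
            )
            frame = pd.DataFrame(
                [
                    {
                        "group": r.group,
                        "center_mz": r.center_mz,
                        "mean": r.mean,
                        "sd": r.sd,
                        "ci_lower": r.ci_lower,
                        "ci_upper": r.ci_upper,
                        "n_outliers": len(r.outlier_rows),
                    }
                    for r in rows
                ]
            )
            path = out / f"summary_by_{grouping}.csv"
            frame.to_csv(path, index=False)
            outputs.append(path)
    _write_manifest(config, "stats", params, [config.outdir / "peaks" / "features.csv"], outputs)


def _run_register(config: PipelineConfig):
    _require(config, "register")
    study = _load_study(config, "preprocess")
    out = _stage_dir(config, "register")
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    for (tp, seg), group in study.groups():
        keys = [section_key(s) for s in group]
        transforms = register_stack([s.tic_image() for s in group])
        path = out / f"transforms_{tp}d_{seg}.csv"
        transforms_to_frame(keys, transforms).to_csv(path, index=False)
        outputs.append(path)
    _write_manifest(config, "register", {},
                    sorted(_stage_dir(config, "preprocess").glob("*.imzML")), outputs)


def _run_volume(config: PipelineConfig):
    _require(config, "volume")
    params = dict(config.volume)
    features = _load_features(config)
    from .volume3d import RigidTransform

    out = _stage_dir(config, "volume")
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    z_spacing = params.get("z_spacing_um", 204.0)
    intervals = params.get("intervals_mz", [400.3, 518.3])
    reg_dir = _stage_dir(config, "register")
    for path in sorted(reg_dir.glob("transforms_*.csv")):
        frame = pd.read_csv(path)
        keys = frame["section"].tolist()
        transforms = [
            RigidTransform(r["rotation_deg"], r["dx_px"], r["dy_px"])
            for _, r in frame.iterrows()
        ]
        for mz in intervals:
            try:
                j = features.interval_index(float(mz))
            except InputError:
                logger.warning("no detected interval near m/z %s; skipping", mz)
                continue
            images = [
                apply_transform(features.ion_image(k, j), t)
                for k, t in zip(keys, transforms)
            ]
            vol = build_volume(images, z_spacing, center_mz=float(mz), transforms=transforms)
            vpath = out / f"{path.stem.replace('transforms_', 'volume_')}_{mz}.tif"
            write_volume_tiff(vol.data, vpath)
            outputs.append(vpath)
    _write_manifest(config, "volume", params, sorted(reg_dir.glob("*.csv")), outputs)


def _run_annotate(config: PipelineConfig):
    _require(config, "annotate")
    params = dict(config.annotate)
    peaks = pd.read_csv(_stage_dir(config, "peaks") / "peaks.csv")
    candidates = load_candidates(params.get("candidates_csv"))
    assignments = match_peaks(
        peaks["center_mz"].to_numpy(), candidates, params.get("tolerance_da", 0.3)
    )
    out = _stage_dir(config, "annotate")
    out.mkdir(parents=True, exist_ok=True)
    path = out / "assignments.csv"
    assignments_to_frame(assignments).to_csv(path, index=False)
    _write_manifest(config, "annotate", params,
                    [config.outdir / "peaks" / "peaks.csv"], [path])


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "peaks": _run_peaks,
    "segment": _run_segment,
    "stats": _run_stats,
    "register": _run_register,
    "volume": _run_volume,
    "annotate": _run_annotate,
}


def run(config: PipelineConfig, stages=None) -> Path:
    """Execute the requested stages in dependency order; returns the outdir."""
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        _RUNNERS[stage](config)
        logger.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
    return config.outdir
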