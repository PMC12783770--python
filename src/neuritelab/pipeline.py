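"""One-config orchestration of simulate -> segment -> morphometry -> mea.

A pipeline run is described by a single YAML/JSON-style mapping with a
global seed, per-stage toggles and per-stage parameter blocks.  The
global seed is fanned out to every stochastic stage through fixed
offsets so one integer reproduces the whole run.  Each run writes a
manifest with the config hash, per-output SHA-256 checksums, stage
timings and seeds; deterministic stages reproduce identical checksums
for identical configs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as morph
from .light_response import AnalysisParams, dose_response
from .mea_sim import Recording, StimulusProtocol, generate_population, write_recording
from .phantom import GroundTruth, PhantomConfig, generate_phantom, write_phantom
from .segmentation import SegParams, evaluate_fpr, segment_volume
from .volume import VoxelVolume

# per-stage seed offsets fanned out from the global seed
SEED_OFFSETS = {"phantom": 0, "recording": 1, "morphometry": 2}
STAGES = ("simulate", "segment", "morphometry", "mea")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration."""

    out_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    phantom: dict = field(default_factory=dict)
    recording: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    mea: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        stages = {s: True for s in STAGES}
        stages.update(d.pop("stages", {}))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return cls(
            out_dir=Path(d.pop("out_dir", ".")),
            seed=int(d.pop("seed", 0)),
            stages=stages,
            phantom=d.pop("phantom", {}),
            recording=d.pop("recording", {}),
            segmentation=d.pop("segmentation", {}),
            morphometry=d.pop("morphometry", {}),
            mea=d.pop("mea", {}),
            paths=d.pop("paths", {}),
        )

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "stages": dict(self.stages),
            "phantom": dict(self.phantom),
            "recording": dict(self.recording),
            "segmentation": dict(self.segmentation),
            "morphometry": dict(self.morphometry),
            "mea": dict(self.mea),
            "paths": dict(self.paths),
        }


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(paths: dict) -> dict:
    return {k: _sha256(Path(v)) for k, v in paths.items() if Path(v).is_file()}


def _log(out_dir: Path, stage: str, level: str, message: str) -> None:
    with (out_dir / "run_log.jsonl").open("a") as fh:
        fh.write(json.dumps({"stage": stage, "level": level, "message": message}) + "\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order.

    A failing stage aborts the run with a :class:`StageError` naming the
    stage; the manifest (covering completed stages) is written either
    way to ``<out_dir>/manifest.json``.
    """
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(), seed=config.seed
    )
    (out_dir / "config.json").write_text(cfg_json)

    volume = truth = phantom_cfg = None
    recording = None
    try:
        if config.stages.get("simulate"):
            t0 = time.perf_counter()
            stage_seed = config.seed + SEED_OFFSETS["phantom"]
            phantom_cfg = PhantomConfig.from_dict({**config.phantom, "seed": stage_seed})
            try:
                volume, truth = generate_phantom(phantom_cfg)
                sim_dir = out_dir / "simulate"
                paths = write_phantom(sim_dir, volume, truth, phantom_cfg)
                rec_cfg = dict(config.recording)
                protocol_name = rec_cfg.pop("protocol", "blue_five")
                protocol = getattr(StimulusProtocol, protocol_name)()
                recording = generate_population(
                    protocol,
                    n_cells=int(rec_cfg.pop("n_cells", 50)),
                    responder_fraction=float(rec_cfg.pop("responder_fraction", 0.4)),
                    model_ranges=rec_cfg.pop("model_ranges", None),
                    seed=config.seed + SEED_OFFSETS["recording"],
                )
                paths.update(write_recording(sim_dir, recording))
            except Exception as exc:  # noqa: BLE001
                raise StageError("simulate", str(exc)) from exc
            manifest.stages["simulate"] = {
                "seed": stage_seed,
                "outputs": _checksums(paths),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            _log(out_dir, "simulate", "info", f"wrote {len(paths)} artifacts")

        if config.stages.get("segment"):
            t0 = time.perf_counter()
            try:
                if volume is None:
                    vol_path = config.paths.get("volume")
                    if not vol_path or not Path(vol_path).is_file():
                        raise FileNotFoundError("no volume available for segmentation")
                    volume = VoxelVolume.load(vol_path)
                    truth_path = config.paths.get("truth")
                    if truth_path and Path(truth_path).is_file():
                        truth = GroundTruth.load(truth_path)
                params = SegParams(**config.segmentation)
                objects, log = segment_volume(volume, params)
                seg_dir = out_dir / "segment"
                seg_dir.mkdir(parents=True, exist_ok=True)
                obj_json = [
                    {
                        "object_id": o.object_id,
                        "z_extent": o.z_extent,
                        "n_voxels": o.n_voxels,
                        "sections": o.sections,
                    }
                    for o in objects
                ]
                (seg_dir / "objects.json").write_text(json.dumps(obj_json, indent=2))
                (seg_dir / "segment_log.json").write_text(json.dumps(log, indent=2))
                paths = {
                    "objects": seg_dir / "objects.json",
                    "log": seg_dir / "segment_log.json",
                }
                if truth is not None:
                    report = evaluate_fpr(objects, truth, volume.layers)
                    (seg_dir / "fpr_report.json").write_text(
                        json.dumps(report.per_layer, indent=2)
                    )
                    paths["fpr_report"] = seg_dir / "fpr_report.json"
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("segment", str(exc)) from exc
            manifest.stages["segment"] = {
                "outputs": _checksums(paths),
                "elapsed_s": round(time.perf_counter() - t0, 3),
                "log": log,
            }
            _log(out_dir, "segment", "info", f"{log['n_objects_postfilter']} objects kept")

        if config.stages.get("morphometry"):
            t0 = time.perf_counter()
            try:
                if truth is None:
                    truth_path = config.paths.get("truth")
                    if not truth_path or not Path(truth_path).is_file():
                        raise FileNotFoundError("no ground truth for morphometry")
                    truth = GroundTruth.load(truth_path)
                if volume is None:
                    raise FileNotFoundError("no volume geometry for morphometry")
                mor_dir = out_dir / "morphometry"
                mor_dir.mkdir(parents=True, exist_ok=True)
                m_cfg = dict(config.morphometry)
                n_bins = int(m_cfg.get("n_bins", 10))
                ring = float(m_cfg.get("ring_spacing_um", 5.0))
                rows = []
                for nid in truth.neuron_ids:
                    recon = morph.NeuronReconstruction.from_truth(
                        truth, nid, volume.voxel_size_nm
                    )
                    if recon.dendrite_voxels.size == 0:
                        continue
                    profile = morph.depth_profile(
                        recon.dendrite_voxels, volume.layers, n_bins=n_bins
                    )
                    sholl = morph.sholl_topview(
                        recon.dendrite_voxels,
                        recon.soma_center_um,
                        volume.voxel_size_nm,
                        ring_spacing_um=ring,
                    )
                    rows.append(
                        {
                            "neuron_id": nid,
                            "stratification": profile.classify(),
                            "off_fraction": profile.off_fraction,
                            "on_fraction": profile.on_fraction,
                            "soma_diameter_um": morph.soma_diameter(
                                recon.soma_voxels, volume.voxel_size_nm
                            )
                            if recon.soma_voxels.size
                            else np.nan,
                            "sholl_peak": int(sholl.counts.max()) if sholl.counts.size else 0,
                        }
                    )
                pd.DataFrame(rows).to_csv(mor_dir / "neurons.csv", index=False)
                dend_ids = truth.ids_of_class("dendrite_strong", "dendrite_weak")
                all_dend = (
                    np.concatenate([truth.voxel_coords(i) for i in dend_ids])
                    if dend_ids
                    else np.empty((0, 3), dtype=int)
                )
                soma_ids = truth.ids_of_class("soma")
                all_soma = (
                    np.concatenate([truth.voxel_coords(i) for i in soma_ids])
                    if soma_ids
                    else np.empty((0, 3), dtype=int)
                )
                cov = morph.grid_box_coverage(
                    all_dend,
                    all_soma,
                    truth.labels.shape[1:],
                    grid_shape=tuple(m_cfg.get("grid_shape", (5, 5))),
                    n_boxes=int(m_cfg.get("n_boxes", 5)),
                    seed=config.seed + SEED_OFFSETS["morphometry"],
                )
                (mor_dir / "coverage.json").write_text(
                    json.dumps(
                        {
                            "boxes": [list(b) for b in cov.box_indices],
                            "fractions": cov.fractions.tolist(),
                            "mean": cov.mean,
                            "min": cov.min,
                            "max": cov.max,
                            "seed": cov.seed,
                        },
                        indent=2,
                    )
                )
                paths = {
                    "neurons": mor_dir / "neurons.csv",
                    "coverage": mor_dir / "coverage.json",
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("morphometry", str(exc)) from exc
            manifest.stages["morphometry"] = {
                "outputs": _checksums(paths),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            _log(out_dir, "morphometry", "info", "profiles and coverage written")

        if config.stages.get("mea"):
            t0 = time.perf_counter()
            try:
                if recording is None:
                    spikes = config.paths.get("spikes")
                    protocol = config.paths.get("protocol")
                    if not spikes or not Path(spikes).is_file():
                        raise FileNotFoundError("no spike recording for mea stage")
                    recording = Recording.from_csv(spikes, protocol)
                params = AnalysisParams(**config.mea)
                table, cells = dose_response(recording, params)
                mea_dir = out_dir / "mea"
                mea_dir.mkdir(parents=True, exist_ok=True)
                table.to_csv(mea_dir / "response_metrics.csv", index=False)
                cells.to_csv(mea_dir / "cell_flags.csv", index=False)
                summary = {
                    "n_cells": int(cells.shape[0]),
                    "dose_dependent_fraction": float(cells["dose_dependent"].mean())
                    if len(cells)
                    else 0.0,
                }
                (mea_dir / "summary.json").write_text(json.dumps(summary, indent=2))
                paths = {
                    "metrics": mea_dir / "response_metrics.csv",
                    "cell_flags": mea_dir / "cell_flags.csv",
                    "summary": mea_dir / "summary.json",
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("mea", str(exc)) from exc
            manifest.stages["mea"] = {
                "outputs": _checksums(paths),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            _log(out_dir, "mea", "info", f"{summary['n_cells']} cells analysed")
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest
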