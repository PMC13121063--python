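"""End-to-end orchestration: simulate/load -> stabilize -> fit -> segment -> boundary.

A run is a pure function of (input, settings, seed): the manifest records
every setting plus SHA-256 checksums of each stage's arrays, so two runs
with identical config and seed produce bit-identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import phantom as ph
from .stack_io import load_stack, save_maps
from .stabilize import stabilize_stack
from .fitting import FitSettings, fit_stack
from .regions import slic_segment, designate_regions, load_manual_roi
from .boundary import boundary_comparison_from_maps
from .stats import summarize_regions

log = logging.getLogger("pbmap")

__all__ = ["RunConfig", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run."""

    # input: either a stack path or a phantom preset name
    input_path: str | None = None
    preset: str | None = None
    seed: int = 0
    frame_interval: float = 1.0
    phantom_size: tuple[int, int] | None = None  # (height, width) override

    stabilize: bool = True
    model: str = "single_exp"
    tau_min_factor: float = 0.1
    tau_max_factor: float = 50.0
    amp_bound_factor: float = 4.0

    n_segments: int = 300
    compactness: float = 0.1
    driver_map: str = "AF0"
    z_core: float = 3.0
    z_junction: float = 1.5
    roi_path: str | None = None

    kinetic_map: str = "tau"
    boundary_z: float = 3.0

    out_dir: str = "pbmap_run"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path / preset must be given")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.tau_min_factor <= 0 or self.tau_max_factor <= self.tau_min_factor:
            raise ValueError("require 0 < tau_min_factor < tau_max_factor")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.z_core <= 0 or self.z_junction <= 0:
            raise ValueError("z thresholds must be > 0")
        if self.driver_map not in ("AF0", "A", "tau", "C"):
            raise ValueError(f"unknown driver_map {self.driver_map!r}")
        if self.kinetic_map not in ("A", "tau", "C"):
            raise ValueError(f"unknown kinetic_map {self.kinetic_map!r}")
        if self.model not in ("single_exp",):
            raise ValueError(f"unsupported map-fitting model {self.model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom_size" in raw and raw["phantom_size"] is not None:
            raw["phantom_size"] = tuple(raw["phantom_size"])
        return cls(**raw)

    def fit_settings(self) -> FitSettings:
        return FitSettings(amp_bound_factor=self.amp_bound_factor,
                           tau_min_factor=self.tau_min_factor,
                           tau_max_factor=self.tau_max_factor)


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                manifest["failed_stage"] = {"stage": name, "error": str(exc)}
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                return False
            manifest.setdefault("stage_seconds", {})[name] = round(dt, 3)
            log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    Writes parameter maps, region labels, lesion summary, boundary metrics
    and ``manifest.json`` under ``config.out_dir``.  On stage failure the
    manifest written so far is retained with a ``failed_stage`` record and
    the exception is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": "pbmap",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "checksums": {},
    }
    try:
        # --- acquire -------------------------------------------------------
        with _stage("acquire", manifest):
            if config.preset is not None:
                kwargs = {}
                if config.phantom_size is not None:
                    kwargs["height"], kwargs["width"] = config.phantom_size
                presets = ph.three_class_presets(seed=config.seed, **kwargs)
                if config.preset not in presets:
                    raise ValueError(f"unknown preset {config.preset!r}; "
                                     f"choose from {sorted(presets)}")
                spec = presets[config.preset]
                stack, truth = ph.generate_phantom(spec)
                manifest["ground_truth"] = {
                    "region_counts": {int(k): int(v) for k, v in
                                      zip(*np.unique(truth.region_mask, return_counts=True))}}
            else:
                stack = load_stack(config.input_path, frame_interval=config.frame_interval)
            manifest["checksums"]["stack"] = _checksum(stack.data)
            manifest["n_frames"] = int(stack.n_frames)
            manifest["frame_interval"] = stack.frame_interval

        # --- stabilize -----------------------------------------------------
        if config.stabilize:
            with _stage("stabilize", manifest):
                stack, trace = stabilize_stack(stack)
                manifest["shift_trace"] = trace.to_jsonable()
                manifest["checksums"]["stabilized"] = _checksum(stack.data)

        # --- fit -----------------------------------------------------------
        with _stage("fit", manifest):
            maps = fit_stack(stack, model=config.model, settings=config.fit_settings())
            save_maps(maps, out / "maps")
            manifest["checksums"]["maps"] = _checksum(maps.A, maps.tau, maps.C,
                                                      maps.af0, maps.error, maps.mask)
            manifest["valid_fraction"] = float(maps.mask.mean())

        # --- segment -------------------------------------------------------
        with _stage("segment", manifest):
            if config.roi_path:
                regions = load_manual_roi(config.roi_path, expected_shape=maps.shape)
            else:
                driver = maps.map_by_name(config.driver_map)
                labels = slic_segment(driver, n_segments=config.n_segments,
                                      compactness=config.compactness,
                                      valid_mask=maps.mask)
                regions = designate_regions(labels, driver, valid_mask=maps.mask,
                                            z_core=config.z_core,
                                            z_junction=config.z_junction,
                                            source_map=config.driver_map)
            import tifffile
            tifffile.imwrite(out / "superpixels.tif",
                             regions.superpixel_labels.astype(np.int32))
            with open(out / "designations.json", "w") as fh:
                json.dump({str(k): v for k, v in regions.designation.items()},
                          fh, indent=2, sort_keys=True)
            manifest["checksums"]["superpixels"] = _checksum(regions.superpixel_labels)
            manifest["region_counts"] = regions.counts()

        # --- summarize -----------------------------------------------------
        with _stage("summarize", manifest):
            lesion_id = config.preset or Path(config.input_path).stem
            table = summarize_regions(maps, regions, lesion_id=lesion_id,
                                      group=config.preset or "unknown")
            table.to_csv(out / "region_summary.csv", index=False)
            manifest["checksums"]["summary"] = hashlib.sha256(
                table.to_csv(index=False).encode()).hexdigest()

        # --- boundary ------------------------------------------------------
        with _stage("boundary", manifest):
            m_af, m_kin, cmp_res = boundary_comparison_from_maps(
                maps, kinetic=config.kinetic_map, z_threshold=config.boundary_z)
            if cmp_res is None:
                manifest["boundary"] = {"empty_mask": True}
            else:
                manifest["boundary"] = {
                    "area_af": cmp_res.area_af,
                    "area_kinetic": cmp_res.area_kinetic,
                    "area_ratio": cmp_res.area_ratio,
                    "dice": cmp_res.dice,
                    "mean_boundary_offset_px": cmp_res.mean_boundary_offset,
                }
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
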