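"""Readers/writers and the end-to-end pipeline driver.

Speckle stacks travel as multi-page TIFF (16-bit, one page per frame) with a
JSON sidecar recording acquisition metadata and the seed; derived maps are
written as 32-bit float TIFF; tabular results as CSV; run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .contrast import flow_index, flow_time_series, temporal_contrast
from .phantom import (
    AcquisitionConfig,
    SectionStack,
    SpeckleStack,
    StrokeScenario,
    apply_scenario,
    dose_recovery_scenario,
    make_flow_map,
    simulate_speckle_stack,
)
from .roi import Calibration, CircularRoi, roi_mask, roi_relative_flow

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "write_sections",
    "read_sections",
    "run_pipeline",
    "make_fixtures",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: SpeckleStack, path: str | Path) -> Path:
    """Write a speckle stack as multi-page 16-bit TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = np.clip(np.round(stack.frames), 0, 2**stack.config.bit_depth - 1).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta: dict[str, Any] = {"config": dataclasses.asdict(stack.config), "version": __version__}
    if stack.truth is not None:
        meta["truth_summary"] = {
            "mean_speed": float(stack.truth.speed.mean()),
            "labels": sorted(str(x) for x in np.unique(stack.truth.label)),
            "calibration_a": stack.truth.calibration_a,
        }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> SpeckleStack:
    """Read a multi-page TIFF stack and its sidecar back into a SpeckleStack."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar.name}; write stacks with speckleflow.io.write_stack "
            "or supply a JSON sidecar with the acquisition config"
        )
    meta = json.loads(sidecar.read_text())
    config = AcquisitionConfig(**meta["config"])
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != config.n_frames:
        raise ValueError(
            f"page count {frames.shape[0]} does not match sidecar n_frames {config.n_frames}"
        )
    return SpeckleStack(frames.astype(float), config)


def write_map(array: np.ndarray, path: str | Path) -> Path:
    """Write a derived map (contrast / flow / rCBF) as 32-bit float TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def write_sections(sections: SectionStack, directory: str | Path) -> Path:
    """Write a section stack as per-slice TIFF pairs plus an index file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {
        "n_slices": sections.n_slices,
        "slice_spacing_h_um": sections.slice_spacing_h,
        "pixel_size_mm": sections.pixel_size,
        "slices": [],
    }
    for i, (neu, ves) in enumerate(zip(sections.neuron_channel, sections.vessel_channel)):
        npath, vpath = f"slice_{i:03d}_neuron.tif", f"slice_{i:03d}_vessel.tif"
        tifffile.imwrite(directory / npath, neu.astype(np.float32))
        tifffile.imwrite(directory / vpath, ves.astype(np.uint8))
        index["slices"].append({"neuron": npath, "vessel": vpath})
    (directory / "index.json").write_text(json.dumps(index, indent=2))
    return directory


def read_sections(directory: str | Path) -> SectionStack:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    neuron = [tifffile.imread(directory / s["neuron"]).astype(float) for s in index["slices"]]
    vessel = [tifffile.imread(directory / s["vessel"]).astype(bool) for s in index["slices"]]
    return SectionStack(neuron, vessel, index["slice_spacing_h_um"], index["pixel_size_mm"])


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    out_dir: str | Path,
    scenario: StrokeScenario | None = None,
    times: list[float] | None = None,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 0.02,
    baseline_tau_ms: float = 0.2,
    config: AcquisitionConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Phantom -> stacks -> rCBF -> ROI means, end to end, with a manifest.

    Generates a flow map carrying the scenario's spot geometry, simulates a
    baseline stack plus one stack per requested time point, computes
    baseline-normalized rCBF, and reports the mean over the spot ROI and the
    evaluation circle at each time.  All outputs land in ``out_dir``;
    deterministic given the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = dose_recovery_scenario(0.0)
    if times is None:
        times = [0.0]
    base_cfg = config or AcquisitionConfig(pixel_size=pixel_size, seed=seed)

    h, w = shape
    center_mm = (h * pixel_size / 2.0, w * pixel_size / 2.0)
    calibration = Calibration(
        pixel_size,
        (
            center_mm[0] / pixel_size + scenario.spot_center_ap_ml[0] / pixel_size,
            center_mm[1] / pixel_size - scenario.spot_center_ap_ml[1] / pixel_size,
        ),
    )
    speed = 1.0
    fmap = make_flow_map(
        w, h, pixel_size,
        parenchyma_speed=speed,
        calibration_a=baseline_tau_ms * speed,
        spot_center_mm=center_mm,
        spot_diameter_mm=scenario.spot_diameter_mm,
    )

    stacks, stack_paths = [], []
    for i, t in enumerate([0.0] + list(times)):
        cfg = dataclasses.replace(base_cfg, seed=base_cfg.seed + i)
        stack = simulate_speckle_stack(apply_scenario(fmap, scenario, t), cfg)
        stacks.append(stack)
        stack_paths.append(write_stack(stack, out_dir / f"stack_t{i:02d}.tif"))

    maps = flow_time_series(stacks, baseline_index=0)
    flows = [flow_index(temporal_contrast(s)) for s in stacks]
    spot = CircularRoi(scenario.spot_center_ap_ml, scenario.spot_diameter_mm, "spot")
    circle = CircularRoi(scenario.spot_center_ap_ml, scenario.eval_circle_diameter_mm, "eval_circle")
    rows = []
    for i, t in enumerate([0.0] + list(times)):
        write_map(maps[i].rcbf, out_dir / f"rcbf_t{i:02d}.tif")
        for roi in (spot, circle):
            mask = roi_mask(roi, calibration, shape)
            rows.append(
                {"time": t, "roi": roi.label, "mean": roi_relative_flow(flows[i], flows[0], mask)}
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "roi_means.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "scenario": {
            "dose_minutes": scenario.dose_minutes,
            "time_unit": scenario.time_unit,
            "times": times,
        },
        "config": dataclasses.asdict(base_cfg),
        "stages": [
            {"stage": "simulate", "output": p.name, "sha256": _sha(p)} for p in stack_paths
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Generate a miniature fixture set: baseline + one stack per dose.

    64 x 64 pixels, 40 frames each; reproducible bit-for-bit from the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pixel_size = 0.02
    paths: dict[str, Path] = {}
    fmap = make_flow_map(64, 64, pixel_size, calibration_a=0.2,
                         spot_center_mm=(0.64, 0.64), spot_diameter_mm=1.0)
    cfg = AcquisitionConfig(pixel_size=pixel_size, seed=seed)
    paths["baseline"] = write_stack(simulate_speckle_stack(fmap, cfg), out_dir / "baseline.tif")
    for i, dose in enumerate((1.0, 2.0, 5.0)):
        scen = dose_recovery_scenario(dose)
        cfg_d = dataclasses.replace(cfg, seed=seed + 1 + i)
        stack = simulate_speckle_stack(apply_scenario(fmap, scen, 14.0), cfg_d)
        paths[f"dose_{int(dose)}min_day14"] = write_stack(
            stack, out_dir / f"dose_{int(dose)}min_day14.tif"
        )
    return paths
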