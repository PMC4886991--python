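"""End-to-end processing of a directory of still frames.

Ties the stages together the way the command-line tool runs them:
read -> recenter -> (optional beam-stop mask) -> triage -> per-image grid
search -> unit-cell clustering -> summary bundle.  Images are independent
work units processed in deterministic filename order, so results do not
depend on scheduling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import cluster_cells
from .analytics import summarize_run
from .frame import ImageFrame
from .gridsearch import (GridSpec, ImageRecord, ProcessOptions, build_grid,
                         process_image_gridsearch)
from .preprocess import (DEFAULT_MIN_SPOTS, make_beamstop_mask,
                         recenter_frame, triage_frame)
from .smv import read_frame
from .spotfind import SpotFindParams

__all__ = ["RunConfig", "process_frames", "process_run"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one processing run needs, loadable from key=value text."""

    target_cell: tuple
    grid: GridSpec = GridSpec(8, 7, 12, 10)
    options: ProcessOptions = ProcessOptions()
    min_spots: int = DEFAULT_MIN_SPOTS
    beamstop_radius: float = 0.0
    beamstop_arm_width: float = 0.0
    linkage_threshold: float = 5.0
    bravais_lattice: str = "aP"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        fields: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                fields[key.strip()] = value.strip()
        cell = tuple(float(x) for x in fields["target_cell"].split())
        grid = GridSpec(float(fields.get("height_median", 8)),
                        float(fields.get("height_spread", 7)),
                        int(fields.get("area_median", 12)),
                        int(fields.get("area_spread", 10)))
        options = ProcessOptions(
            d_L=float(fields.get("d_min", 3.5)),
            strong_threshold=float(fields.get("strong_threshold", 5.0)),
            epv_fraction=float(fields.get("epv_fraction", 0.25)),
            required_lattice=fields.get("required_lattice") or None,
            cell_tolerance=float(fields.get("cell_tolerance", 0.05)),
            angle_tolerance=float(fields.get("angle_tolerance", 1.0)))
        return cls(target_cell=cell, grid=grid, options=options,
                   min_spots=int(fields.get("min_spots", DEFAULT_MIN_SPOTS)),
                   beamstop_radius=float(fields.get("beamstop_radius", 0.0)),
                   beamstop_arm_width=float(fields.get("beamstop_arm", 0.0)),
                   linkage_threshold=float(fields.get("linkage_threshold", 5.0)),
                   bravais_lattice=fields.get("bravais_lattice", "aP"))


def _triage_params(grid: list[tuple[float, int]]) -> SpotFindParams:
    """One cheap pass at the grid-search median point."""
    heights = sorted({h for h, _ in grid})
    areas = sorted({a for _, a in grid})
    return SpotFindParams(min_height=heights[len(heights) // 2],
                          min_area=areas[len(areas) // 2])


def process_frames(frames: list[ImageFrame], config: RunConfig
                   ) -> tuple[list[ImageRecord], list[list[dict]]]:
    """Triage and grid-search a list of in-memory frames."""
    grid = build_grid(config.grid)
    triage_pt = _triage_params(grid)
    records: list[ImageRecord] = []
    logs: list[list[dict]] = []
    for frame in frames:
        frame = recenter_frame(frame)
        if config.beamstop_radius > 0 or config.beamstop_arm_width > 0:
            frame = frame.with_mask(make_beamstop_mask(
                frame.geometry, config.beamstop_radius,
                config.beamstop_arm_width))
        decision = triage_frame(frame, triage_pt, min_spots=config.min_spots)
        if not decision.keep:
            records.append(ImageRecord(frame.source_id, "no_diffraction"))
            logs.append([])
            continue
        best, results, log = process_image_gridsearch(
            frame, grid, config.target_cell, config.options)
        logs.append(log)
        if best is None:
            status = "failed_filter" if results else "not_integrated"
            histogram: dict[str, int] = {}
            for entry in log:
                if entry["stage_reached"] != "done":
                    key = f"{entry['stage_reached']}: {entry['reason']}"
                    histogram[key] = histogram.get(key, 0) + 1
            records.append(ImageRecord(frame.source_id, status,
                                       failure_histogram=histogram))
        else:
            records.append(ImageRecord(frame.source_id, "integrated",
                                       best=best))
    return records, logs


def _write_outputs(records, logs, config, out_dir: Path):
    grid = build_grid(config.grid)
    out_dir.mkdir(parents=True, exist_ok=True)
    final = out_dir / "final"
    final.mkdir(exist_ok=True)
    log_rows = []
    for record, log in zip(records, logs):
        for entry in log:
            log_rows.append({"image": record.image_id, **entry})
        if record.best is None:
            continue
        stem = Path(record.image_id).stem
        record.best.reflections.to_csv(final / f"{stem}.refl", sep="\t",
                                       index=False, float_format="%.6g")
        lat = record.best.lattice
        sidecar = {
            "cell": list(lat.cell),
            "orientation": [float(x) for x in lat.orientation.ravel()],
            "D": lat.mosaic_block_size_D, "eta": lat.mosaic_angle_eta,
            "rmsd": lat.rmsd_obs_pred, "n_indexed": lat.n_indexed,
            "n_strong": record.best.n_strong(config.options.strong_threshold),
            "epv": record.best.epv,
            "grid_point": list(record.best.grid_point),
        }
        (final / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    pd.DataFrame(log_rows).to_csv(out_dir / "grid_log.tsv", sep="\t",
                                  index=False, float_format="%.6g")

    integrated = [r for r in records if r.status == "integrated"]
    if integrated:
        report = cluster_cells(
            [r.best.lattice.cell for r in integrated],
            linkage_threshold=config.linkage_threshold,
            image_ids=[r.image_id for r in integrated])
        (out_dir / "clusters.json").write_text(json.dumps({
            "linkage_threshold": report.linkage_threshold,
            "dominant_index": report.dominant_index,
            "clusters": [{"members": c["members"],
                          "centroid_cell": list(c["centroid_cell"]),
                          "spread": list(c["spread"])}
                         for c in report.clusters]}, indent=1))
        summarize_run(records, report, grid, out_dir,
                      bravais_lattice=config.bravais_lattice)
    return records


def process_run(input_dir, config: RunConfig, out_dir):
    """Process every ``*.img`` under ``input_dir``; write the full output
    bundle to ``out_dir``.  Returns the per-image records."""
    paths = sorted(Path(input_dir).glob("*.img"))
    if not paths:
        raise FileNotFoundError(f"no .img frames under {input_dir}")
    frames = [read_frame(p) for p in paths]
    records, logs = process_frames(frames, config)
    _write_outputs(records, logs, config, Path(out_dir))
    return records
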