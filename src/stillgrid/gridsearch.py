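"""Per-image spot-finding parameter grid search with EPV-based selection.

Still-image indexing is highly sensitive to the two spot-finding
thresholds, and no single pair works across a heterogeneous serial data
set.  The grid search therefore runs the full
spotfind -> index -> refine -> mosaic -> predict -> integrate pipeline at
every pairwise combination of threshold values and keeps each result that
completes.  The best result per image is then chosen by a two-step
heuristic: (i) keep the quarter of results with the smallest Ewald
proximal volume (the sharpest crystal models); (ii) among those, return
the one with the most strong integrated reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .epv import compute_epv
from .frame import ImageFrame
from .index import (IndexingError, bravais_filter, estimate_mosaic,
                    index_still)
from .integrate import (STRONG_THRESHOLD, IntegrationResult,
                        integrate_reflections, predict_reflections)
from .spotfind import SpotFindParams, estimate_background, find_spots

__all__ = ["GridSpec", "build_grid", "select_best",
           "process_image_gridsearch", "ProcessOptions", "ImageRecord"]


@dataclass(frozen=True)
class GridSpec:
    """Median +/- spread definition of the two searched parameters."""

    height_median: float
    height_spread: float
    area_median: int
    area_spread: int

    def __post_init__(self):
        if self.height_spread < 0 or self.area_spread < 0:
            raise ValueError("spreads must be non-negative")


def build_grid(spec: GridSpec) -> list[tuple[float, int]]:
    """All pairwise (min_height, min_area) combinations, row-major with
    height as the outer loop, unit step in each parameter.

    Values outside the validity floor (height <= 0, area < 1) are dropped;
    an empty grid after flooring is an error.  The canonical serial-run
    choice of 8 +/- 7 sigma height and 12 +/- 10 px area yields a 15 x 21
    grid of 315 pairs.
    """
    heights = [h for h in
               np.arange(spec.height_median - spec.height_spread,
                         spec.height_median + spec.height_spread + 0.5, 1.0)
               if h > 0]
    areas = [int(a) for a in
             np.arange(spec.area_median - spec.area_spread,
                       spec.area_median + spec.area_spread + 0.5, 1.0)
             if a >= 1]
    grid = [(float(h), int(a)) for h in heights for a in areas]
    if not grid:
        raise ValueError("grid is empty after dropping invalid values")
    return grid


def select_best(results: list[IntegrationResult],
                epv_fraction: float = 0.25,
                strong_threshold: float = STRONG_THRESHOLD
                ) -> IntegrationResult:
    """Two-step best-result selection.

    (i) keep the ``ceil(epv_fraction * N)`` results with the smallest EPV
    (ties: more reflections, then grid order); (ii) of those return the one
    with the most strong reflections (I/sigma strictly above threshold;
    ties: smaller EPV, then grid order).  Invariant under permutation of
    the input because every comparison ends at the unique grid index.
    """
    if not results:
        raise ValueError("no integration results")
    n_keep = math.ceil(epv_fraction * len(results))
    pool = sorted(results,
                  key=lambda r: (r.epv, -len(r.reflections), r.grid_index))
    pool = pool[:n_keep]
    return min(pool, key=lambda r: (-r.n_strong(strong_threshold), r.epv,
                                    r.grid_index))


@dataclass(frozen=True)
class ProcessOptions:
    """Knobs for the per-image pipeline."""

    d_L: float = 3.5                       # outer resolution limit, angstrom
    strong_threshold: float = STRONG_THRESHOLD
    epv_fraction: float = 0.25
    n_min_spots: int = 10                  # indexing minimum
    required_lattice: str | None = None    # e.g. "oP"; None disables filter
    cell_tolerance: float = 0.05
    angle_tolerance: float = 1.0
    integration_radius: float = 3.0
    n_rotations: int = 80000               # coarse SO(3) search size
    reuse_orientation: bool = True         # share orientation across grid


@dataclass
class ImageRecord:
    """Outcome of one image: status plus the selected result if any.

    ``status`` is one of ``integrated``, ``no_diffraction`` (failed
    triage), ``not_integrated`` (every grid point failed), or
    ``failed_filter`` (integrated but rejected by the lattice filter).
    """

    image_id: str
    status: str
    best: IntegrationResult | None = None
    failure_histogram: dict = field(default_factory=dict)


def process_image_gridsearch(frame: ImageFrame, grid, target_cell,
                             options: ProcessOptions = ProcessOptions()):
    """Run the full pipeline at every grid point and select the best result.

    Returns ``(best_or_None, all_results, log)`` where ``log`` has one dict
    per grid point recording the stage reached and any failure reason.
    Per-point failures are data, not errors; the image as a whole fails
    only when no grid point survives.

    The coarse orientation search runs at most a few times per image
    (bootstrapped near the grid centre): the crystal does not change
    between grid points, so once an orientation is found every other point
    starts from it and runs only the cheap local polish.
    """
    background = estimate_background(frame)
    results: list[IntegrationResult] = []
    log = [{"grid_index": gi, "min_height": height, "min_area": area,
            "stage_reached": "spotfind", "reason": "", "epv": np.nan,
            "n_strong": 0, "selected": False}
           for gi, (height, area) in enumerate(grid)]
    cached_R = None
    # the crystal does not change between grid points, so the expensive
    # coarse orientation search is bootstrapped near the grid centre (the
    # best-behaved spot sets) and capped; once an orientation is in hand
    # every other point only runs the cheap local polish
    middle = len(grid) // 2
    order = sorted(range(len(grid)), key=lambda i: (abs(i - middle), i))
    full_search_budget = 3 if options.reuse_orientation else len(grid)
    for gi in order:
        height, area = grid[gi]
        entry = log[gi]
        params = SpotFindParams(min_height=height, min_area=area)
        spots = find_spots(frame, params, background=background)
        if len(spots) < options.n_min_spots:
            entry["reason"] = f"only {len(spots)} spots"
            continue
        try:
            entry["stage_reached"] = "index"
            allow_full = (not options.reuse_orientation
                          or (cached_R is None and full_search_budget > 0))
            if allow_full and cached_R is None:
                full_search_budget -= 1
            model = index_still(
                spots, target_cell, frame,
                n_min=options.n_min_spots, n_rotations=options.n_rotations,
                initial_orientation=cached_R if options.reuse_orientation
                else None, allow_full_search=allow_full)
        except IndexingError as exc:
            entry["reason"] = exc.reason
            continue
        if cached_R is None and options.reuse_orientation:
            cached_R = model.orientation
        entry["stage_reached"] = "mosaic"
        strong = [s for s in spots
                  if s.peak_height_sigma >= 2.0 * params.min_height]
        model = estimate_mosaic(model, strong or spots, frame,
                                d_L=options.d_L)
        entry["stage_reached"] = "integrate"
        preds = predict_reflections(model, frame.geometry, frame.wavelength,
                                    options.d_L)
        result = integrate_reflections(frame, preds, background, model,
                                       mask_radius=options.integration_radius)
        if len(result.reflections) == 0:
            entry["reason"] = "no reflections integrated"
            continue
        result.grid_point = (height, area)
        result.grid_index = gi
        result.epv = compute_epv(model.mosaic_block_size_D,
                                 model.mosaic_angle_eta, frame.wavelength,
                                 options.d_L)
        entry["stage_reached"] = "done"
        entry["epv"] = result.epv
        entry["n_strong"] = result.n_strong(options.strong_threshold)
        results.append(result)
    results.sort(key=lambda r: r.grid_index)

    pool = results
    if options.required_lattice is not None:
        pool = [r for r in results
                if bravais_filter(r.lattice.cell, options.required_lattice,
                                  target_cell=target_cell,
                                  angle_tolerance=options.angle_tolerance,
                                  length_tolerance=options.cell_tolerance)]
    if not pool:
        return None, results, log
    best = select_best(pool, epv_fraction=options.epv_fraction,
                       strong_threshold=options.strong_threshold)
    log[best.grid_index]["selected"] = True
    return best, results, log
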