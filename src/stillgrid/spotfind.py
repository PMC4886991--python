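"""Candidate Bragg-peak detection.

Two parameters drive the whole grid search: the minimum peak height
(background-subtracted intensity over the local background standard
deviation) and the minimum spot area (connected pixels above threshold).
The background model is deliberately simple and robust — per-tile median
and scaled MAD — because still backgrounds from solvent/air scatter are
smooth at the tile scale while Bragg peaks are sparse outliers the median
ignores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .frame import ImageFrame
from .geometry import d_spacing_at_pixel

__all__ = ["Spot", "SpotFindParams", "estimate_background", "find_spots",
           "spots_to_table"]

_MAD_TO_SIGMA = 1.4826
_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SpotFindParams:
    """Grid-searched thresholds: ``min_height`` in background-sigma units,
    ``min_area`` in connected pixels."""

    min_height: float
    min_area: int

    def __post_init__(self):
        if self.min_height <= 0:
            raise ValueError("min_height must be positive")
        if int(self.min_area) != self.min_area or self.min_area < 1:
            raise ValueError("min_area must be an integer >= 1")
        object.__setattr__(self, "min_area", int(self.min_area))


@dataclass(frozen=True)
class Spot:
    """One candidate Bragg peak."""

    centroid: tuple[float, float]    # (slow, fast), intensity-weighted
    area: int                        # pixels in the connected component
    peak_height_sigma: float         # max (I - bg) / sigma over the component
    summed_intensity: float          # background-subtracted counts
    sigma_intensity: float           # counting-statistics sigma
    d_spacing: float                 # angstrom (inf at the beam centre)


def estimate_background(frame: ImageFrame, tile: int = 32):
    """Per-pixel robust background level and sigma rasters.

    Tiles the raster into ``tile`` x ``tile`` blocks, takes the median and
    1.4826*MAD of unmasked pixels in each, and broadcasts the block values
    back to pixel resolution.  Raises on a fully masked frame.
    """
    mask = frame.effective_mask()
    if mask.all():
        raise ValueError("cannot estimate background: frame fully masked")
    data = frame.raster.astype(float)
    n_slow, n_fast = data.shape
    nbs = -(-n_slow // tile)
    nbf = -(-n_fast // tile)
    level = np.empty((nbs, nbf))
    sigma = np.empty((nbs, nbf))
    for bi in range(nbs):
        for bj in range(nbf):
            sl = np.s_[bi * tile:(bi + 1) * tile, bj * tile:(bj + 1) * tile]
            vals = data[sl][~mask[sl]]
            if vals.size == 0:
                level[bi, bj] = np.nan
                sigma[bi, bj] = np.nan
                continue
            med = np.median(vals)
            level[bi, bj] = med
            sigma[bi, bj] = _MAD_TO_SIGMA * np.median(np.abs(vals - med))
    # fill tiles that were fully masked with the global medians
    if np.isnan(level).any():
        level[np.isnan(level)] = np.nanmedian(level)
        sigma[np.isnan(sigma)] = np.nanmedian(sigma)
    bg = np.repeat(np.repeat(level, tile, axis=0), tile, axis=1)
    sg = np.repeat(np.repeat(sigma, tile, axis=0), tile, axis=1)
    return bg[:n_slow, :n_fast], sg[:n_slow, :n_fast]


def find_spots(frame: ImageFrame, params: SpotFindParams,
               background=None) -> list[Spot]:
    """Threshold-and-label spot search.

    A spot is a maximal 8-connected component of unmasked pixels with
    ``value >= background + min_height * sigma``, kept when its pixel count
    reaches ``min_area``.  Output is sorted by summed intensity descending,
    ties broken by centroid ``(slow, fast)``.

    ``background`` may carry a precomputed ``(level, sigma)`` pair so one
    estimate is shared across all grid points of a frame.
    """
    bg, sg = background if background is not None else estimate_background(frame)
    data = frame.raster.astype(float)
    mask = frame.effective_mask()
    # rasters are integer counts, so one count is the smallest resolvable
    # step: floor sigma there to keep thresholds meaningful on noise-free
    # (or locally flat) backgrounds
    sg_floor = np.maximum(sg, 1.0)
    above = (data >= bg + params.min_height * sg_floor) & ~mask
    # zero-sigma flats: require a genuinely positive excess
    above &= (data - bg) > 0
    labels, n_lab = ndimage.label(above, structure=_EIGHT_CONNECTED)
    if n_lab == 0:
        return []
    idx = np.arange(1, n_lab + 1)
    net = data - bg
    pos_net = np.clip(net, 0.0, None)
    areas = ndimage.sum_labels(np.ones_like(data), labels, idx)
    wsum = ndimage.sum_labels(pos_net, labels, idx)
    ys, xs = np.indices(data.shape, sparse=True)
    cy = ndimage.sum_labels(pos_net * ys, labels, idx) / np.maximum(wsum, 1e-12)
    cx = ndimage.sum_labels(pos_net * xs, labels, idx) / np.maximum(wsum, 1e-12)
    summed = ndimage.sum_labels(net, labels, idx)
    var = (ndimage.sum_labels(np.clip(data, 0, None), labels, idx)
           + ndimage.sum_labels(sg_floor ** 2, labels, idx))
    height = ndimage.maximum(net / sg_floor, labels, idx)
    keep = (areas >= params.min_area) & (wsum > 0)
    d = d_spacing_at_pixel(np.column_stack([cy, cx]), frame.geometry,
                           frame.wavelength)
    spots = [Spot(centroid=(float(cy[i]), float(cx[i])), area=int(areas[i]),
                  peak_height_sigma=float(height[i]),
                  summed_intensity=float(summed[i]),
                  sigma_intensity=float(np.sqrt(var[i])),
                  d_spacing=float(d[i]))
             for i in np.nonzero(keep)[0]]
    spots.sort(key=lambda s: (-s.summed_intensity, s.centroid))
    return spots


def spots_to_table(spots: list[Spot]) -> pd.DataFrame:
    """Tab-separated-friendly table: slow fast area height_sigma I sigI d."""
    return pd.DataFrame({
        "slow": [s.centroid[0] for s in spots],
        "fast": [s.centroid[1] for s in spots],
        "area": [s.area for s in spots],
        "height_sigma": [s.peak_height_sigma for s in spots],
        "I": [s.summed_intensity for s in spots],
        "sigI": [s.sigma_intensity for s in spots],
        "d": [s.d_spacing for s in spots],
    })
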