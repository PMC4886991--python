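"""Frame pre-processing: beam recentering, beam-stop masking, triage.

Serial runs waste most exposures on frames with no crystal in the beam
(often 90% or more).  Triage runs the spot finder once at a single cheap
parameter point and discards frames with too few candidate peaks before
the expensive per-frame grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .frame import ImageFrame
from .geometry import DetectorGeometry
from .spotfind import SpotFindParams, find_spots

__all__ = ["TriageDecision", "recenter_frame", "make_beamstop_mask",
           "triage_frame"]

#: Default minimum candidate-spot count for a frame to count as diffracting.
DEFAULT_MIN_SPOTS = 10


@dataclass(frozen=True)
class TriageDecision:
    keep: bool
    n_bragg_candidates: int
    reason: str


def recenter_frame(frame: ImageFrame) -> ImageFrame:
    """Pad the raster so the direct beam sits at the geometric centre.

    Indexing code downstream assumes the beam at ``((n-1)/2, (n-1)/2)``.
    Padding (never cropping) preserves every recorded pixel; added pixels
    are zero-valued and masked.  Idempotent: a centred frame (within half a
    pixel) is returned unchanged.
    """
    g = frame.geometry
    bs, bf = g.beam_center
    if not (0 <= bs <= g.n_slow - 1 and 0 <= bf <= g.n_fast - 1):
        raise ValueError(f"beam center {g.beam_center} outside the raster")

    def pads(b: float, n: int) -> tuple[int, int]:
        # after padding (lo, hi) the centre index (n+lo+hi-1)/2 must equal
        # b+lo; one side is always 0
        diff = 2.0 * b - (n - 1)
        if diff >= 0:
            return 0, max(int(round(diff)), 0)
        return max(int(round(-diff)), 0), 0

    (slo, shi) = pads(bs, g.n_slow)
    (flo, fhi) = pads(bf, g.n_fast)
    if slo == shi == flo == fhi == 0:
        return frame
    raster = np.pad(frame.raster, ((slo, shi), (flo, fhi)))
    pad_mask = np.ones(raster.shape, dtype=bool)
    pad_mask[slo:slo + g.n_slow, flo:flo + g.n_fast] = frame.effective_mask()
    geom = DetectorGeometry(
        n_slow=raster.shape[0], n_fast=raster.shape[1],
        pixel_size=g.pixel_size, distance=g.distance,
        beam_center=(bs + slo, bf + flo))
    return replace(frame, raster=raster, geometry=geom, mask=pad_mask)


def make_beamstop_mask(geometry: DetectorGeometry, radius_px: float,
                       arm_width_px: float,
                       arm_direction: str = "+fast") -> np.ndarray:
    """Boolean mask of a circular beam-stop shadow plus its support arm.

    The disc is centred on the beam; the arm is a rectangle of the given
    width running from the beam centre to the detector edge along
    ``arm_direction`` (one of ``+slow``, ``-slow``, ``+fast``, ``-fast``).
    """
    if radius_px < 0 or arm_width_px < 0:
        raise ValueError("radius and arm width must be non-negative")
    bs, bf = geometry.beam_center
    ys, xs = np.indices(geometry.shape)
    mask = np.zeros(geometry.shape, dtype=bool)
    if radius_px > 0:
        mask |= (ys - bs) ** 2 + (xs - bf) ** 2 <= radius_px ** 2
    if arm_width_px > 0:
        half = arm_width_px / 2.0
        if arm_direction == "+fast":
            mask |= (np.abs(ys - bs) <= half) & (xs >= bf)
        elif arm_direction == "-fast":
            mask |= (np.abs(ys - bs) <= half) & (xs <= bf)
        elif arm_direction == "+slow":
            mask |= (np.abs(xs - bf) <= half) & (ys >= bs)
        elif arm_direction == "-slow":
            mask |= (np.abs(xs - bf) <= half) & (ys <= bs)
        else:
            raise ValueError(f"unknown arm_direction {arm_direction!r}")
    return mask


def triage_frame(frame: ImageFrame, spot_params: SpotFindParams,
                 min_spots: int = DEFAULT_MIN_SPOTS,
                 background=None) -> TriageDecision:
    """Keep a frame iff the spot finder sees at least ``min_spots``
    candidates at ``spot_params``.  ``min_spots=0`` bypasses triage."""
    if min_spots < 0:
        raise ValueError("min_spots must be non-negative")
    if min_spots == 0:
        return TriageDecision(keep=True, n_bragg_candidates=0,
                              reason="triage bypassed (min_spots=0)")
    n = len(find_spots(frame, spot_params, background=background))
    if n >= min_spots:
        return TriageDecision(True, n, f"{n} candidate spots >= {min_spots}")
    return TriageDecision(False, n, f"only {n} candidate spots < {min_spots}")
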