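"""Reflection prediction and summation integration.

Prediction enumerates every reciprocal-lattice node inside the resolution
limit whose distance from the Ewald sphere is within half the mosaic spot
width w(d) = 2/D + eta/d — exactly the region whose volume the EPV
measures, so orientation-averaged prediction counts check out against
EPV * V_cell.  Integration is plain summation in a fixed circular mask
with local-background subtraction and counting-statistics sigmas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import b_matrix
from .epv import spot_width
from .frame import ImageFrame
from .geometry import DetectorGeometry, ewald_offsets, project_q_to_pixels
from .index import LatticeModel

__all__ = ["IntegrationResult", "predict_reflections",
           "integrate_reflections"]

#: Default I/sigma(I) threshold above which a reflection counts as strong.
STRONG_THRESHOLD = 5.0


@dataclass
class IntegrationResult:
    """Per-image integrated reflection table plus its crystal model."""

    reflections: pd.DataFrame        # h k l I sigI d partial_flag
    lattice: LatticeModel
    image_id: str = ""
    grid_point: tuple = (np.nan, np.nan)     # (min_height, min_area)
    grid_index: int = -1                     # position in grid order
    epv: float = np.nan                      # 1/angstrom^3
    n_dropped: int = 0                       # off-detector / masked

    def n_strong(self, threshold: float = STRONG_THRESHOLD) -> int:
        """Count of reflections with I/sigma(I) strictly above threshold."""
        refl = self.reflections
        if len(refl) == 0:
            return 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = refl["I"].to_numpy() / refl["sigI"].to_numpy()
        return int(np.sum(ratio > threshold))


def predict_reflections(model: LatticeModel, geom: DetectorGeometry,
                        wavelength: float, d_L: float,
                        d_max: float | None = None) -> pd.DataFrame:
    """Nodes satisfying the mosaic diffraction condition, with detector
    positions.

    Columns: h k l, d, delta (signed sphere offset), slow, fast,
    on_detector.  ``d_max`` optionally cuts low-resolution nodes (off by
    default: the proximal volume spans from the beam axis outwards).
    """
    if d_L < wavelength / 2.0:
        raise ValueError("resolution unreachable: d_L < lambda/2")
    B = model.orientation @ b_matrix(model.cell)
    a, b, c = model.cell[:3]
    ranges = [np.arange(-int(np.ceil(e / d_L)), int(np.ceil(e / d_L)) + 1)
              for e in (a, b, c)]
    h, k, l = np.meshgrid(*ranges, indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ B.T
    inv_d = np.linalg.norm(q, axis=1)
    d = np.where(inv_d > 0, 1.0 / inv_d, np.inf)
    keep = d >= d_L
    if d_max is not None:
        keep &= d <= d_max
    hkl, q, d = hkl[keep], q[keep], d[keep]
    delta = ewald_offsets(q, wavelength)
    w = spot_width(d, model.mosaic_block_size_D, model.mosaic_angle_eta)
    near = np.abs(delta) <= w / 2.0
    hkl, q, d, delta, w = hkl[near], q[near], d[near], delta[near], w[near]
    bc = model.beam_center_refined
    if not np.all(np.isfinite(bc)):
        bc = geom.beam_center
    pos, on = project_q_to_pixels(q, geom, wavelength, beam_center=bc)
    out = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
        "d": d, "delta": delta, "w": w,
        "slow": pos[:, 0], "fast": pos[:, 1], "on_detector": on,
    })
    return out.sort_values(["h", "k", "l"], ignore_index=True)


def integrate_reflections(frame: ImageFrame, predictions: pd.DataFrame,
                          background, model: LatticeModel,
                          mask_radius: float = 3.0,
                          image_id: str | None = None) -> IntegrationResult:
    """Summation-integrate predicted reflections in circular masks.

    Predictions off the detector, or whose mask touches an excluded pixel,
    are dropped and tallied in ``n_dropped``.  ``partial_flag`` marks
    reflections predicted further than a quarter spot-width from the Ewald
    sphere, i.e. recorded at well below full partiality.
    """
    bg, sg = background
    data = frame.raster.astype(float)
    excl = frame.effective_mask()
    n_slow, n_fast = data.shape
    r = int(np.ceil(mask_radius))
    oy, ox = np.indices((2 * r + 1, 2 * r + 1)) - r
    disc = oy ** 2 + ox ** 2 <= mask_radius ** 2
    rows = []
    n_dropped = 0
    for rec in predictions.itertuples(index=False):
        if not rec.on_detector or not np.isfinite(rec.slow):
            n_dropped += 1
            continue
        cs, cf = int(round(rec.slow)), int(round(rec.fast))
        ys, xs = oy[disc] + cs, ox[disc] + cf
        inside = (ys >= 0) & (ys < n_slow) & (xs >= 0) & (xs < n_fast)
        if not inside.all() or excl[ys[inside], xs[inside]].any():
            n_dropped += 1
            continue
        vals = data[ys, xs]
        net = vals - bg[ys, xs]
        intensity = float(net.sum())
        var = float(np.clip(vals, 0, None).sum() + (sg[ys, xs] ** 2).sum())
        rows.append({
            "h": int(rec.h), "k": int(rec.k), "l": int(rec.l),
            "I": intensity, "sigI": float(np.sqrt(max(var, 1e-12))),
            "d": float(rec.d),
            "partial_flag": bool(abs(rec.delta) > rec.w / 4.0),
        })
    refl = pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigI", "d",
                                       "partial_flag"])
    return IntegrationResult(reflections=refl, lattice=model,
                             image_id=image_id or frame.source_id,
                             n_dropped=n_dropped)
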