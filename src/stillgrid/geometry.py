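"""Detector geometry and still-diffraction ray tracing.

Lab frame: the incident beam travels along +z from the crystal (origin) to
a flat detector at ``z = distance`` mm.  Detector pixels are addressed as
``(slow, fast)``, 0-based, with pixel centres at integer coordinates; the
``fast`` axis maps to lab +x and the ``slow`` axis to lab +y.  The Ewald
sphere has radius ``1/lambda`` and is centred at ``(0, 0, -1/lambda)``, so a
reciprocal-lattice vector ``q`` diffracts when ``|q + z/lambda| = 1/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DetectorGeometry", "q_vectors_from_pixels", "project_q_to_pixels",
           "d_spacing_at_pixel", "ewald_offsets"]


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector description.

    Parameters
    ----------
    n_slow, n_fast : int
        Raster dimensions in pixels.
    pixel_size : float
        Pixel edge in mm (square pixels).
    distance : float
        Crystal-to-detector distance in mm.
    beam_center : tuple of float
        Direct-beam position ``(slow, fast)`` in pixels; may be fractional.
    """

    n_slow: int
    n_fast: int
    pixel_size: float
    distance: float
    beam_center: tuple[float, float]

    def __post_init__(self):
        if self.n_slow <= 0 or self.n_fast <= 0:
            raise ValueError("raster dimensions must be positive")
        if self.pixel_size <= 0 or self.distance <= 0:
            raise ValueError("pixel_size and distance must be positive")

    def with_beam_center(self, slow: float, fast: float) -> "DetectorGeometry":
        return replace(self, beam_center=(float(slow), float(fast)))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_slow, self.n_fast)


def q_vectors_from_pixels(pixels: np.ndarray, geom: DetectorGeometry,
                          wavelength: float,
                          beam_center=None) -> np.ndarray:
    """Scattering vectors (1/angstrom) for ``(slow, fast)`` pixel positions.

    ``q = s/lambda - z/lambda`` with ``s`` the unit vector from the crystal
    to the pixel, so ``|q| = 2 sin(theta) / lambda = 1/d``.
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    bc = geom.beam_center if beam_center is None else beam_center
    y_mm = (pixels[:, 0] - bc[0]) * geom.pixel_size
    x_mm = (pixels[:, 1] - bc[1]) * geom.pixel_size
    vec = np.column_stack([x_mm, y_mm, np.full(len(pixels), geom.distance)])
    s = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    s[:, 2] -= 1.0
    return s / wavelength


def project_q_to_pixels(q: np.ndarray, geom: DetectorGeometry,
                        wavelength: float,
                        beam_center=None) -> tuple[np.ndarray, np.ndarray]:
    """Project reciprocal vectors through the Ewald construction onto the
    detector.

    The diffracted ray for node ``q`` leaves the sphere centre through the
    node: direction ``q + z/lambda``.  Returns ``(positions, on_detector)``
    where positions are ``(slow, fast)`` pixels (NaN where the ray points
    away from the detector) and ``on_detector`` also requires the position
    to land on the raster.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    bc = geom.beam_center if beam_center is None else beam_center
    s = q.copy()
    s[:, 2] += 1.0 / wavelength
    pos = np.full((len(q), 2), np.nan)
    forward = s[:, 2] > 1e-12
    x_mm = geom.distance * s[forward, 0] / s[forward, 2]
    y_mm = geom.distance * s[forward, 1] / s[forward, 2]
    pos[forward, 0] = y_mm / geom.pixel_size + bc[0]
    pos[forward, 1] = x_mm / geom.pixel_size + bc[1]
    on = (forward
          & (pos[:, 0] >= 0) & (pos[:, 0] <= geom.n_slow - 1)
          & (pos[:, 1] >= 0) & (pos[:, 1] <= geom.n_fast - 1))
    return pos, on


def d_spacing_at_pixel(pixels: np.ndarray, geom: DetectorGeometry,
                       wavelength: float) -> np.ndarray:
    """Resolution d (angstrom) of pixel positions via Bragg's law.

    ``tan(2 theta) = r_mm / distance``; the direct-beam pixel maps to +inf.
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    dy = (pixels[:, 0] - geom.beam_center[0]) * geom.pixel_size
    dx = (pixels[:, 1] - geom.beam_center[1]) * geom.pixel_size
    r = np.hypot(dx, dy)
    two_theta = np.arctan2(r, geom.distance)
    with np.errstate(divide="ignore"):
        return wavelength / (2.0 * np.sin(two_theta / 2.0))


def ewald_offsets(q: np.ndarray, wavelength: float) -> np.ndarray:
    """Signed distance (1/angstrom) of each node from the Ewald sphere.

    Positive values lie outside the sphere.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    centre = np.array([0.0, 0.0, -1.0 / wavelength])
    return np.linalg.norm(q - centre, axis=1) - 1.0 / wavelength
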