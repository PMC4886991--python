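"""In-memory still-image container."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DetectorGeometry

__all__ = ["ImageFrame"]


@dataclass
class ImageFrame:
    """One still exposure: intensity raster plus geometry.

    ``raster`` is ``(slow, fast)``, non-negative integers (detector counts).
    ``mask`` marks excluded pixels with True (beam-stop shadow, padding).
    """

    raster: np.ndarray
    geometry: DetectorGeometry
    wavelength: float
    mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.raster.shape != self.geometry.shape:
            raise ValueError(
                f"raster shape {self.raster.shape} does not match geometry "
                f"{self.geometry.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.raster.shape:
                raise ValueError("mask shape must equal raster shape")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    def effective_mask(self) -> np.ndarray:
        """Boolean exclusion mask, all-False when none was set."""
        if self.mask is None:
            return np.zeros(self.raster.shape, dtype=bool)
        return self.mask

    def with_mask(self, mask: np.ndarray) -> "ImageFrame":
        """Copy of the frame with ``mask`` OR-ed onto any existing mask."""
        combined = self.effective_mask() | np.asarray(mask, dtype=bool)
        return replace(self, mask=combined)
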