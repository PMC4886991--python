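"""Synthetic still-diffraction image generation with known ground truth.

Every downstream stage (triage, spot finding, indexing, integration, EPV
selection, clustering) is exercised against frames produced here, so the
generator records a full manifest of what it drew: the crystal model and,
per frame, every reflection close enough to the Ewald sphere to diffract,
with its Miller index, detector position and true integrated intensity.

The reflection model mirrors the mosaic picture used for the Ewald
proximal volume: a node at resolution ``d`` diffracts when its distance
``delta`` from the sphere satisfies ``|delta| <= w(d)/2`` with
``w = 2/D + eta/d``; the recorded intensity is attenuated by a smooth
partiality factor ``exp(-delta^2 / (2 sigma_r^2))`` whose FWHM equals
``w``.  Spots are drawn as isotropic 2-D Gaussians on the detector and
Poisson noise is applied to background plus signal.  This emulates the
image-to-image variability of serial data (spot size, intensity,
background, blank frames); it makes no attempt at SASE spectra,
polarization, absorption or panel geometry.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cells import b_matrix, validate_cell
from .epv import spot_width
from .frame import ImageFrame
from .geometry import DetectorGeometry, ewald_offsets, project_q_to_pixels
from .smv import write_frame

__all__ = ["GroundTruth", "Heterogeneity", "random_crystal",
           "reflection_manifest", "render_still", "generate_dataset",
           "default_geometry"]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355...


@dataclass(frozen=True)
class GroundTruth:
    """True crystal model behind one synthetic frame."""

    cell: tuple                      # (a, b, c, alpha, beta, gamma)
    orientation: np.ndarray          # 3x3 proper rotation
    mosaic_block_size_D: float       # angstrom
    mosaic_angle_eta: float          # rad, full width
    wavelength: float                # angstrom
    is_blank: bool = False
    seed: int = 0

    def __post_init__(self):
        validate_cell(self.cell)
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("orientation must be a proper rotation matrix")
        object.__setattr__(self, "orientation", R)
        if self.mosaic_block_size_D <= 0:
            raise ValueError("mosaic block size D must be positive")
        if self.mosaic_angle_eta < 0:
            raise ValueError("mosaic angle eta must be non-negative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def quaternion(self) -> np.ndarray:
        """Scalar-last (x, y, z, w) unit quaternion of the orientation."""
        return Rotation.from_matrix(self.orientation).as_quat()


def default_geometry(n: int = 256, pixel_size: float = 0.172,
                     distance: float = 50.0) -> DetectorGeometry:
    """Small PILATUS-like detector centred on the beam."""
    return DetectorGeometry(n_slow=n, n_fast=n, pixel_size=pixel_size,
                            distance=distance,
                            beam_center=((n - 1) / 2.0, (n - 1) / 2.0))


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform draw from SO(3) via Shoemake's subgroup-algorithm quaternion:
    three independent U(0,1) variates map to a Haar-uniform unit quaternion.
    """
    u1, u2, u3 = rng.random(3)
    quat = np.array([
        np.sqrt(1.0 - u1) * np.sin(2.0 * np.pi * u2),
        np.sqrt(1.0 - u1) * np.cos(2.0 * np.pi * u2),
        np.sqrt(u1) * np.sin(2.0 * np.pi * u3),
        np.sqrt(u1) * np.cos(2.0 * np.pi * u3),
    ])
    return Rotation.from_quat(quat).as_matrix()


def random_crystal(cell, D_range, eta_range, rng_seed: int,
                   wavelength: float = 1.3,
                   is_blank: bool = False) -> GroundTruth:
    """Draw a crystal: uniform orientation, D and eta uniform in the given
    closed intervals.  Deterministic given ``rng_seed``."""
    cell = validate_cell(cell)
    if not (D_range[0] <= D_range[1]) or D_range[0] <= 0:
        raise ValueError(f"invalid D_range {D_range}")
    if not (eta_range[0] <= eta_range[1]) or eta_range[0] < 0:
        raise ValueError(f"invalid eta_range {eta_range}")
    rng = np.random.default_rng(rng_seed)
    R = _uniform_rotation(rng)
    D = rng.uniform(D_range[0], D_range[1])
    eta = rng.uniform(eta_range[0], eta_range[1])
    return GroundTruth(cell=cell, orientation=R, mosaic_block_size_D=float(D),
                       mosaic_angle_eta=float(eta), wavelength=wavelength,
                       is_blank=is_blank, seed=int(rng_seed))


def _enumerate_nodes(truth: GroundTruth, d_min: float):
    """All reciprocal nodes with d >= d_min: Miller indices and lab-frame q."""
    B = truth.orientation @ b_matrix(truth.cell)
    a, b, c = truth.cell[:3]
    hmax = int(np.ceil(a / d_min))
    kmax = int(np.ceil(b / d_min))
    lmax = int(np.ceil(c / d_min))
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ B.T
    d = 1.0 / np.linalg.norm(q, axis=1)
    keep = d >= d_min
    return hkl[keep], q[keep], d[keep]


def reflection_manifest(truth: GroundTruth, det: DetectorGeometry,
                        d_min: float) -> pd.DataFrame:
    """Reflections within the mosaic half-width of the Ewald sphere.

    Columns: h k l, delta (signed sphere offset), d, partiality,
    slow/fast detector position (NaN off-detector), on_detector flag.
    """
    if d_min < truth.wavelength / 2.0:
        raise ValueError("d_min below the Bragg limit lambda/2")
    empty = pd.DataFrame(columns=["h", "k", "l", "delta", "d", "partiality",
                                  "slow", "fast", "on_detector"])
    if truth.is_blank:
        return empty
    hkl, q, d = _enumerate_nodes(truth, d_min)
    if len(hkl) == 0:
        return empty
    delta = ewald_offsets(q, truth.wavelength)
    w = spot_width(d, truth.mosaic_block_size_D, truth.mosaic_angle_eta)
    near = np.abs(delta) <= w / 2.0
    hkl, q, d, delta, w = hkl[near], q[near], d[near], delta[near], w[near]
    sigma_r = w / (2.0 * _FWHM)
    partiality = np.exp(-(delta ** 2) / (2.0 * sigma_r ** 2))
    pos, on = project_q_to_pixels(q, det, truth.wavelength)
    df = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
        "delta": delta, "d": d, "partiality": partiality,
        "slow": pos[:, 0], "fast": pos[:, 1], "on_detector": on,
    })
    return df.sort_values(["h", "k", "l"], ignore_index=True)


def render_still(truth: GroundTruth, det: DetectorGeometry,
                 background_mean: float, d_min: float, rng_seed: int,
                 spot_sigma_px: float = 1.3,
                 mean_intensity: float = 2000.0,
                 intensity_spread: float = 0.5,
                 poisson_noise: bool = True):
    """Render one frame; returns ``(ImageFrame, manifest)``.

    ``mean_intensity`` is the mean full (partiality-free) integrated spot
    intensity in counts; per-reflection intensities are lognormal with the
    given log-sd.  With ``poisson_noise=False`` the expectation image is
    rounded deterministically (used for noiseless ground-truth fixtures).
    """
    if background_mean < 0:
        raise ValueError("background_mean must be non-negative")
    rng = np.random.default_rng(rng_seed)
    manifest = reflection_manifest(truth, det, d_min)
    image = np.full(det.shape, float(background_mean))
    intensities = np.zeros(len(manifest))
    if len(manifest):
        full = rng.lognormal(np.log(mean_intensity) - intensity_spread ** 2 / 2,
                             intensity_spread, len(manifest))
        intensities = full * manifest["partiality"].to_numpy()
        half = max(int(np.ceil(4 * spot_sigma_px)), 2)
        offsets = np.arange(-half, half + 1)
        oy, ox = np.meshgrid(offsets, offsets, indexing="ij")
        for inten, slow, fast, on in zip(intensities,
                                         manifest["slow"].to_numpy(),
                                         manifest["fast"].to_numpy(),
                                         manifest["on_detector"].to_numpy()):
            if not on:
                continue
            cs, cf = int(round(slow)), int(round(fast))
            stamp = np.exp(-(((oy + cs - slow) ** 2 + (ox + cf - fast) ** 2)
                             / (2.0 * spot_sigma_px ** 2)))
            stamp *= inten / (2.0 * np.pi * spot_sigma_px ** 2)
            ys, xs = oy + cs, ox + cf
            ok = (ys >= 0) & (ys < det.n_slow) & (xs >= 0) & (xs < det.n_fast)
            np.add.at(image, (ys[ok], xs[ok]), stamp[ok])
    manifest = manifest.assign(intensity=intensities)
    if poisson_noise:
        raster = rng.poisson(image)
    else:
        raster = np.rint(image).astype(np.int64)
    raster = np.clip(raster, 0, 65535).astype(np.int64)
    frame = ImageFrame(raster, det, truth.wavelength,
                       source_id=f"sim-{truth.seed}")
    return frame, manifest


@dataclass(frozen=True)
class Heterogeneity:
    """Per-image variability ranges for generate_dataset."""

    D_range: tuple = (300.0, 1000.0)
    eta_range: tuple = (0.0005, 0.004)
    spot_sigma_range: tuple = (0.9, 2.8)      # sharp cores to diffuse blobs
    intensity_range: tuple = (400.0, 4000.0)  # weak diffraction is the norm
    background_range: tuple = (30.0, 150.0)
    cell_jitter: float = 0.002          # relative sd on cell lengths


def _image_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    # counter scheme: child sequence keyed on (master, index)
    return np.random.SeedSequence([int(master_seed), int(index)])


def generate_dataset(n_images: int, blank_fraction: float, populations,
                     heterogeneity: Heterogeneity | None, out_dir,
                     rng_seed: int, det: DetectorGeometry | None = None,
                     wavelength: float = 1.3, d_min: float = 3.5,
                     poisson_noise: bool = True) -> pd.DataFrame:
    """Write ``n_images`` SMV frames plus ``manifest.tsv`` to ``out_dir``.

    ``populations`` is a list of ``(cell, weight)`` with weights summing
    to 1; each frame draws its form from that mixture, then jitters the
    cell lengths.  Roughly ``blank_fraction`` of frames carry background
    only.  Fully deterministic given ``rng_seed`` (per-image generators are
    keyed on ``(rng_seed, image_index)``).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0.0 <= blank_fraction <= 1.0:
        raise ValueError("blank_fraction must be in [0, 1]")
    weights = np.array([w for _, w in populations], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("population weights must sum to 1")
    cells = [validate_cell(c) for c, _ in populations]
    het = heterogeneity or Heterogeneity()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    det = det or default_geometry()

    rows = []
    for i in range(n_images):
        ss = _image_seed(rng_seed, i)
        rng = np.random.default_rng(ss)
        is_blank = bool(rng.random() < blank_fraction)
        form = int(rng.choice(len(cells), p=weights))
        cell = np.array(cells[form])
        cell[:3] *= 1.0 + het.cell_jitter * rng.standard_normal(3)
        R = _uniform_rotation(rng)
        truth = GroundTruth(cell=tuple(cell), orientation=R,
                            mosaic_block_size_D=float(rng.uniform(*het.D_range)),
                            mosaic_angle_eta=float(rng.uniform(*het.eta_range)),
                            wavelength=wavelength, is_blank=is_blank, seed=i)
        frame, manifest = render_still(
            truth, det,
            background_mean=float(rng.uniform(*het.background_range)),
            d_min=d_min,
            rng_seed=np.random.default_rng(ss.spawn(1)[0]).integers(2 ** 31),
            spot_sigma_px=float(rng.uniform(*het.spot_sigma_range)),
            mean_intensity=float(rng.uniform(*het.intensity_range)),
            poisson_noise=poisson_noise)
        name = f"frame_{i:05d}.img"
        write_frame(frame, out_dir / name)
        quat = truth.quaternion
        rows.append({
            "filename": name, "is_blank": int(is_blank), "form": form,
            **{k: v for k, v in zip("abc", truth.cell[:3])},
            "alpha": truth.cell[3], "beta": truth.cell[4],
            "gamma": truth.cell[5],
            "qx": quat[0], "qy": quat[1], "qz": quat[2], "qw": quat[3],
            "D": truth.mosaic_block_size_D, "eta": truth.mosaic_angle_eta,
            "n_reflections": int(manifest["on_detector"].sum()) if len(manifest) else 0,
        })
    manifest_df = pd.DataFrame(rows)
    manifest_df.to_csv(out_dir / "manifest.tsv", sep="\t", index=False,
                       float_format="%.8g")
    return manifest_df
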