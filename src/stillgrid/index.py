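"""Target-cell indexing, lattice refinement and mosaic-parameter estimation.

Indexing here is orientation search against a known target cell: each
candidate Bragg spot maps to a reciprocal-space vector through the Ewald
construction, and we search SO(3) for the rotation that places the most
observed vectors on reciprocal-lattice nodes.  The coarse stage scores a
low-discrepancy covering of the rotation group (super-Fibonacci spiral);
the best candidates are polished by iterated nearest-node assignment with
a Kabsch (orthogonal Procrustes) solve, which converges from a few degrees
away.  Cell lengths and beam centre are then refined by least squares on
observed-minus-predicted spot positions.

Mosaic parameters (block size D, rotational spread eta) are estimated by a
coverage criterion: on a documented 2-D scan, the spot-width model with
the smallest Ewald proximal volume such that every indexed strong spot's
node lies within half the model spot width w(d) = 2/D + eta/d of the
Ewald sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .cells import b_matrix, niggli_reduce, validate_cell
from .epv import compute_epv
from .frame import ImageFrame
from .geometry import (DetectorGeometry, ewald_offsets, project_q_to_pixels,
                       q_vectors_from_pixels)
from .spotfind import Spot

__all__ = ["LatticeModel", "IndexingError", "fit_orientation",
           "refine_lattice", "index_still", "estimate_mosaic",
           "bravais_filter"]


class IndexingError(RuntimeError):
    """Indexing failure with a machine-readable ``reason``."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class LatticeModel:
    """Crystal model for one still."""

    cell: tuple
    orientation: np.ndarray                  # 3x3 proper rotation
    mosaic_block_size_D: float = 500.0       # angstrom
    mosaic_angle_eta: float = 0.0            # rad, full width
    beam_center_refined: tuple = (np.nan, np.nan)   # pixels (slow, fast)
    rmsd_obs_pred: float = np.nan            # pixels
    n_indexed: int = 0
    refined: bool = False
    mosaic_saturated: bool = False

    def __post_init__(self):
        validate_cell(self.cell)
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("orientation must be a proper rotation")
        self.orientation = R


def _super_fibonacci(n: int) -> np.ndarray:
    """n quaternions quasi-uniformly covering SO(3) (super-Fibonacci
    spiral: the double-Fibonacci construction on the 3-sphere)."""
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041    # root of psi^4 = psi + 4
    i = np.arange(n) + 0.5
    r = np.sqrt(i / n)
    big_r = np.sqrt(1.0 - i / n)
    alpha = 2.0 * np.pi * i / phi
    beta = 2.0 * np.pi * i / psi
    return np.column_stack([r * np.sin(alpha), r * np.cos(alpha),
                            big_r * np.sin(beta), big_r * np.cos(beta)])


def _spot_q(spots: list[Spot], geom: DetectorGeometry, wavelength: float,
            beam_center=None) -> np.ndarray:
    pixels = np.array([s.centroid for s in spots], dtype=float)
    return q_vectors_from_pixels(pixels, geom, wavelength,
                                 beam_center=beam_center)


def _reject_merged(spots: list[Spot], factor: float = 1.4) -> list[Spot]:
    """Drop area outliers: within one still the spot footprint is set by
    the crystal, so isolated-spot areas cluster tightly around the median
    and components much larger are overlapping reflections whose joint
    centroid indexes nowhere."""
    if len(spots) < 5:
        return spots
    median_area = float(np.median([s.area for s in spots]))
    kept = [s for s in spots if s.area <= factor * median_area]
    return kept if len(kept) >= 5 else spots


def _index_tolerance(cell) -> float:
    """0.15 x shortest reciprocal cell edge (1/angstrom)."""
    return 0.15 * np.linalg.norm(b_matrix(cell), axis=0).min()


#: Assignment-tolerance relaxation used while searching and refining.  A
#: couple of pixels of beam-centre error shifts every observed vector by a
#: common offset larger than the strict indexing tolerance; searching at
#: the relaxed tolerance lets such solutions surface so that beam-centre
#: refinement can pull them back in.  Validation stays at the strict value.
_SEARCH_RELAX = 2.5


def _lattice_residuals(R: np.ndarray, B: np.ndarray,
                       q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-node Miller assignment and Cartesian residual norms."""
    hfrac = q @ R @ np.linalg.inv(B).T       # == Binv @ R.T @ q_i, stacked
    hkl = np.rint(hfrac)
    err = (hfrac - hkl) @ B.T                # rotation preserves norms
    return hkl, np.linalg.norm(err, axis=1)


def _polish_with_beam(R0: np.ndarray, bc0, pixels: np.ndarray,
                      geom: DetectorGeometry, wavelength: float,
                      B: np.ndarray, tol: float, n_iter: int = 15,
                      update_beam: bool = True) -> tuple[np.ndarray, tuple]:
    """Iterated assign-and-align refinement of rotation plus beam centre.

    Alternates a Kabsch solve for the rotation with a direct solve for the
    beam centre: in this projection model a beam-centre shift moves every
    predicted position by exactly that shift, so the optimal correction is
    the robust mean of the observed-minus-predicted positions of currently
    assigned spots.
    """
    R, bc = R0, tuple(bc0)
    prev_hkl = None
    shift = np.zeros(2)
    for _ in range(n_iter):
        q = q_vectors_from_pixels(pixels, geom, wavelength, beam_center=bc)
        hkl, res = _lattice_residuals(R, B, q)
        use = (res <= 3.0 * tol) & np.any(hkl != 0, axis=1)
        if use.sum() < 3:
            return R, bc
        target = hkl[use] @ B.T
        M = q[use].T @ target
        U, _, Vt = np.linalg.svd(M)
        S = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ S @ Vt
        if update_beam:
            pred, _ = project_q_to_pixels(target @ R.T, geom, wavelength,
                                          beam_center=bc)
            diff = pixels[use] - pred
            diff = diff[np.all(np.isfinite(diff), axis=1)]
            if len(diff):
                shift = np.median(diff, axis=0)
                shift = np.clip(shift, -3.0, 3.0)
                bc = (bc[0] + shift[0], bc[1] + shift[1])
        if prev_hkl is not None and hkl.shape == prev_hkl.shape \
                and np.array_equal(hkl, prev_hkl) \
                and np.hypot(*shift) < 1e-4:
            break
        prev_hkl = hkl
    return R, bc


def fit_orientation(spots: list[Spot], target_cell, geom: DetectorGeometry,
                    wavelength: float, n_min: int = 10, f_idx: float = 0.5,
                    n_rotations: int = 80000, max_spots: int = 40,
                    top_k: int = 300,
                    initial_orientation: np.ndarray | None = None,
                    allow_full_search: bool = True,
                    _escalated: bool = False) -> LatticeModel:
    """Find the crystal orientation that indexes the spot list.

    Succeeds iff at least a fraction ``f_idx`` of the (brightest
    ``max_spots``) spots land within the indexing tolerance of a
    reciprocal-lattice node.  ``initial_orientation`` short-circuits the
    coarse search with a local polish from a known-good rotation (used to
    reuse one image's orientation across grid points); the full search
    runs as fallback when the shortcut fails.

    Raises :class:`IndexingError` with reason ``insufficient spots`` or
    ``indexing failed``.
    """
    cell = validate_cell(target_cell)
    if len(spots) < n_min:
        raise IndexingError("insufficient spots")
    spots_used = _reject_merged(spots)[:max_spots]  # intensity-sorted
    pixels = np.array([s.centroid for s in spots_used], dtype=float)
    q = _spot_q(spots_used, geom, wavelength)
    B = b_matrix(cell)
    BinvT = np.linalg.inv(B).T
    tol = _index_tolerance(cell)

    def finish(R: np.ndarray, bc) -> LatticeModel | None:
        qv = q_vectors_from_pixels(pixels, geom, wavelength, beam_center=bc)
        hkl, res = _lattice_residuals(R, B, qv)
        # acceptance bar at twice the strict tolerance: wide mosaic models
        # park genuine reflections up to w(d)/2 off the sphere, which the
        # back-projected residual inherits; a random rotation still only
        # hits ~5% of spots at this radius, far below the f_idx bar.  The
        # absolute floor of n_min indexed spots keeps sparse frames from
        # being "solved" by a spurious aliased orientation
        ok = (res <= 2.0 * tol) & np.any(hkl != 0, axis=1)
        if ok.sum() < max(f_idx * len(qv), float(n_min)):
            return None
        return LatticeModel(cell=cell, orientation=R,
                            beam_center_refined=tuple(bc),
                            n_indexed=int(ok.sum()))

    if initial_orientation is not None:
        R, bc = _polish_with_beam(np.asarray(initial_orientation, float),
                                  geom.beam_center, pixels, geom, wavelength,
                                  B, tol)
        model = finish(R, bc)
        if model is not None:
            return model
        if not allow_full_search:
            raise IndexingError("indexing failed")
    elif not allow_full_search:
        raise IndexingError("indexing failed")

    quats = _super_fibonacci(n_rotations)
    scores = np.empty(n_rotations, dtype=np.int32)
    resid = np.empty(n_rotations)
    refined_R = np.empty((n_rotations, 3, 3))
    refined_bc = np.empty((n_rotations, 2))
    chunk = 4000
    score_tol = _SEARCH_RELAX * tol
    bc_nominal = np.array(geom.beam_center, dtype=float)
    for lo in range(0, n_rotations, chunk):
        Rs = Rotation.from_quat(quats[lo:lo + chunk]).as_matrix()
        n_c = len(Rs)
        bc = np.tile(bc_nominal, (n_c, 1))
        # batched soft-weighted sweeps alternating a Kabsch solve with a
        # per-candidate beam-centre update pull every candidate to the
        # nearest joint (rotation, beam) optimum, widening the effective
        # basin from ~1 degree (raw nearest-node scoring) to the covering
        # radius of the rotation grid even under a small beam-centre error
        for sweep in range(3):
            y_mm = (pixels[None, :, 0] - bc[:, :1]) * geom.pixel_size
            x_mm = (pixels[None, :, 1] - bc[:, 1:]) * geom.pixel_size
            vec = np.stack([x_mm, y_mm,
                            np.full_like(x_mm, geom.distance)], axis=2)
            s_in = vec / np.linalg.norm(vec, axis=2, keepdims=True)
            q_nm = s_in.copy()
            q_nm[:, :, 2] -= 1.0
            q_nm /= wavelength
            hfrac = np.einsum("nmk,nkj,jl->nml", q_nm, Rs, BinvT)
            hkl = np.rint(hfrac)
            err = np.linalg.norm(
                np.einsum("ij,nmj->nmi", B, hfrac - hkl), axis=2)
            wgt = 1.0 / (1.0 + (err / score_tol) ** 2)
            target = np.einsum("nmj,kj->nmk", hkl, B)
            M = np.einsum("nm,nmk,nmj->nkj", wgt, q_nm, target)
            U, _, Vt = np.linalg.svd(M)
            sign = np.sign(np.linalg.det(np.einsum("nij,njk->nik", U, Vt)))
            U[:, :, 2] *= sign[:, None]
            Rs = np.einsum("nij,njk->nik", U, Vt)
            if sweep == 0:
                continue          # let the rotation settle first
            s_out = np.einsum("nmj,nkj->nmk", target, Rs)
            s_out[:, :, 2] += 1.0 / wavelength
            with np.errstate(divide="ignore", invalid="ignore"):
                px_fast = (geom.distance * s_out[:, :, 0] / s_out[:, :, 2]
                           / geom.pixel_size + bc[:, 1:])
                px_slow = (geom.distance * s_out[:, :, 1] / s_out[:, :, 2]
                           / geom.pixel_size + bc[:, :1])
            d_slow = pixels[None, :, 0] - px_slow
            d_fast = pixels[None, :, 1] - px_fast
            good = np.isfinite(d_slow) & np.isfinite(d_fast)
            w2 = np.where(good, wgt, 0.0)
            norm = w2.sum(axis=1) + 1e-12
            shift = np.stack([(w2 * np.where(good, d_slow, 0)).sum(axis=1),
                              (w2 * np.where(good, d_fast, 0)).sum(axis=1)],
                             axis=1) / norm[:, None]
            bc = bc + np.clip(shift, -2.0, 2.0)
        y_mm = (pixels[None, :, 0] - bc[:, :1]) * geom.pixel_size
        x_mm = (pixels[None, :, 1] - bc[:, 1:]) * geom.pixel_size
        vec = np.stack([x_mm, y_mm,
                        np.full_like(x_mm, geom.distance)], axis=2)
        s_in = vec / np.linalg.norm(vec, axis=2, keepdims=True)
        q_nm = s_in
        q_nm[:, :, 2] -= 1.0
        q_nm /= wavelength
        hfrac = np.einsum("nmk,nkj,jl->nml", q_nm, Rs, BinvT)
        err = np.linalg.norm(
            np.einsum("ij,nmj->nmi", B, hfrac - np.rint(hfrac)), axis=2)
        scores[lo:lo + chunk] = (err <= tol).sum(axis=1)
        resid[lo:lo + chunk] = np.minimum(err, score_tol).mean(axis=1)
        refined_R[lo:lo + chunk] = Rs
        refined_bc[lo:lo + chunk] = bc
    order = np.lexsort((resid, -scores))[:top_k]
    best = None
    for idx in order:
        # two polish variants per candidate: rotation-only from the nominal
        # beam (wide basin; a residual beam error fits inside the relaxed
        # acceptance radius and is repaired by refine_lattice), and joint
        # rotation+beam from the sweep state (narrow basin, exact)
        attempts = [_polish_with_beam(refined_R[idx], refined_bc[idx],
                                      pixels, geom, wavelength, B, tol),
                    _polish_with_beam(refined_R[idx], geom.beam_center,
                                      pixels, geom, wavelength, B, tol,
                                      update_beam=False)]
        for R, bc in attempts:
            model = finish(R, bc)
            if model is not None and (best is None
                                      or model.n_indexed > best.n_indexed):
                best = model
        if best is not None and best.n_indexed >= 0.9 * len(q):
            break
    if best is None:
        if _escalated:
            raise IndexingError("indexing failed")
        # one escalation: a denser rotation grid with more polish starts
        # rescues frames whose basin fell between coarse candidates
        return fit_orientation(spots, target_cell, geom, wavelength,
                               n_min=n_min, f_idx=f_idx,
                               n_rotations=2 * n_rotations, max_spots=max_spots,
                               top_k=2 * top_k, _escalated=True)
    return best


def _predicted_pixels(params: np.ndarray, base: LatticeModel,
                      hkl: np.ndarray, geom: DetectorGeometry,
                      wavelength: float) -> np.ndarray:
    """Spot positions predicted from refinement parameters.

    ``params`` = (rotvec perturbation (3), relative scale of a/b/c (3),
    beam-centre shift in pixels (2)).
    """
    drot = Rotation.from_rotvec(params[:3]).as_matrix()
    cell = list(base.cell)
    for i in range(3):
        cell[i] = base.cell[i] * (1.0 + params[3 + i])
    B = b_matrix(tuple(cell))
    q = hkl @ (drot @ base.orientation @ B).T
    bc = (geom.beam_center[0] + params[6], geom.beam_center[1] + params[7])
    pos, _ = project_q_to_pixels(q, geom, wavelength, beam_center=bc)
    return pos


def refine_lattice(model: LatticeModel, spots: list[Spot],
                   frame: ImageFrame, max_spots: int = 120) -> LatticeModel:
    """Least-squares refinement of orientation, cell lengths and beam
    centre against observed spot positions.

    Cell angles stay at their target values (still images barely constrain
    them).  Guarded: if the refit increases the positional rmsd, the input
    model is returned with ``refined=False``.
    """
    geom, wavelength = frame.geometry, frame.wavelength
    spots_used = _reject_merged(spots)[:max_spots]
    bc0 = model.beam_center_refined
    if not np.all(np.isfinite(bc0)):
        bc0 = geom.beam_center
    q_obs = _spot_q(spots_used, geom, wavelength, beam_center=bc0)
    all_obs = np.array([s.centroid for s in spots_used])
    tol_strict = _index_tolerance(model.cell)
    tol = _SEARCH_RELAX * tol_strict
    current = model
    rms1 = np.nan
    for round_i in range(2):  # refit with reassignment under the new model
        B = b_matrix(current.cell)
        if round_i > 0:
            # the first round absorbed any beam-centre error; reassign
            # strictly so stray matches cannot bias the final parameters
            bc_now = current.beam_center_refined
            if np.all(np.isfinite(bc_now)):
                q_obs = _spot_q(spots_used, geom, wavelength,
                                beam_center=bc_now)
        round_tol = tol if round_i == 0 else tol_strict
        hkl, res = _lattice_residuals(current.orientation, B, q_obs)
        use = (res <= round_tol) & np.any(hkl != 0, axis=1)
        if use.sum() < 5:
            return replace(model, beam_center_refined=tuple(bc0),
                           refined=False)
        hkl_use = hkl[use]
        obs = all_obs[use]

        def residuals(params, base=current, hkl_use=hkl_use, obs=obs):
            pred = _predicted_pixels(params, base, hkl_use, geom, wavelength)
            out = (pred - obs).ravel()
            out = np.where(np.isfinite(out), out, 1e3)
            # a still constrains cell scales only in the plane normal to
            # the beam; a weak prior (sd 0.5% per axis) pins the unseen
            # direction to the target instead of letting it drift
            prior = params[3:6] / 0.005
            return np.concatenate([out, prior])

        x0 = np.zeros(8)
        x0[6] = bc0[0] - geom.beam_center[0]
        x0[7] = bc0[1] - geom.beam_center[1]
        rms0 = np.sqrt(np.mean(residuals(x0) ** 2))
        bounds = ([-0.2] * 3 + [-0.1] * 3 + [-20.0] * 2,
                  [0.2] * 3 + [0.1] * 3 + [20.0] * 2)
        fit = least_squares(residuals, x0, method="trf", loss="soft_l1",
                            f_scale=0.5, bounds=bounds, xtol=1e-12,
                            ftol=1e-12)
        rms1 = np.sqrt(np.mean(fit.fun ** 2))
        if not fit.success or rms1 > rms0 + 1e-9:
            if current is model:
                return replace(model, rmsd_obs_pred=float(rms0),
                               beam_center_refined=tuple(bc0),
                               refined=False)
            break
        p = fit.x
        drot = Rotation.from_rotvec(p[:3]).as_matrix()
        cell = list(current.cell)
        for i in range(3):
            cell[i] = current.cell[i] * (1.0 + p[3 + i])
        current = replace(
            current, cell=tuple(cell),
            orientation=drot @ current.orientation,
            beam_center_refined=(geom.beam_center[0] + p[6],
                                 geom.beam_center[1] + p[7]),
            rmsd_obs_pred=float(rms1), refined=True)
    # recount indexed spots under the final model; a refit that indexes
    # fewer spots than it started with has jumped to a pseudo-solution
    # (cell aliasing can shrink the residuals on a sparse subset), so
    # revert to the input model in that case
    B0 = b_matrix(model.cell)
    _, res0 = _lattice_residuals(model.orientation, B0, q_obs)
    n_before = int((res0 <= tol_strict).sum())
    B2 = b_matrix(current.cell)
    _, res2 = _lattice_residuals(current.orientation, B2, q_obs)
    n_after = int((res2 <= tol_strict).sum())
    if n_after < n_before:
        return replace(model, n_indexed=n_before,
                       beam_center_refined=tuple(bc0), refined=False)
    return replace(current, n_indexed=n_after)


def estimate_mosaic(model: LatticeModel, spots: list[Spot],
                    frame: ImageFrame, d_L: float = 3.5,
                    inv_D_max: float = 1.0 / 50.0,
                    eta_max: float = 0.02,
                    n_eta: int = 81) -> LatticeModel:
    """Smallest covering mosaic model for the indexed spots.

    For each eta on a linear scan the minimum block-size term that still
    covers every spot is ``2/D >= max_i (2|delta_i| - eta/d_i)``; among
    those covering pairs the one with the smallest EPV is kept.  When even
    the scan boundary (``D = 1/inv_D_max``, ``eta = eta_max``) fails to
    cover, boundary values are returned flagged ``mosaic_saturated``.
    """
    geom, wavelength = frame.geometry, frame.wavelength
    bc = model.beam_center_refined
    if not np.all(np.isfinite(bc)):
        bc = geom.beam_center
    q_obs = _spot_q(_reject_merged(spots), geom, wavelength, beam_center=bc)
    B = b_matrix(model.cell)
    hkl, res = _lattice_residuals(model.orientation, B, q_obs)
    tol = _index_tolerance(model.cell)
    # wider assignment tolerance than indexing: a node a full spot
    # half-width off the sphere back-projects that far from its on-sphere
    # observation, and clipping at the indexing tolerance would cap the
    # recoverable mosaic width at the tolerance itself
    use = (res <= 3.0 * tol) & np.any(hkl != 0, axis=1)
    if use.sum() == 0:
        return replace(model, mosaic_saturated=True)
    nodes = hkl[use] @ (model.orientation @ B).T
    delta = np.abs(ewald_offsets(nodes, wavelength))
    inv_d = np.linalg.norm(nodes, axis=1)
    n_trim = int(0.02 * len(delta))          # tolerate ~2% stray assignments
    inv_D_min = 1.0 / 20000.0
    best = None
    for eta in np.linspace(0.0, eta_max, n_eta):
        deficit = 2.0 * delta - eta * inv_d
        if n_trim:
            deficit = np.sort(deficit)[:-n_trim]
        need = np.max(deficit) / 2.0
        inv_D = min(max(need, inv_D_min), inv_D_max)
        covered = need <= inv_D_max + 1e-15
        epv = compute_epv(1.0 / inv_D, eta, wavelength, d_L,
                          quadrature_points=96)
        if covered and (best is None or epv < best[0]):
            best = (epv, 1.0 / inv_D, eta)
    if best is None:
        return replace(model, mosaic_block_size_D=1.0 / inv_D_max,
                       mosaic_angle_eta=eta_max, mosaic_saturated=True)
    return replace(model, mosaic_block_size_D=best[1], mosaic_angle_eta=best[2],
                   mosaic_saturated=False)


def index_still(spots: list[Spot], target_cell, frame: ImageFrame,
                n_min: int = 10, n_rotations: int = 80000,
                initial_orientation: np.ndarray | None = None,
                allow_full_search: bool = True) -> LatticeModel:
    """Fit and refine a lattice model for one still, with a quality gate.

    Runs :func:`fit_orientation` followed by :func:`refine_lattice`.  A
    solution whose refinement was rejected and which indexes fewer than
    ``n_min`` spots at the strict tolerance is treated as unreliable; one
    retry with a doubled rotation grid is attempted before giving up.

    Raises :class:`IndexingError` when no trustworthy model is found.
    """
    geom, wavelength = frame.geometry, frame.wavelength
    last_exc: IndexingError | None = None
    for attempt, n_rot in enumerate((n_rotations, 2 * n_rotations)):
        try:
            model = fit_orientation(
                spots, target_cell, geom, wavelength, n_min=n_min,
                n_rotations=n_rot,
                initial_orientation=initial_orientation if attempt == 0
                else None,
                allow_full_search=allow_full_search)
        except IndexingError as exc:
            last_exc = exc
            if not allow_full_search:
                raise
            continue
        refined = refine_lattice(model, spots, frame)
        if refined.refined or refined.n_indexed >= n_min:
            return refined
        last_exc = IndexingError("refinement rejected the solution")
        if not allow_full_search:
            break
    raise last_exc or IndexingError("indexing failed")


_LATTICE_FAMILY_ANGLES = {
    "a": None,                # triclinic: no constraint
    "m": ("alpha", "gamma"),  # monoclinic: two right angles
    "o": ("alpha", "beta", "gamma"),
    "t": ("alpha", "beta", "gamma"),
    "h": None,                # checked separately
    "c": ("alpha", "beta", "gamma"),
}


def bravais_filter(cell, required_lattice: str,
                   target_cell=None, angle_tolerance: float = 1.0,
                   length_tolerance: float = 0.05) -> bool:
    """True iff the Niggli-reduced cell is consistent with the required
    Bravais lattice family (and optionally a target cell).

    ``required_lattice`` is a Pearson-style symbol such as ``oP``; only its
    family letter constrains the check (centring cannot be told apart on a
    reduced primitive cell).  Angles are compared within
    ``angle_tolerance`` degrees; lengths, when ``target_cell`` is given,
    within relative ``length_tolerance`` after sorting both reduced cells.
    """
    family = required_lattice[0].lower()
    if family not in _LATTICE_FAMILY_ANGLES:
        raise ValueError(f"unknown Bravais symbol {required_lattice!r}")
    red = niggli_reduce(cell)
    lengths, angles = np.array(red[:3]), np.array(red[3:])
    names = _LATTICE_FAMILY_ANGLES[family]
    if family in ("o", "t", "c"):
        if np.any(np.abs(angles - 90.0) > angle_tolerance):
            return False
    elif family == "m":
        # Niggli settings vary; require at least two ~90 degree angles
        if (np.abs(angles - 90.0) <= angle_tolerance).sum() < 2:
            return False
    elif family == "h":
        ok_hex = (abs(angles[0] - 90) <= angle_tolerance
                  and abs(angles[1] - 90) <= angle_tolerance
                  and abs(angles[2] - 120) <= angle_tolerance)
        rhomb = (np.max(angles) - np.min(angles) <= angle_tolerance
                 and np.max(lengths) / np.min(lengths) - 1 <= length_tolerance)
        if not (ok_hex or rhomb):
            return False
    if family == "t":
        s = np.sort(lengths)
        if not (abs(s[1] / s[0] - 1) <= length_tolerance
                or abs(s[2] / s[1] - 1) <= length_tolerance):
            return False
    if family == "c":
        s = np.sort(lengths)
        if abs(s[2] / s[0] - 1) > length_tolerance:
            return False
    if target_cell is not None:
        tgt = np.sort(np.array(niggli_reduce(target_cell)[:3]))
        got = np.sort(lengths)
        if np.any(np.abs(got / tgt - 1.0) > length_tolerance):
            return False
    return True
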